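import numpy as np
import pytest

from nemasex import synth
from nemasex.morphometry import (
    MidlineSkeleton,
    Rejection,
    TailProbeConfig,
    diameter_at,
    extract_features,
    measure_length,
    measure_thickness,
    skeletonize_region,
    tail_ratios,
)
from nemasex.segmentation import InvalidParameterError, WormRegion

from conftest import rectangle_region, region_from_mask


def make_line_skeleton(points, um_per_pixel=6.5):
    pts = np.asarray(points)
    steps = np.where(
        (pts[1:, 0] == pts[:-1, 0]) | (pts[1:, 1] == pts[:-1, 1]), 1.0, np.sqrt(2.0)
    )
    return MidlineSkeleton(
        points=pts,
        step_lengths=steps,
        total_length_px=float(steps.sum()),
        cumulative_um=np.concatenate([[0.0], np.cumsum(steps)]) * um_per_pixel,
        um_per_pixel=um_per_pixel,
    )


def cone_region(d_at_20=14.0, d_at_120=42.0, length_um=800.0, um_per_pixel=6.5):
    """Straight worm with symmetric linear tapers hitting given diameters at 20/120 um."""
    s = np.linspace(0, length_um, 800)
    xp = [0.0, 20.0, 120.0, length_um - 120.0, length_um - 20.0, length_um]
    fp = [3.0, d_at_20 / 2, d_at_120 / 2, d_at_120 / 2, d_at_20 / 2, 3.0]
    half = np.interp(s, xp, fp)
    pts_px = np.stack([np.full_like(s, 40.0), 10 + s / um_per_pixel], axis=1)
    mask = np.zeros((80, int(30 + length_um / um_per_pixel)), dtype=bool)
    synth._stamp_discs(mask, pts_px, half / um_per_pixel)
    return region_from_mask(mask, um_per_pixel)


class TestSkeletonize:
    def test_rectangle_gives_single_path(self):
        skel = skeletonize_region(rectangle_region(200, 10))
        assert isinstance(skel, MidlineSkeleton)
        assert len(skel.points) >= 2
        # strictly increasing arc length, single 8-connected path
        assert np.all(np.diff(skel.cumulative_um) > 0)
        assert np.all(np.abs(np.diff(skel.points, axis=0)).max(axis=1) == 1)

    def test_x_shape_rejected_as_branched(self):
        m = np.zeros((120, 120), dtype=bool)
        for i in range(100):
            m[10 + i, 10 + i] = True
            m[10 + i, 109 - i] = True
        from scipy import ndimage as ndi

        m = ndi.binary_dilation(m, iterations=4)
        result = skeletonize_region(region_from_mask(m))
        assert isinstance(result, Rejection)
        assert result.reason == "branched"

    def test_tiny_blob_degenerate(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 4] = True
        result = skeletonize_region(region_from_mask(m))
        assert isinstance(result, Rejection)
        assert result.reason == "degenerate"

    def test_generator_worm_arc_length_close_to_truth(self):
        mask, truth = synth.make_worm(synth.default_specs()["hermaphrodite"], 7)
        skel = skeletonize_region(region_from_mask(mask))
        assert isinstance(skel, MidlineSkeleton)
        assert measure_length(skel) == pytest.approx(truth.length_um, rel=0.05)

    def test_path_ordered_from_smaller_endpoint(self):
        skel = skeletonize_region(rectangle_region(100, 8))
        assert tuple(skel.points[0]) < tuple(skel.points[-1])

    def test_malformed_region_raises(self):
        with pytest.raises(InvalidParameterError):
            skeletonize_region(region_from_mask(np.zeros((5, 5), dtype=bool)))


class TestLengthThickness:
    def test_horizontal_line_length(self):
        skel = make_line_skeleton([(0, c) for c in range(101)])
        assert measure_length(skel, 6.5) == pytest.approx(650.0)

    def test_diagonal_line_length(self):
        skel = make_line_skeleton([(i, i) for i in range(101)])
        assert measure_length(skel, 6.5) == pytest.approx(100 * np.sqrt(2) * 6.5)

    @pytest.mark.parametrize("upp,expected", [(6.5, 65.0), (7.0, 70.0)])
    def test_thickness_formula(self, upp, expected):
        skel = make_line_skeleton([(0, c) for c in range(201)], upp)
        region = WormRegion(
            mask=np.ones((1, 1), dtype=bool),
            bbox=(0, 0, 1, 1),
            area_px=2000,
            touches_border=False,
            um_per_pixel=upp,
        )
        assert measure_thickness(region, skel, upp) == pytest.approx(expected)

    def test_scaling_linear_in_calibration(self):
        region = rectangle_region(150, 9, um_per_pixel=6.0)
        skel = skeletonize_region(region)
        assert measure_length(skel, 12.0) == pytest.approx(2 * measure_length(skel, 6.0))
        assert measure_thickness(region, skel, 12.0) == pytest.approx(
            2 * measure_thickness(region, skel, 6.0)
        )

    def test_constant_width_generator_worm_thickness(self):
        spec = synth.WormSpec(
            "hermaphrodite",
            length_um_range=(900.0, 900.0),
            body_halfwidth_um_range=(26.0, 26.0),
            tail_a_frac=(1.0, 1.0),
            tail_b_frac=(1.0, 1.0),
        )
        mask, truth = synth.make_worm(spec, 3)
        region = region_from_mask(mask)
        skel = skeletonize_region(region)
        assert measure_thickness(region, skel) == pytest.approx(52.0, rel=0.15)


class TestDiameters:
    def test_rectangle_constant_diameter(self):
        region = rectangle_region(200, 11)
        skel = skeletonize_region(region)
        for s in (150.0, 400.0, 650.0):
            d = diameter_at(region, skel, s, "A")
            assert abs(d - 11 * 6.5) <= 6.5 + 1e-9  # +/- 1 px quantization

    def test_thin_line_diameter(self):
        region = rectangle_region(200, 2)
        skel = skeletonize_region(region, TailProbeConfig(spur_prune_um=20.0))
        d = diameter_at(region, skel, 300.0, "A")
        assert abs(d - 2 * 6.5) <= 6.5

    def test_out_of_range_arc_position(self):
        region = rectangle_region(100, 8)
        skel = skeletonize_region(region)
        with pytest.raises(ValueError):
            diameter_at(region, skel, 1e6, "A")

    def test_cone_taper_probes_match_spec(self):
        region = cone_region(d_at_20=14.0, d_at_120=42.0)
        skel = skeletonize_region(region)
        assert isinstance(skel, MidlineSkeleton)
        d20 = diameter_at(region, skel, 20.0, "A")
        d120 = diameter_at(region, skel, 120.0, "A")
        assert abs(d20 - 14.0) <= 6.5 + 1e-9
        assert abs(d120 - 42.0) <= 6.5 + 1e-9


class TestTailRatios:
    def test_rectangle_ratios_are_one(self):
        region = rectangle_region(200, 11)
        skel = skeletonize_region(region)
        r1, r2 = tail_ratios(region, skel)
        assert r1 == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_short_object_rejected(self):
        region = rectangle_region(30, 6)
        skel = skeletonize_region(region, TailProbeConfig(spur_prune_um=20.0))
        result = tail_ratios(region, skel)
        assert isinstance(result, Rejection)
        assert result.reason == "too_short"

    def test_male_blunter_than_hermaphrodite_in_paired_draws(self):
        specs = synth.default_specs()
        wins = 0
        n = 100
        for seed in range(n):
            r2s = {}
            for lab in ("hermaphrodite", "male"):
                mask, _ = synth.make_worm(specs[lab], 10_000 + seed)
                feats = extract_features(region_from_mask(mask))
                r2s[lab] = feats.r2
            wins += r2s["male"] > r2s["hermaphrodite"]
        assert wins >= 0.9 * n

    def test_probe_config_validation(self):
        with pytest.raises(InvalidParameterError):
            TailProbeConfig(x1_um=120.0, x2_um=20.0)


class TestExtractFeatures:
    def test_rectangle_features(self):
        feats = extract_features(rectangle_region(200, 10))
        # endpoint extension recovers the thinning erosion: midline truth is L px
        assert feats.length_um == pytest.approx(200 * 6.5, rel=0.05)
        assert feats.thickness_um == pytest.approx(65.0, rel=0.1)
        assert feats.r1 == pytest.approx(1.0, abs=0.15)
        assert feats.r2 == pytest.approx(1.0, abs=0.15)

    def test_rejections_propagate_with_region_id(self):
        m = np.zeros((40, 40), dtype=bool)
        m[18:22, 5:35] = True  # ~195 um long: shorter than 2 * X2
        region = region_from_mask(m, region_id=17)
        result = extract_features(region)
        assert isinstance(result, Rejection)
        assert result.reason == "too_short"
        assert result.region_id == 17

    @pytest.mark.parametrize("seed", [21, 22, 23, 24])
    def test_rotation_robustness(self, seed):
        """90-degree rotation: size features stable to ~2%, ratios to the
        +/-1 px diameter quantization (large relative at D(X1) ~ 2 px)."""
        mask, _ = synth.make_worm(synth.default_specs()["male"], seed)
        f0 = extract_features(region_from_mask(mask))
        f90 = extract_features(region_from_mask(np.rot90(mask).copy()))
        assert f90.length_um == pytest.approx(f0.length_um, rel=0.025)
        assert f90.thickness_um == pytest.approx(f0.thickness_um, rel=0.025)
        assert f90.r1 == pytest.approx(f0.r1, abs=0.25)
        assert f90.r2 == pytest.approx(f0.r2, abs=0.25)


def test_r1_never_exceeds_r2_and_length_tracks_truth_across_seeds():
    specs = synth.default_specs()
    rng_seeds = range(40)
    for seed in rng_seeds:
        lab = ("hermaphrodite", "male", "larva")[seed % 3]
        mask, truth = synth.make_worm(specs[lab], 500 + seed)
        feats = extract_features(region_from_mask(mask))
        if isinstance(feats, Rejection):
            continue
        assert feats.r1 <= feats.r2
        assert feats.length_um == pytest.approx(truth.length_um, rel=0.05)
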