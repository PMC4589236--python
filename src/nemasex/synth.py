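"""Seeded synthetic plate-image generator with per-animal ground truth.

Renders brightfield-like plate scans of *C. elegans*: dark, elongated,
smoothly curved animals on a bright background, with class-specific
size and tail-taper profiles, plus the confounders a real scan shows —
eggs, debris specks, uneven illumination, sensor noise, and crowding.
Every animal carries a truth record (midline polyline, length, expected
probe diameters, exact rendered mask), so each pipeline stage can be
tested against known geometry without a microscope.

A worm is modelled as a curvature-bounded random midline with a
half-width profile along arc length: constant in the body, tapering at
each end through target diameters at the two probe positions (20 and
120 um from the tip). Hermaphrodites are the largest with two sharply
tapered ends; males are smaller with one blunt end (the male tail);
larvae are short and thin. Rasterization stamps discs along the
midline, so the mask truth is exact and aliasing-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .segmentation import GrayscaleImage

DEFAULT_UM_PER_PIXEL = 6.5


class GenerationError(RuntimeError):
    """The requested geometry cannot be rendered (canvas too small, no layout)."""


@dataclass(frozen=True)
class TailProfile:
    """Target body diameters (um) at 20 and 120 um of arc from one end."""

    d_x1_um: float
    d_x2_um: float


@dataclass(frozen=True)
class WormSpec:
    """Morphology recipe for one worm class.

    ``tail_a`` / ``tail_b`` give the taper targets for the two ends as
    fractions of the sampled body diameter; ``curvature_per_um`` bounds
    the midline bend rate (rad/um). ``intensity_contrast`` is the
    fractional darkening of the worm relative to the background.
    """

    class_label: str
    length_um_range: tuple[float, float]
    body_halfwidth_um_range: tuple[float, float]
    tail_a_frac: tuple[float, float]  # (D(20), D(120)) as fractions of body diameter
    tail_b_frac: tuple[float, float]
    curvature_per_um: float = 0.004
    intensity_contrast: float = 0.35

    def __post_init__(self):
        lo, hi = self.length_um_range
        if not (0 < lo <= hi):
            raise GenerationError("length range must be positive and ordered")
        lo, hi = self.body_halfwidth_um_range
        if not (0 < lo <= hi):
            raise GenerationError("halfwidth range must be positive and ordered")


def default_specs() -> dict[str, WormSpec]:
    """Class recipes reproducing the qualitative adult/male/larva ordering.

    Hermaphrodites: long and thick, both ends sharply tapered
    (D(20)/D(120) ~ 0.33, e.g. 14/42 um at a 70 um body). Males: shorter
    and thinner with one blunt tail (ratio ~ 0.62). Larvae: short, thin,
    mildly tapered. These are engineering choices for a plausible adult
    plate, not literature measurements.
    """
    return {
        "hermaphrodite": WormSpec(
            "hermaphrodite",
            length_um_range=(900.0, 1200.0),
            body_halfwidth_um_range=(30.0, 40.0),
            tail_a_frac=(0.20, 0.60),
            tail_b_frac=(0.20, 0.60),
        ),
        "male": WormSpec(
            "male",
            length_um_range=(700.0, 900.0),
            body_halfwidth_um_range=(22.0, 30.0),
            tail_a_frac=(0.55, 0.88),  # blunt male tail
            tail_b_frac=(0.22, 0.62),
            intensity_contrast=0.33,
        ),
        "larva": WormSpec(
            "larva",
            length_um_range=(280.0, 600.0),
            body_halfwidth_um_range=(10.0, 20.0),
            tail_a_frac=(0.40, 0.90),
            tail_b_frac=(0.40, 0.90),
            curvature_per_um=0.006,
            intensity_contrast=0.30,
        ),
    }


def validate_spec_set(specs: dict[str, WormSpec]) -> None:
    """Male blunt-end taper ratio must exceed the hermaphrodite's."""
    if "male" in specs and "hermaphrodite" in specs:
        male = specs["male"]
        herm = specs["hermaphrodite"]
        male_blunt = max(
            male.tail_a_frac[0] / male.tail_a_frac[1],
            male.tail_b_frac[0] / male.tail_b_frac[1],
        )
        herm_max = max(
            herm.tail_a_frac[0] / herm.tail_a_frac[1],
            herm.tail_b_frac[0] / herm.tail_b_frac[1],
        )
        if not male_blunt > herm_max:
            raise GenerationError(
                "male blunt-end D(X1)/D(X2) must exceed the hermaphrodite ratio"
            )


@dataclass
class AnimalTruth:
    animal_id: int
    class_label: str
    midline_um: np.ndarray  # (n, 2) midline polyline in um (row, col)
    length_um: float
    body_halfwidth_um: float
    d_probe_um: dict  # {"A": (D(20), D(120)), "B": (...)}
    bbox: tuple[int, int, int, int]  # (row0, col0, h, w) of local mask in the plate
    mask: np.ndarray  # local boolean raster

    def to_jsonable(self) -> dict:
        d = {
            "animal_id": self.animal_id,
            "class_label": self.class_label,
            "midline_um": self.midline_um.tolist(),
            "length_um": self.length_um,
            "body_halfwidth_um": self.body_halfwidth_um,
            "d_probe_um": {k: list(v) for k, v in self.d_probe_um.items()},
            "bbox": list(self.bbox),
        }
        return d


@dataclass
class PlateTruth:
    animals: list[AnimalTruth]
    image_shape: tuple[int, int]
    um_per_pixel: float
    seed: int
    noise_sigma: float
    illumination_gradient: float
    label_image: np.ndarray  # uint16, 0 background, animal_id elsewhere

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.animals:
            out[a.class_label] = out.get(a.class_label, 0) + 1
        return out

    def male_percentage(self) -> float | None:
        c = self.counts()
        males, herms = c.get("male", 0), c.get("hermaphrodite", 0)
        if males + herms == 0:
            return None
        return 100.0 * males / (males + herms)

    def write_json(self, path: str | Path) -> None:
        doc = {
            "image_shape": list(self.image_shape),
            "um_per_pixel": self.um_per_pixel,
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "illumination_gradient": self.illumination_gradient,
            "animals": [a.to_jsonable() for a in self.animals],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# single-worm construction


def _midline(rng: np.random.Generator, length_um: float, kappa: float) -> np.ndarray:
    """Curvature-bounded random midline polyline in um, starting at origin."""
    ds = 3.0
    n = max(int(round(length_um / ds)), 2)
    theta = rng.uniform(0, 2 * np.pi)
    # persistent random turning, clipped to the curvature bound
    turns = np.clip(rng.normal(0.0, 0.6 * kappa * ds, n - 1), -kappa * ds, kappa * ds)
    # smooth the turn sequence so bends are gradual, re-clip to the bound
    turns = np.clip(ndi.uniform_filter1d(turns, size=7, mode="nearest"),
                    -kappa * ds, kappa * ds)
    headings = theta + np.concatenate([[0.0], np.cumsum(turns)])
    steps = np.stack([np.sin(headings), np.cos(headings)], axis=1) * ds
    pts = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
    # rescale so the polyline arc length equals length_um exactly
    arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    return pts * (length_um / arc)


def _halfwidth_profile(
    s: np.ndarray, length_um: float, hb: float, tail_a: TailProfile, tail_b: TailProfile
) -> np.ndarray:
    """Half-width at arc positions ``s``: body plateau with per-end tapers."""

    def from_end(dist, prof):
        taper_end = 120.0 + max(hb - prof.d_x2_um / 2.0, 0.0) * 4.0 + 40.0
        # the very tip comes to a point (<= 5 um half-width) regardless of
        # how blunt the 20 um probe position is, as real tails do; this also
        # keeps the rendered mask from extending far past the midline end
        xp = [0.0, 20.0, 120.0, taper_end]
        fp = [min(0.40 * prof.d_x1_um, 5.0), prof.d_x1_um / 2.0, prof.d_x2_um / 2.0, hb]
        return np.interp(dist, xp, fp)

    h = np.minimum(from_end(s, tail_a), from_end(length_um - s, tail_b))
    return np.minimum(h, hb)


def make_worm(
    spec: WormSpec, rng_seed: int | np.random.Generator, um_per_pixel: float = DEFAULT_UM_PER_PIXEL
) -> tuple[np.ndarray, AnimalTruth]:
    """Render one worm on a tight local canvas; deterministic per seed.

    Returns the boolean mask raster and the truth record (bbox is local,
    origin (0, 0); ``render_plate`` rewrites it on placement).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    length = rng.uniform(*spec.length_um_range)
    hb = rng.uniform(*spec.body_halfwidth_um_range)
    body_d = 2.0 * hb
    tail_a = TailProfile(spec.tail_a_frac[0] * body_d, spec.tail_a_frac[1] * body_d)
    tail_b = TailProfile(spec.tail_b_frac[0] * body_d, spec.tail_b_frac[1] * body_d)
    mid = _midline(rng, length, spec.curvature_per_um)
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    halfw = _halfwidth_profile(s, length, hb, tail_a, tail_b)

    pad = (halfw.max() / um_per_pixel) + 3
    mid_px = mid / um_per_pixel
    origin = mid_px.min(axis=0) - pad
    mid_px = mid_px - origin
    shape = tuple(np.ceil(mid_px.max(axis=0) + pad + 1).astype(int))
    if min(shape) < 3:
        raise GenerationError("worm spec degenerate at this calibration")
    mask = np.zeros(shape, dtype=bool)
    _stamp_discs(mask, mid_px, halfw / um_per_pixel)

    truth = AnimalTruth(
        animal_id=0,
        class_label=spec.class_label,
        midline_um=mid_px * um_per_pixel,  # aligned with the local mask raster
        length_um=float(length),
        body_halfwidth_um=float(hb),
        d_probe_um={
            "A": (tail_a.d_x1_um, tail_a.d_x2_um),
            "B": (tail_b.d_x1_um, tail_b.d_x2_um),
        },
        bbox=(0, 0, shape[0], shape[1]),
        mask=mask,
    )
    return mask, truth


def _stamp_discs(mask: np.ndarray, centers_px: np.ndarray, radii_px: np.ndarray) -> None:
    """Stamp filled discs along a polyline, interpolating to ~0.7 px spacing."""
    seg = np.linalg.norm(np.diff(centers_px, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / 0.7)), 2)
    si = np.linspace(0.0, total, n)
    rows = np.interp(si, s, centers_px[:, 0])
    cols = np.interp(si, s, centers_px[:, 1])
    rads = np.interp(si, s, radii_px)
    H, W = mask.shape
    for r, c, rad in zip(rows, cols, rads):
        rad = max(rad, 0.6)
        r0, r1 = max(int(np.floor(r - rad)), 0), min(int(np.ceil(r + rad)) + 1, H)
        c0, c1 = max(int(np.floor(c - rad)), 0), min(int(np.ceil(c + rad)) + 1, W)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2


def _stamp_ellipse(mask, center, axes_px, angle, value=True):
    r, c = center
    a, b = axes_px
    rad = max(a, b)
    H, W = mask.shape
    r0, r1 = max(int(r - rad - 1), 0), min(int(r + rad + 2), H)
    c0, c1 = max(int(c - rad - 1), 0), min(int(c + rad + 2), W)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - r, xx - c
    u = dy * np.cos(angle) + dx * np.sin(angle)
    v = -dy * np.sin(angle) + dx * np.cos(angle)
    mask[r0:r1, c0:c1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# plate assembly


def render_plate(
    counts: dict[str, int],
    specs: dict[str, WormSpec] | None = None,
    layout: str = "spaced",
    noise_sigma: float = 0.0,
    illumination_gradient: float = 0.0,
    eggs: int = 0,
    eggs_at_tails: bool = False,
    debris: int = 0,
    seed: int = 0,
    image_shape: tuple[int, int] = (1200, 1200),
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL,
    max_placement_tries: int = 400,
) -> tuple[GrayscaleImage, PlateTruth]:
    """Render a full plate image plus its truth record; deterministic per seed.

    ``layout="spaced"`` guarantees at least three worm-widths of
    clearance between animals by rejection sampling; ``"crowded"``
    drops animals uniformly and lets them overlap. Eggs are small
    ellipses (below the region-filter area bound), optionally glued to
    a hermaphrodite body end to emulate the egg-touching failure mode;
    debris are few-pixel specks. The background is bright field with an
    optional linear illumination ramp and Gaussian sensor noise.
    """
    if layout not in ("spaced", "crowded"):
        raise ValueError("layout must be 'spaced' or 'crowded'")
    if specs is None:
        specs = default_specs()
    validate_spec_set({k: v for k, v in specs.items() if k in counts and counts[k] > 0})
    rng = np.random.default_rng(seed)
    H, W = image_shape
    label_img = np.zeros((H, W), dtype=np.uint16)
    contrast = np.zeros((H, W), dtype=np.float64)

    max_hw_um = max(
        (specs[k].body_halfwidth_um_range[1] for k in counts if counts.get(k, 0) > 0),
        default=40.0,
    )
    clearance_px = 3.0 * (2.0 * max_hw_um / um_per_pixel)

    order = [lab for lab in ("hermaphrodite", "male", "larva") if counts.get(lab, 0) > 0
             for _ in range(counts[lab])]
    rng.shuffle(order)

    animals: list[AnimalTruth] = []
    animal_id = 0
    for lab in order:
        mask, truth = make_worm(specs[lab], rng, um_per_pixel)
        h, w = mask.shape
        if h >= H or w >= W:
            raise GenerationError("canvas too small for the worm spec")
        placed = False
        for _ in range(max_placement_tries):
            r0 = int(rng.integers(1, H - h - 1))
            c0 = int(rng.integers(1, W - w - 1))
            if layout == "spaced":
                if not _clear(label_img, mask, r0, c0, clearance_px):
                    continue
            else:
                # crowded animals may touch and cross, but two bodies cannot
                # coincide: cap the overlapped fraction of the new body
                window = label_img[r0 : r0 + h, c0 : c0 + w] > 0
                if (window & mask).sum() > 0.15 * mask.sum():
                    continue
            placed = True
            break
        if not placed:
            if layout == "spaced":
                raise GenerationError(
                    f"could not place animal {animal_id} with required clearance"
                )
            r0 = int(rng.integers(1, H - h - 1))
            c0 = int(rng.integers(1, W - w - 1))
        animal_id += 1
        win = (slice(r0, r0 + h), slice(c0, c0 + w))
        label_img[win][mask] = animal_id
        contrast[win][mask] = np.maximum(
            contrast[win][mask], specs[lab].intensity_contrast
        )
        truth.animal_id = animal_id
        truth.bbox = (r0, c0, h, w)
        animals.append(truth)

    _scatter_eggs(rng, contrast, animals, eggs, eggs_at_tails, um_per_pixel, (H, W))
    for _ in range(debris):
        r = rng.uniform(0, H - 1)
        c = rng.uniform(0, W - 1)
        rad = rng.uniform(4.0, 12.0) / um_per_pixel
        _stamp_ellipse_contrast(contrast, (r, c), (max(rad, 0.8),) * 2, 0.0, 0.30)

    background = 0.82
    img = background * (1.0 - contrast)
    if illumination_gradient:
        ramp = 1.0 + illumination_gradient * np.linspace(-1.0, 1.0, W)[None, :]
        img = img * ramp
    if noise_sigma:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img8 = np.clip(img * 255.0, 0, 255).astype(np.uint8)

    truth = PlateTruth(
        animals=animals,
        image_shape=(H, W),
        um_per_pixel=um_per_pixel,
        seed=seed,
        noise_sigma=noise_sigma,
        illumination_gradient=illumination_gradient,
        label_image=label_img,
    )
    return GrayscaleImage(img8, um_per_pixel), truth


def _clear(label_img, mask, r0, c0, clearance_px) -> bool:
    """True when no already-placed pixel lies within clearance of the candidate."""
    pad = int(np.ceil(clearance_px))
    h, w = mask.shape
    H, W = label_img.shape
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r0 + h + pad, H), min(c0 + w + pad, W)
    window = label_img[rr0:rr1, cc0:cc1] > 0
    if not window.any():
        return True
    dist = ndi.distance_transform_edt(~window)
    sub = dist[r0 - rr0 : r0 - rr0 + h, c0 - cc0 : c0 - cc0 + w]
    return bool(sub[mask].min() > clearance_px)


def _stamp_ellipse_contrast(contrast, center, axes_px, angle, value):
    m = np.zeros(contrast.shape, dtype=bool)
    _stamp_ellipse(m, center, axes_px, angle)
    contrast[m] = np.maximum(contrast[m], value)


def _scatter_eggs(rng, contrast, animals, eggs, eggs_at_tails, um_per_pixel, shape):
    if eggs <= 0:
        return
    H, W = shape
    herms = [a for a in animals if a.class_label == "hermaphrodite"]
    for i in range(eggs):
        a_um = rng.uniform(22.0, 28.0) / um_per_pixel  # semi-axes of a ~50x30 um egg
        b_um = rng.uniform(13.0, 17.0) / um_per_pixel
        angle = rng.uniform(0, np.pi)
        if eggs_at_tails and herms:
            worm = herms[int(rng.integers(len(herms)))]
            end = worm.midline_um[0] if rng.random() < 0.5 else worm.midline_um[-1]
            r = worm.bbox[0] + end[0] / um_per_pixel
            c = worm.bbox[1] + end[1] / um_per_pixel
            # centre the egg just past the body tip so the two masks touch
            jitter = rng.normal(0, 1.0, 2)
            r, c = r + jitter[0], c + jitter[1]
        else:
            r, c = rng.uniform(0, H - 1), rng.uniform(0, W - 1)
        _stamp_ellipse_contrast(contrast, (r, c), (a_um, b_um), angle, 0.32)


# ---------------------------------------------------------------------------
# labelled feature generation (training fixtures, recall experiments)


def generate_training_records(
    n_per_class: dict[str, int] | None = None,
    seed: int = 0,
    specs: dict[str, WormSpec] | None = None,
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL,
):
    """Measured features for individually rendered worms of known class.

    Renders one worm at a time and runs the full metrology on its exact
    mask; worms rejected by the metrology (rare short larvae) are
    redrawn, so the output has exactly the requested class counts.
    Default counts mirror a standard labelled training set of
    46 hermaphrodites, 46 males and 39 larvae.
    """
    from .classifier import TrainingRecord
    from .morphometry import Rejection, extract_features
    from .segmentation import WormRegion

    if n_per_class is None:
        n_per_class = {"hermaphrodite": 46, "male": 46, "larva": 39}
    if specs is None:
        specs = default_specs()
    rng = np.random.default_rng(seed)
    records = []
    for lab, n in n_per_class.items():
        got = 0
        attempts = 0
        while got < n:
            attempts += 1
            if attempts > 50 * max(n, 1):
                raise GenerationError(f"cannot generate measurable {lab} worms")
            mask, _truth = make_worm(specs[lab], rng, um_per_pixel)
            region = WormRegion(
                mask=mask,
                bbox=(0, 0, *mask.shape),
                area_px=int(mask.sum()),
                touches_border=False,
                um_per_pixel=um_per_pixel,
            )
            feats = extract_features(region)
            if isinstance(feats, Rejection):
                continue
            records.append(TrainingRecord(lab, feats))
            got += 1
    return records
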