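import numpy as np
import pytest

from nemasex.classifier import (
    CLASS_LABELS,
    ClassModel,
    TrainingError,
    TrainingRecord,
    classify,
    fit_training,
    load_model,
    mahalanobis_distance,
    save_model,
)
from nemasex.morphometry import ShapeFeatures


def feat(L, T, r1, r2):
    return ShapeFeatures(L, T, r1, r2)


def records_for(label, rows):
    return [TrainingRecord(label, feat(*r)) for r in rows]


def three_class_records(herm_rows, male_rows, larva_rows):
    return (
        records_for("hermaphrodite", herm_rows)
        + records_for("male", male_rows)
        + records_for("larva", larva_rows)
    )


BASE_HERM = [(1000 + 10 * i, 55 + i, 0.30 + 0.01 * i, 0.40 + 0.01 * i) for i in range(6)]
BASE_MALE = [(800 + 10 * i, 41 + i, 0.40 + 0.01 * i, 0.65 + 0.01 * i) for i in range(6)]
BASE_LARVA = [(430 + 10 * i, 21 + i, 0.45 + 0.01 * i, 0.55 + 0.01 * i) for i in range(6)]


class TestFitTraining:
    def test_mean_and_unbiased_covariance_match_hand_computation(self):
        model = fit_training(three_class_records(BASE_HERM, BASE_MALE, BASE_LARVA))
        X = np.array(BASE_HERM, dtype=float)
        mean = X.sum(axis=0) / len(X)
        dev = X - mean
        cov = sum(np.outer(d, d) for d in dev) / (len(X) - 1)  # explicit summation
        cm = model.classes["hermaphrodite"]
        assert np.allclose(cm.mean, mean)
        assert np.allclose(cm.covariance, cov)
        assert cm.n == 6

    def test_identical_records_get_ridge_and_zero_self_distance(self):
        herm = [(1000.0, 55.0, 0.3, 0.4)] * 6  # singular covariance
        model = fit_training(three_class_records(herm, BASE_MALE, BASE_LARVA))
        cm = model.classes["hermaphrodite"]
        assert cm.ridge > 0
        assert mahalanobis_distance(np.array(herm[0]), cm) == pytest.approx(0.0, abs=1e-8)

    def test_missing_class_named_in_error(self):
        with pytest.raises(TrainingError, match="larva"):
            fit_training(records_for("hermaphrodite", BASE_HERM) + records_for("male", BASE_MALE))

    def test_too_few_records_rejected(self):
        with pytest.raises(TrainingError, match="male"):
            fit_training(three_class_records(BASE_HERM, BASE_MALE[:3], BASE_LARVA))

    def test_order_independence(self):
        recs = three_class_records(BASE_HERM, BASE_MALE, BASE_LARVA)
        m1 = fit_training(recs)
        m2 = fit_training(list(reversed(recs)))
        for lab in CLASS_LABELS:
            assert np.array_equal(m1.classes[lab].mean, m2.classes[lab].mean)
            assert np.array_equal(m1.classes[lab].covariance, m2.classes[lab].covariance)

    def test_shipped_table_class_counts(self, shipped_model):
        assert shipped_model.class_counts == {
            "hermaphrodite": 46,
            "male": 46,
            "larva": 39,
        }

    def test_model_roundtrip(self, tmp_path, shipped_model):
        path = tmp_path / "model.json"
        save_model(shipped_model, path)
        loaded = load_model(path)
        for lab in CLASS_LABELS:
            assert np.allclose(loaded.classes[lab].mean, shipped_model.classes[lab].mean)
            assert np.allclose(
                loaded.classes[lab].covariance, shipped_model.classes[lab].covariance
            )


class TestMahalanobisDistance:
    def test_zero_at_class_mean(self, shipped_model):
        for lab in CLASS_LABELS:
            cm = shipped_model.classes[lab]
            assert mahalanobis_distance(cm.mean, cm) == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_reduces_to_euclidean(self):
        cm = ClassModel("male", np.zeros(4), np.eye(4), 10, 0.0)
        x = np.array([1.0, 2.0, 2.0, 4.0])
        assert mahalanobis_distance(x, cm) == pytest.approx(5.0)

    def test_two_dimensional_hand_example(self):
        # mu=(0,0), Sigma=diag(4,1), x=(2,1): sqrt(4/4 + 1/1) = sqrt(2)
        cm = ClassModel("male", np.zeros(2), np.diag([4.0, 1.0]), 10, 0.0)
        assert mahalanobis_distance(np.array([2.0, 1.0]), cm) == pytest.approx(np.sqrt(2))

    def test_non_finite_input_rejected(self, shipped_model):
        with pytest.raises(ValueError):
            mahalanobis_distance(
                np.array([np.nan, 1, 1, 1]), shipped_model.classes["male"]
            )

    def test_matches_brute_force_quadratic_form_on_random_spd(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            dim = int(rng.integers(2, 6))
            A = rng.normal(size=(dim, dim))
            cov = A @ A.T + 1e-3 * np.eye(dim)
            mu = rng.normal(size=dim)
            x = rng.normal(size=dim)
            cm = ClassModel("male", mu, cov, 10, 0.0)
            inv = np.linalg.inv(cov)
            d = x - mu
            brute = np.sqrt(sum(d[i] * inv[i, j] * d[j] for i in range(dim) for j in range(dim)))
            assert mahalanobis_distance(x, cm) == pytest.approx(brute, rel=1e-10)


class TestClassify:
    def test_class_mean_assigned_to_its_class(self, shipped_model):
        for lab in CLASS_LABELS:
            res = classify(shipped_model.classes[lab].mean, shipped_model)
            assert res.label == lab
            assert res.distances[lab] == pytest.approx(0.0, abs=1e-10)

    def test_tie_broken_by_fixed_order_and_flagged(self):
        # two classes mirrored around x, equidistant from it
        herm = [(900.0 + i, 50.0, 0.3, 0.4) for i in (-2, -1, 0, 1, 2, 3)]
        male = [(1100.0 + i, 50.0, 0.3, 0.4) for i in (-2, -1, 0, 1, 2, 3)]
        model = fit_training(three_class_records(herm, male, BASE_LARVA))
        x = 0.5 * (model.classes["hermaphrodite"].mean + model.classes["male"].mean)
        res = classify(x, model)
        assert res.tie
        assert res.margin == pytest.approx(0.0)
        assert res.label == "hermaphrodite"  # fixed tie order

    def test_margin_is_gap_between_two_closest(self, shipped_model):
        res = classify(np.array([900.0, 50.0, 0.35, 0.5]), shipped_model)
        ds = sorted(res.distances.values())
        assert res.margin == pytest.approx(ds[1] - ds[0])

    def test_agrees_with_independent_argmin_oracle(self, shipped_model):
        rng = np.random.default_rng(7)
        hits = 0
        n = 100
        labels = list(CLASS_LABELS)
        for _ in range(n):
            lab = labels[int(rng.integers(3))]
            cm = shipped_model.classes[lab]
            x = rng.multivariate_normal(cm.mean, cm.covariance)
            # independent oracle: explicit inverse + quadratic form argmin
            dists = {}
            for lab2 in labels:
                c2 = shipped_model.classes[lab2]
                inv = np.linalg.inv(c2.regularized_covariance())
                d = x - c2.mean
                dists[lab2] = float(np.sqrt(d @ inv @ d))
            oracle = min(labels, key=lambda k: dists[k])
            hits += classify(x, shipped_model).label == oracle
        assert hits >= 0.95 * n

    def test_invariant_under_common_rescaling(self):
        rng0 = np.random.default_rng(11)

        def jittered(rows):
            return [tuple(np.array(r) * (1 + 0.03 * rng0.normal(size=4))) for r in rows]

        recs = three_class_records(
            jittered(BASE_HERM), jittered(BASE_MALE), jittered(BASE_LARVA)
        )
        model = fit_training(recs)
        scale = np.array([2.0, 0.5, 10.0, 10.0])
        scaled = [
            TrainingRecord(r.label, ShapeFeatures(*(r.features.as_vector() * scale)))
            for r in recs
        ]
        model_s = fit_training(scaled)
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = np.array(
                [rng.uniform(400, 1100), rng.uniform(20, 60), rng.uniform(0.2, 0.6), rng.uniform(0.3, 0.8)]
            )
            assert classify(x, model).label == classify(x * scale, model_s).label
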