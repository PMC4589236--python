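"""Nearest-class Mahalanobis assignment of worms to hermaphrodite / male / larva.

Each class is summarised by the sample mean and unbiased covariance of
its training features (length, thickness, r1, r2). An unknown worm is
assigned to the class whose Mahalanobis distance

    d(x, k) = sqrt((x - mu_k)^T (Sigma_k + ridge_k I)^-1 (x - mu_k))

is smallest. Covariances estimated from a few dozen worms can be
near-singular (r1 and r2 are correlated and bounded), so a small ridge
is added to the diagonal only when the condition number exceeds a
bound, using the smallest value from a doubling schedule that restores
conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import FEATURE_ORDER, ShapeFeatures

CLASS_LABELS = ("hermaphrodite", "male", "larva")

MODEL_SCHEMA_VERSION = 1

#: condition-number bound above which ridge regularization kicks in
DEFAULT_COND_BOUND = 1e8


class TrainingError(ValueError):
    """The training set violates the class/record requirements."""


@dataclass(frozen=True)
class TrainingRecord:
    label: str
    features: ShapeFeatures

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise TrainingError(f"unknown class label {self.label!r}")


@dataclass(frozen=True)
class ClassModel:
    label: str
    mean: np.ndarray
    covariance: np.ndarray
    n: int
    ridge: float = 0.0

    def regularized_covariance(self) -> np.ndarray:
        return self.covariance + self.ridge * np.eye(len(self.mean))


@dataclass(frozen=True)
class TrainingModel:
    classes: dict[str, ClassModel]
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self):
        if set(self.classes) != set(CLASS_LABELS):
            raise TrainingError(f"model must contain exactly the classes {CLASS_LABELS}")

    @property
    def class_counts(self) -> dict[str, int]:
        return {k: cm.n for k, cm in self.classes.items()}


@dataclass(frozen=True)
class Classification:
    label: str
    distances: dict[str, float]
    margin: float
    tie: bool = False


def _choose_ridge(cov: np.ndarray, cond_bound: float) -> float:
    """Smallest ridge from a doubling schedule bringing cond below the bound."""
    if np.linalg.cond(cov) <= cond_bound:
        return 0.0
    scale = float(np.trace(cov)) / len(cov)
    ridge = max(scale, 1.0) * 1e-12
    eye = np.eye(len(cov))
    while np.linalg.cond(cov + ridge * eye) > cond_bound:
        ridge *= 2.0
    return ridge


def fit_training(
    records: list[TrainingRecord], cond_bound: float = DEFAULT_COND_BOUND
) -> TrainingModel:
    """Per-class mean and unbiased covariance over the fixed feature order.

    Requires all three classes with at least 5 records each. Records are
    sorted (by label, then feature values) before fitting so the result
    does not depend on input order.
    """
    for i, rec in enumerate(records):
        if not np.all(np.isfinite(rec.features.as_vector())):
            raise TrainingError(f"non-finite features in record {i}")
    recs = sorted(records, key=lambda r: (r.label, tuple(r.features.as_vector())))
    classes = {}
    for lab in CLASS_LABELS:
        X = np.array([r.features.as_vector() for r in recs if r.label == lab])
        if len(X) < 5:
            raise TrainingError(
                f"class {lab!r} has {len(X)} records; at least 5 are required"
            )
        cov = np.cov(X, rowvar=False, ddof=1)
        ridge = _choose_ridge(cov, cond_bound)
        classes[lab] = ClassModel(lab, X.mean(axis=0), cov, len(X), ridge)
    return TrainingModel(classes)


def mahalanobis_distance(x: ShapeFeatures | np.ndarray, cm: ClassModel) -> float:
    """sqrt((x-mu)^T (Sigma + ridge I)^-1 (x-mu)), via a linear solve."""
    v = x.as_vector() if isinstance(x, ShapeFeatures) else np.asarray(x, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite feature vector")
    d = v - cm.mean
    q = float(d @ np.linalg.solve(cm.regularized_covariance(), d))
    return float(np.sqrt(max(q, 0.0)))


def classify(x: ShapeFeatures | np.ndarray, model: TrainingModel) -> Classification:
    """Assign to the class with the shortest Mahalanobis distance.

    Exact distance ties are broken by the fixed order
    hermaphrodite > male > larva and flagged in the result.
    """
    dists = {lab: mahalanobis_distance(x, model.classes[lab]) for lab in CLASS_LABELS}
    best = min(CLASS_LABELS, key=lambda lab: dists[lab])
    ordered = sorted(dists.values())
    tie = sum(1 for v in dists.values() if v == dists[best]) > 1
    return Classification(
        label=best,
        distances=dists,
        margin=float(ordered[1] - ordered[0]),
        tie=tie,
    )


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: TrainingModel) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_order": list(model.feature_order),
        "units": "um",
        "classes": {
            lab: {
                "n": cm.n,
                "mean": cm.mean.tolist(),
                "covariance": cm.covariance.tolist(),
                "ridge": cm.ridge,
            }
            for lab, cm in model.classes.items()
        },
    }


def save_model(model: TrainingModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> TrainingModel:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {d.get('schema_version')!r}")
    classes = {
        lab: ClassModel(
            lab,
            np.array(c["mean"]),
            np.array(c["covariance"]),
            int(c["n"]),
            float(c["ridge"]),
        )
        for lab, c in d["classes"].items()
    }
    return TrainingModel(classes, tuple(d["feature_order"]))


def read_training_csv(path: str | Path) -> list[TrainingRecord]:
    """Load a labelled training table (columns: class,length_um,thickness_um,r1,r2)."""
    df = pd.read_csv(path)
    required = ["class", *FEATURE_ORDER]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrainingError(f"training CSV missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            feats = ShapeFeatures(
                float(row["length_um"]),
                float(row["thickness_um"]),
                float(row["r1"]),
                float(row["r2"]),
            )
        except (TypeError, ValueError) as e:
            raise TrainingError(f"invalid feature values in row {i}: {e}") from e
        records.append(TrainingRecord(str(row["class"]), feats))
    return records
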