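"""End-to-end orchestration: image -> regions -> features -> sexes -> report.

One image corresponds to one well. A run produces a
:class:`PlateReport` per image: per-class counts, rejection tallies by
reason, the male percentage (males / (males + hermaphrodites), larvae
excluded as a nuisance class), and a per-worm table with distances and
margins. Low-margin calls can be exported for human review and the
corrected labels re-imported, replacing an interactive inspection GUI
with a scriptable loop.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    CLASS_LABELS,
    TrainingModel,
    classify,
    fit_training,
    load_model,
    read_training_csv,
    save_model,
)
from .morphometry import Rejection, ShapeFeatures, TailProbeConfig, extract_features
from .segmentation import (
    GrayscaleImage,
    RegionFilterConfig,
    binarize,
    extract_regions,
)

logger = logging.getLogger("nemasex")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; echoed into every report."""

    um_per_pixel: float = 6.5
    window_um: float = 300.0
    offset: float = 0.02
    dark_foreground: bool = True
    region_filter: RegionFilterConfig = field(default_factory=RegionFilterConfig)
    tail_probe: TailProbeConfig = field(default_factory=TailProbeConfig)
    model_path: str | None = None
    training_csv: str | None = None
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_jsonable(self) -> dict:
        d = {
            "um_per_pixel": self.um_per_pixel,
            "window_um": self.window_um,
            "offset": self.offset,
            "dark_foreground": self.dark_foreground,
            "region_filter": vars(self.region_filter).copy(),
            "tail_probe": vars(self.tail_probe).copy(),
            "model_path": self.model_path,
            "training_csv": self.training_csv,
            "seed": self.seed,
        }
        return d


@dataclass
class WormRow:
    region_id: int
    bbox: tuple[int, int, int, int]
    features: ShapeFeatures | None
    label: str | None
    distances: dict[str, float] | None
    margin: float | None
    tie: bool = False
    rejection_reason: str | None = None


@dataclass
class PlateReport:
    """Summary of one plate/well image."""

    image: str
    counts: dict[str, int]
    rejections: dict[str, int]
    male_percentage: float | None
    worms: list[WormRow]
    config: dict = field(default_factory=dict)
    model_hash: str | None = None
    version: str = ""

    def to_jsonable(self) -> dict:
        return {
            "image": self.image,
            "counts": self.counts,
            "rejections": self.rejections,
            "male_percentage": self.male_percentage,
            "worms": [
                {
                    "region_id": w.region_id,
                    "bbox": list(w.bbox),
                    "label": w.label,
                    "features": None
                    if w.features is None
                    else {
                        "length_um": w.features.length_um,
                        "thickness_um": w.features.thickness_um,
                        "r1": w.features.r1,
                        "r2": w.features.r2,
                    },
                    "distances": w.distances,
                    "margin": w.margin,
                    "tie": w.tie,
                    "rejection_reason": w.rejection_reason,
                }
                for w in self.worms
            ],
            "config": self.config,
            "model_hash": self.model_hash,
            "version": self.version,
        }


def _male_percentage(counts: dict[str, int]) -> float | None:
    males = counts.get("male", 0)
    herms = counts.get("hermaphrodite", 0)
    if males + herms == 0:
        return None
    return 100.0 * males / (males + herms)


def classify_plate(
    features: list[ShapeFeatures | Rejection],
    model: TrainingModel,
    image: str = "",
    bboxes: dict[int, tuple[int, int, int, int]] | None = None,
) -> PlateReport:
    """Aggregate per-worm classifications into a plate report.

    ``features`` may mix successful measurements and rejections;
    rejections are tallied by reason and never classified. The male
    percentage excludes larvae from the denominator and is ``None``
    when no adults were classified.
    """
    counts = {lab: 0 for lab in CLASS_LABELS}
    rejections: dict[str, int] = {}
    rows: list[WormRow] = []
    bboxes = bboxes or {}
    for item in features:
        if isinstance(item, Rejection):
            rejections[item.reason] = rejections.get(item.reason, 0) + 1
            rows.append(
                WormRow(
                    region_id=item.region_id,
                    bbox=bboxes.get(item.region_id, (0, 0, 0, 0)),
                    features=None,
                    label=None,
                    distances=None,
                    margin=None,
                    rejection_reason=item.reason,
                )
            )
            continue
        cl = classify(item, model)
        counts[cl.label] += 1
        rows.append(
            WormRow(
                region_id=item.region_id,
                bbox=bboxes.get(item.region_id, (0, 0, 0, 0)),
                features=item,
                label=cl.label,
                distances=cl.distances,
                margin=cl.margin,
                tie=cl.tie,
            )
        )
    return PlateReport(
        image=image,
        counts=counts,
        rejections=rejections,
        male_percentage=_male_percentage(counts),
        worms=rows,
    )


def read_image(path: str | Path, um_per_pixel: float = 6.5) -> GrayscaleImage:
    """Load an 8/16-bit grayscale TIFF or PNG plate image."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        px = iio.imread(p)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse RGB(A) scans to luminance
        px = px[..., :3].mean(axis=2)
    return GrayscaleImage(px, um_per_pixel)


def _resolve_model(cfg: RunConfig) -> tuple[TrainingModel, str | None]:
    if cfg.model_path:
        model = load_model(cfg.model_path)
        digest = hashlib.sha256(Path(cfg.model_path).read_bytes()).hexdigest()
        return model, digest
    if cfg.training_csv:
        model = fit_training(read_training_csv(cfg.training_csv))
        return model, None
    raise ValueError("RunConfig needs model_path or training_csv")


def process_image(image: GrayscaleImage, cfg: RunConfig, model: TrainingModel,
                  name: str = "") -> PlateReport:
    """Run segmentation, metrology and classification on one in-memory image."""
    mask = binarize(image, cfg.window_um, cfg.offset, cfg.dark_foreground)
    regions = extract_regions(mask, cfg.region_filter)
    logger.info("%s: %d candidate regions after filtering", name or "<image>", len(regions))
    feats = [extract_features(r, cfg=cfg.tail_probe) for r in regions]
    bboxes = {r.region_id: r.bbox for r in regions}
    report = classify_plate(feats, model, image=name, bboxes=bboxes)
    logger.info(
        "%s: counts=%s rejections=%s", name or "<image>", report.counts, report.rejections
    )
    report.config = cfg.to_jsonable()
    from . import __version__

    report.version = __version__
    return report


def run_pipeline(image_paths: list[str | Path], cfg: RunConfig) -> list[PlateReport]:
    """Batch-process plate images; one failed image does not abort the batch.

    When ``cfg.out_dir`` is set, writes ``<stem>.report.json`` and
    ``<stem>.worms.csv`` per image plus a ``batch_summary.json``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    model, model_hash = _resolve_model(cfg)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    reports: list[PlateReport] = []
    for path in image_paths:
        path = Path(path)
        try:
            image = read_image(path, cfg.um_per_pixel)
            report = process_image(image, cfg, model, name=str(path))
            report.model_hash = model_hash
        except Exception as e:  # keep the batch alive, record the failure
            logger.error("failed on %s: %s", path, e)
            report = PlateReport(
                image=str(path),
                counts={},
                rejections={"error": 1},
                male_percentage=None,
                worms=[],
                config=cfg.to_jsonable(),
            )
        reports.append(report)
        if out_dir:
            stem = path.stem
            Path(out_dir, f"{stem}.report.json").write_text(
                json.dumps(report.to_jsonable(), indent=1)
            )
            write_worms_csv(report, Path(out_dir, f"{stem}.worms.csv"))
    if out_dir:
        summary = {
            "n_images": len(reports),
            "reports": [
                {
                    "image": r.image,
                    "counts": r.counts,
                    "male_percentage": r.male_percentage,
                }
                for r in reports
            ],
        }
        Path(out_dir, "batch_summary.json").write_text(json.dumps(summary, indent=1))
    return reports


def write_worms_csv(report: PlateReport, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(
            [
                "region_id", "row0", "col0", "height", "width",
                "length_um", "thickness_um", "r1", "r2",
                "label", "dist_hermaphrodite", "dist_male", "dist_larva",
                "margin", "tie_flag", "status",
            ]
        )
        for row in report.worms:
            feats = row.features
            dists = row.distances or {}
            w.writerow(
                [
                    row.region_id, *row.bbox,
                    *(["", "", "", ""] if feats is None else
                      [f"{feats.length_um:.3f}", f"{feats.thickness_um:.3f}",
                       f"{feats.r1:.5f}", f"{feats.r2:.5f}"]),
                    row.label or "",
                    *(f"{dists.get(k):.6f}" if k in dists else "" for k in CLASS_LABELS),
                    "" if row.margin is None else f"{row.margin:.6f}",
                    int(row.tie),
                    row.rejection_reason or "ok",
                ]
            )


def train_from_csv(csv_path: str | Path, model_path: str | Path, **fit_kwargs) -> TrainingModel:
    """Fit the classifier from a labelled feature CSV and save the model JSON."""
    model = fit_training(read_training_csv(csv_path), **fit_kwargs)
    save_model(model, model_path)
    return model


def export_review(report: PlateReport, k: int) -> pd.DataFrame:
    """The k lowest-margin classifications, for human re-labelling.

    Ties (margin 0) sort first. Columns include the bounding box so the
    reviewer can find each animal in the image; edit ``label`` and feed
    the frame back through :func:`apply_corrections`.
    """
    rows = [w for w in report.worms if w.label is not None]
    rows.sort(key=lambda w: (w.margin, w.region_id))
    rows = rows[: max(k, 0)]
    return pd.DataFrame(
        {
            "region_id": [w.region_id for w in rows],
            "row0": [w.bbox[0] for w in rows],
            "col0": [w.bbox[1] for w in rows],
            "height": [w.bbox[2] for w in rows],
            "width": [w.bbox[3] for w in rows],
            "label": [w.label for w in rows],
            "margin": [w.margin for w in rows],
            "tie_flag": [int(w.tie) for w in rows],
        }
    )


def apply_corrections(report: PlateReport, corrections: pd.DataFrame) -> PlateReport:
    """Recompute a report with human-edited labels.

    ``corrections`` needs columns ``region_id`` and ``label``; rows for
    unknown region ids or rejected regions are ignored. The total
    number of classified worms is preserved.
    """
    new_labels = {
        int(r.region_id): str(r.label) for r in corrections.itertuples()
    }
    for lab in new_labels.values():
        if lab not in CLASS_LABELS:
            raise ValueError(f"unknown corrected label {lab!r}")
    worms = []
    counts = {lab: 0 for lab in CLASS_LABELS}
    for w in report.worms:
        if w.label is not None and w.region_id in new_labels:
            w = replace_label(w, new_labels[w.region_id])
        if w.label is not None:
            counts[w.label] += 1
        worms.append(w)
    return PlateReport(
        image=report.image,
        counts=counts,
        rejections=dict(report.rejections),
        male_percentage=_male_percentage(counts),
        worms=worms,
        config=dict(report.config),
        model_hash=report.model_hash,
        version=report.version,
    )


def replace_label(w: WormRow, label: str) -> WormRow:
    return WormRow(
        region_id=w.region_id,
        bbox=w.bbox,
        features=w.features,
        label=label,
        distances=w.distances,
        margin=w.margin,
        tie=w.tie,
        rejection_reason=w.rejection_reason,
    )
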