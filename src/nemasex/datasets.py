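"""Bundled fixture tables.

``strain_counts`` is a transcription of a published 28-strain him-screen
count table (wild-type plus 27 mutants, automatic and manual male
percentages with totals). ``training_table`` is a synthetic labelled
feature table (46 hermaphrodites / 46 males / 39 larvae) produced by
rendering single worms with :mod:`nemasex.synth` and measuring them with
:mod:`nemasex.morphometry`; it is a stand-in for a real annotated image
set and is regenerable with :func:`nemasex.synth.generate_training_records`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .classifier import TrainingRecord, read_training_csv
from .himstats import StrainCounts, read_strain_table


def _data_path(name: str) -> Path:
    return Path(resources.files("nemasex").joinpath("data", name))


def strain_counts() -> tuple[list[StrainCounts], list[StrainCounts]]:
    """(automatic, manual) per-strain male percentages of the him screen."""
    return read_strain_table(_data_path("strain_counts.csv"))


def strain_counts_frame() -> pd.DataFrame:
    return pd.read_csv(_data_path("strain_counts.csv"))


def training_table_path() -> Path:
    """Path of the shipped synthetic 131-row training CSV."""
    return _data_path("training_synthetic.csv")


def training_records() -> list[TrainingRecord]:
    """The shipped synthetic training set (46/46/39 labelled feature rows)."""
    return read_training_csv(training_table_path())
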