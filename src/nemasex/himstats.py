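"""Sex-ratio statistics: the him screen and manual-vs-automatic agreement.

A him ("high incidence of males") screen compares each mutant strain's
male percentage against the wild-type reference with a Pearson
chi-square test on the reconstructed 2x2 table (male vs non-male x
strain), flagging strains at p < 1e-4. Published strain tables print
only (male %, n), so male counts are reconstructed by nearest-integer
rounding of pct*n/100. No continuity correction and no
multiple-testing adjustment are applied: with thousands of animals per
strain the correction is immaterial, and the screen is defined at the
raw threshold.

The agreement layer quantifies how well automatic counts track manual
ones: Pearson correlation of paired per-strain male percentages, the
maximum absolute discrepancy, and per-well error analyses (error vs
male percentage and vs total animal count).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_P = 1e-4


class InsufficientDataError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass(frozen=True)
class StrainCounts:
    """One strain's male percentage and total animal count from one source."""

    strain: str
    male_pct: float
    n: int
    source: str = "automatic"

    def __post_init__(self):
        if not (0 <= self.male_pct <= 100):
            raise ValueError("male_pct must lie in [0, 100]")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.source not in ("automatic", "manual"):
            raise ValueError("source must be 'automatic' or 'manual'")

    @property
    def male_count(self) -> int:
        return int(round(self.male_pct * self.n / 100.0))


@dataclass(frozen=True)
class WellRecord:
    """Per-well manual and automatic male/hermaphrodite counts."""

    well_id: str
    manual_male: int
    manual_herm: int
    auto_male: int
    auto_herm: int

    def __post_init__(self):
        for v in (self.manual_male, self.manual_herm, self.auto_male, self.auto_herm):
            if v < 0:
                raise ValueError("counts must be non-negative")


def chi_square_vs_reference(
    test: StrainCounts, ref: StrainCounts, continuity_correction: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-square (df=1) of test vs reference male proportions.

    Reconstructs the 2x2 table (male / non-male x strain) from the
    printed percentages and totals. Returns (statistic, p_value,
    significant_at_1e-4).
    """
    table = np.array(
        [
            [test.male_count, test.n - test.male_count],
            [ref.male_count, ref.n - ref.male_count],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedTestError("2x2 table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(stat), float(p), bool(p < SIGNIFICANCE_P)


def him_screen(
    table: list[StrainCounts], ref_label: str = "wild-type", **kwargs
) -> list[str]:
    """Strains whose male percentage differs from the reference at p < 1e-4.

    Returns the flagged strain names sorted alphabetically; the
    reference strain itself is never flagged.
    """
    refs = [s for s in table if s.strain == ref_label]
    if not refs:
        raise KeyError(f"reference strain {ref_label!r} not in table")
    ref = refs[0]
    flagged = []
    for s in table:
        if s.strain == ref_label:
            continue
        _, _, sig = chi_square_vs_reference(s, ref, **kwargs)
        if sig:
            flagged.append(s.strain)
    return sorted(flagged)


def agreement_summary(
    auto: list[StrainCounts], manual: list[StrainCounts]
) -> tuple[float, float]:
    """(Pearson r, max |auto - manual| male %) over matched strains.

    The maximum discrepancy is returned at full precision; round to two
    significant figures for reporting.
    """
    am = {s.strain: s.male_pct for s in auto}
    mm = {s.strain: s.male_pct for s in manual}
    common = sorted(set(am) & set(mm))
    if len(common) < 3:
        raise InsufficientDataError("need at least 3 matched strains")
    if set(am) != set(mm):
        raise ValueError("auto and manual strain sets differ")
    a = np.array([am[s] for s in common])
    m = np.array([mm[s] for s in common])
    r = float(stats.pearsonr(a, m).statistic)
    return r, float(np.abs(a - m).max())


@dataclass(frozen=True)
class ErrorAnalysis:
    r_sexratio: float
    p_sexratio: float
    pct_cases_error_lt_10: float
    r_error_vs_malepct_filtered: float
    p_error_vs_malepct_filtered: float
    r_error_vs_total: float
    p_error_vs_total: float
    n_wells: int


def error_analysis(wells: list[WellRecord], min_animals: int = 10) -> ErrorAnalysis:
    """Per-well manual-vs-automatic sex-ratio error structure.

    For each well with both sources defined (male+hermaphrodite > 0),
    computes male percentages and their absolute difference. Reports
    the manual/automatic correlation, the share of wells with error
    under 10 percentage points, the error-vs-male-percentage
    correlation after dropping wells with fewer than ``min_animals``
    manually counted animals, and the error-vs-total-count correlation
    over all wells.
    """
    if not wells:
        raise InsufficientDataError("no wells supplied")
    rows = []
    for w in wells:
        mt, at = w.manual_male + w.manual_herm, w.auto_male + w.auto_herm
        if mt == 0 or at == 0:
            continue
        rows.append(
            (
                100.0 * w.manual_male / mt,
                100.0 * w.auto_male / at,
                mt,
            )
        )
    if len(rows) < 3:
        raise InsufficientDataError("fewer than 3 wells with defined sex ratios")
    man, auto, total = map(np.array, zip(*rows))
    err = np.abs(man - auto)

    def _pearson(x, y):
        # a constant vector (e.g. zero error everywhere) has no defined r
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return type("R", (), {"statistic": np.nan, "pvalue": np.nan})()
        return stats.pearsonr(x, y)

    r_sex = _pearson(man, auto)
    keep = total >= min_animals
    if keep.sum() >= 3:
        r_filt = _pearson(err[keep], man[keep])
    else:
        raise InsufficientDataError("fewer than 3 wells above the animal threshold")
    r_tot = _pearson(err, total)
    return ErrorAnalysis(
        r_sexratio=float(r_sex.statistic),
        p_sexratio=float(r_sex.pvalue),
        pct_cases_error_lt_10=float(100.0 * np.mean(err < 10.0)),
        r_error_vs_malepct_filtered=float(r_filt.statistic),
        p_error_vs_malepct_filtered=float(r_filt.pvalue),
        r_error_vs_total=float(r_tot.statistic),
        p_error_vs_total=float(r_tot.pvalue),
        n_wells=len(rows),
    )


# ---------------------------------------------------------------------------
# table I/O


def read_strain_table(path: str | Path) -> tuple[list[StrainCounts], list[StrainCounts]]:
    """Load a strain count table CSV.

    Expected columns: genotype, auto_male_pct, auto_n, manual_male_pct,
    manual_n. Returns (automatic, manual) StrainCounts lists.
    """
    df = pd.read_csv(path)
    auto = [
        StrainCounts(r.genotype, float(r.auto_male_pct), int(r.auto_n), "automatic")
        for r in df.itertuples()
    ]
    manual = [
        StrainCounts(r.genotype, float(r.manual_male_pct), int(r.manual_n), "manual")
        for r in df.itertuples()
    ]
    return auto, manual


#: column mapping for per-well raw-data tables (XLSX or CSV)
WELL_COLUMNS = {
    "well_id": "well_id",
    "manual_male": "manual_male",
    "manual_herm": "manual_herm",
    "auto_male": "auto_male",
    "auto_herm": "auto_herm",
}


def read_well_table(path: str | Path, columns: dict[str, str] | None = None) -> list[WellRecord]:
    """Load per-well counts from CSV or XLSX with a configurable column mapping."""
    cols = dict(WELL_COLUMNS)
    if columns:
        cols.update(columns)
    p = Path(path)
    df = pd.read_excel(p) if p.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(p)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns {missing}")
    return [
        WellRecord(
            str(row[cols["well_id"]]),
            int(row[cols["manual_male"]]),
            int(row[cols["manual_herm"]]),
            int(row[cols["auto_male"]]),
            int(row[cols["auto_herm"]]),
        )
        for _, row in df.iterrows()
    ]
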