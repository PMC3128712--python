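"""Carrier- and allele-level 2x2 contingency epidemiology.

Exposure can be counted at two levels:

* **carrier** — individuals with at least one copy (n = cases + controls);
* **allele** — chromosomes (n = 2 x cases + 2 x controls).

Odds ratios use Woolf's log-OR variance 1/a + 1/b + 1/c + 1/d; Haldane's
correction (add 0.5 to all four cells) is applied only when explicitly
requested, since published carrier ORs are typically uncorrected while
allele tables with empty cells require the correction.  Association
p-values use a Pearson chi-square without continuity correction when all
expected cells are at least 5, otherwise a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact

from .alignment import CohortGenotypes, ResidueGenotypeMatrix, normalize_allele_name, one_letter

Level = Literal["carrier", "allele"]
Correction = Literal["none", "haldane"]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposed/unexposed counts in cases and controls.

    a: exposed cases, b: unexposed cases, c: exposed controls,
    d: unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int
    level: Level = "carrier"
    label: str = ""

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n_case_units(self) -> int:
        return self.a + self.b

    @property
    def n_control_units(self) -> int:
        return self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def scaled(self, factor: int) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a * factor, self.b * factor, self.c * factor, self.d * factor,
            level=self.level, label=self.label,
        )

    def case_percent(self) -> int:
        """Exposed-case share as an integer percent (as printed in tables)."""
        return round(100.0 * self.a / self.n_case_units)

    def control_percent(self) -> int:
        return round(100.0 * self.c / self.n_control_units)


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    correction: Correction

    def __iter__(self):
        return iter((self.or_point, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class AssociationTestResult:
    p: float
    method: Literal["chi2", "fisher"]
    statistic: float | None = None


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def _table_from_bool(exposed: np.ndarray, status: np.ndarray, level, label):
    exposed = np.asarray(exposed, dtype=bool)
    case = np.asarray(status, dtype=bool)
    return ContingencyTable2x2(
        a=int((exposed & case).sum()),
        b=int((~exposed & case).sum()),
        c=int((exposed & ~case).sum()),
        d=int((~exposed & ~case).sum()),
        level=level,
        label=label,
    )


def carrier_table(
    matrix: ResidueGenotypeMatrix, position: int, amino_acid: str
) -> ContingencyTable2x2:
    """Individuals carrying >= 1 copy of *amino_acid* at *position*."""
    aa = one_letter(amino_acid)
    mask = matrix.valid_mask([position])
    dosage = matrix.dosage(position, aa)
    return _table_from_bool(
        (dosage >= 1)[mask], matrix.status[mask], "carrier", f"{aa}{position}"
    )


def carrier_table_for_allele(
    cohort: CohortGenotypes, allele: str
) -> ContingencyTable2x2:
    allele = normalize_allele_name(allele)
    exposed = np.array([allele in (a, b) for _, _, a, b in cohort.records])
    return _table_from_bool(exposed, cohort.status, "carrier", allele)


def allele_table(
    matrix: ResidueGenotypeMatrix, position: int, amino_acid: str
) -> ContingencyTable2x2:
    """Chromosomes carrying *amino_acid* at *position* (a+b = 2 x cases)."""
    aa = one_letter(amino_acid)
    mask = matrix.valid_mask([position])
    dosage = matrix.dosage(position, aa)[mask].astype(int)
    case = matrix.status[mask].astype(bool)
    a = int(dosage[case].sum())
    c = int(dosage[~case].sum())
    return ContingencyTable2x2(
        a=a,
        b=2 * int(case.sum()) - a,
        c=c,
        d=2 * int((~case).sum()) - c,
        level="allele",
        label=f"{aa}{position}",
    )


def allele_table_for_allele(
    cohort: CohortGenotypes, allele: str
) -> ContingencyTable2x2:
    allele = normalize_allele_name(allele)
    status = cohort.status.astype(bool)
    dosage = np.array(
        [(a == allele) + (b == allele) for _, _, a, b in cohort.records], dtype=int
    )
    a = int(dosage[status].sum())
    c = int(dosage[~status].sum())
    return ContingencyTable2x2(
        a=a,
        b=2 * int(status.sum()) - a,
        c=c,
        d=2 * int((~status).sum()) - c,
        level="allele",
        label=allele,
    )


def table_from_counts(
    exposed_cases: int,
    total_cases: int,
    exposed_controls: int,
    total_controls: int,
    level: Level = "carrier",
    label: str = "",
) -> ContingencyTable2x2:
    """Build a table from published exposed/total summary counts."""
    return ContingencyTable2x2(
        a=exposed_cases,
        b=total_cases - exposed_cases,
        c=exposed_controls,
        d=total_controls - exposed_controls,
        level=level,
        label=label,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def woolf_or(
    table: ContingencyTable2x2, correction: Correction = "none"
) -> OddsRatioResult:
    """Odds ratio with a Woolf 95% CI, optionally Haldane-corrected.

    With ``correction="haldane"`` 0.5 is added to all four cells before both
    the point estimate and the variance; with ``correction="none"`` every
    cell must be positive.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    shift = 0.5 if correction == "haldane" else 0.0
    a, b, c, d = (x + shift for x in table.cells)
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "zero cell in 2x2 table; use correction='haldane' for a finite OR"
        )
    or_point = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = np.log(or_point)
    return OddsRatioResult(
        or_point=float(or_point),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        correction=correction,
    )


def expected_cells(table: ContingencyTable2x2) -> np.ndarray:
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        raise ValueError("empty margin in 2x2 table")
    return rows * cols / n


def association_test(table: ContingencyTable2x2) -> AssociationTestResult:
    """Pearson chi-square (no continuity correction) when all expected
    cells >= 5, otherwise a two-sided Fisher exact test (sum of tables at
    most as probable as the observed one)."""
    exp = expected_cells(table)
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (exp >= 5.0).all():
        stat = float(((obs - exp) ** 2 / exp).sum())
        return AssociationTestResult(
            p=float(chi2.sf(stat, 1)), method="chi2", statistic=stat
        )
    _, p = fisher_exact(obs, alternative="two-sided")
    return AssociationTestResult(p=float(p), method="fisher")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return min(1.0, m * p)


def epistats_row(
    table: ContingencyTable2x2,
    correction: Correction,
    m_bonferroni: int = 1,
) -> dict:
    """One results-TSV row: counts, OR, CI, raw and corrected p."""
    orr = woolf_or(table, correction)
    test = association_test(table)
    return {
        "exposure": table.label,
        "level": table.level,
        "a": table.a,
        "b": table.b,
        "c": table.c,
        "d": table.d,
        "or": orr.or_point,
        "ci_low": orr.ci_low,
        "ci_high": orr.ci_high,
        "p": test.p,
        "p_bonferroni": bonferroni(test.p, m_bonferroni),
        "correction": correction,
    }


def epistats_frame(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "level", "a", "b", "c", "d",
            "or", "ci_low", "ci_high", "p", "p_bonferroni", "correction",
        ],
    )
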