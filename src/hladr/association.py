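"""Stepwise conditional likelihood-ratio association scan over residues.

The scan asks, residue by residue, whether amino-acid variation at that
position improves a logistic model of case-control status over a base model
containing zero or more already-accepted residues.  Two codings are
supported:

* ``dosage`` — one covariate per non-reference amino acid holding its copy
  number (0/1/2) in the individual; the effect of an amino acid is additive
  on the log-odds scale.
* ``genotype`` — one indicator per observed unordered amino-acid pair
  (one pair omitted as reference); pairs rarer than ``min_count`` in either
  arm are pooled into a single "rare" category to avoid empty cells.

The overall residue effect is a likelihood-ratio chi-square comparing the
nested fits.  Reference categories are chosen deterministically (most
frequent), which leaves the LR statistic unchanged.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import chi2

from .alignment import ResidueGenotypeMatrix, one_letter

Coding = Literal["dosage", "genotype"]

#: Absolute coefficient magnitude (log-odds) beyond which an otherwise
#: "converged" fit is treated as diverging (complete separation).
_SEPARATION_BOUND = 15.0


class RankDeficientDesignError(ValueError):
    """Design matrix has linearly dependent columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"rank-deficient design; collinear column(s): {columns}")


@dataclass
class DesignMatrix:
    """A labelled numeric design with an intercept column ``const``."""

    frame: pd.DataFrame
    coding: Coding
    residues_encoded: list[int]
    references: dict[int, str]

    @property
    def labels(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_samples(self) -> int:
        return len(self.frame)


@dataclass
class LogisticFit:
    params: pd.Series
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    message: str = ""
    cov_params: pd.DataFrame | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.params.index)


@dataclass
class LrtResult:
    """Likelihood-ratio test of one candidate residue against a base model."""

    position: int
    base_residues: tuple[int, ...]
    statistic: float
    df: int
    p: float
    n_samples: int
    rank: int | None = None


@dataclass
class ScanFailure:
    position: int
    reason: str


@dataclass
class ScanResult:
    results: list[LrtResult]
    failures: list[ScanFailure] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": r.position,
                "base": "+".join(str(b) for b in r.base_residues) or "-",
                "lr_statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "rank": r.rank,
                "n": r.n_samples,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def top(self) -> LrtResult:
        return self.results[0]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _resolve_mask(matrix: ResidueGenotypeMatrix, residues, sample_mask):
    mask = matrix.valid_mask(residues)
    if sample_mask is not None:
        mask = mask & np.asarray(sample_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no samples left after exclusions")
    return mask


def dosage_design(
    matrix: ResidueGenotypeMatrix,
    residues: Sequence[int],
    sample_mask: np.ndarray | None = None,
    reference: Mapping[int, str] | None = None,
) -> DesignMatrix:
    """Allele-dosage design: per residue, copy-number columns for every
    observed amino acid except the reference (default: the most frequent).
    """
    residues = list(residues)
    mask = _resolve_mask(matrix, residues, sample_mask)
    ids = [s for s, m in zip(matrix.sample_ids, mask) if m]
    data: dict[str, np.ndarray] = {"const": np.ones(int(mask.sum()))}
    refs: dict[int, str] = {}
    for pos in residues:
        counts = matrix.allele_counts(pos, mask)
        observed = sorted(a for a in counts if a != "X")
        if len(observed) < 2:
            raise ValueError(f"residue {pos} is monomorphic in the analysis sample")
        if reference and pos in reference:
            ref = one_letter(reference[pos])
            if ref not in observed:
                raise ValueError(f"reference {ref!r} not observed at residue {pos}")
        else:
            ref = max(observed, key=lambda a: (counts[a], a))
        refs[pos] = ref
        for aa in observed:
            if aa == ref:
                continue
            data[f"p{pos}:{aa}"] = matrix.dosage(pos, aa)[mask].astype(float)
    frame = pd.DataFrame(data, index=ids)
    return DesignMatrix(frame=frame, coding="dosage", residues_encoded=residues,
                        references=refs)


def genotype_pair_categories(
    matrix: ResidueGenotypeMatrix,
    position: int,
    mask: np.ndarray,
    min_count: int = 2,
) -> tuple[list[str], dict[str, str]]:
    """Observed pair categories at *position* after rare pooling.

    Returns (kept category labels incl. possibly ``rare``, pair -> category).
    A pair is pooled when its count is below *min_count* in cases OR in
    controls.  If the pooled category itself is rarer than *min_count* in an
    arm it is merged into the most frequent (reference) category, with a
    warning.
    """
    status = matrix.status
    case_counts: Counter = Counter()
    ctrl_counts: Counter = Counter()
    for i in np.flatnonzero(mask):
        pair = matrix.pair(i, position)
        label = "".join(pair)
        (case_counts if status[i] else ctrl_counts)[label] += 1
    pairs = sorted(set(case_counts) | set(ctrl_counts))
    if len(pairs) < 2:
        raise ValueError(
            f"residue {position}: a single amino-acid pair observed (no df)"
        )
    rare = [
        p for p in pairs
        if case_counts[p] < min_count or ctrl_counts[p] < min_count
    ]
    kept = [p for p in pairs if p not in rare]
    category = {p: p for p in kept}
    if rare:
        rare_cases = sum(case_counts[p] for p in rare)
        rare_ctrls = sum(ctrl_counts[p] for p in rare)
        if rare_cases < min_count or rare_ctrls < min_count:
            if not kept:
                raise ValueError(
                    f"residue {position}: all pairs rare; cannot form categories"
                )
            ref = max(kept, key=lambda p: (case_counts[p] + ctrl_counts[p], p))
            warnings.warn(
                f"residue {position}: pooled rare category still has < "
                f"{min_count} in an arm; merged into reference {ref}",
                stacklevel=2,
            )
            for p in rare:
                category[p] = ref
        else:
            for p in rare:
                category[p] = "rare"
            kept = kept + ["rare"]
    if len(kept) < 2:
        raise ValueError(
            f"residue {position}: a single genotype category after pooling (no df)"
        )
    return kept, category


def genotype_design(
    matrix: ResidueGenotypeMatrix,
    residues: Sequence[int],
    min_count: int = 2,
    sample_mask: np.ndarray | None = None,
    reference: Mapping[int, str] | None = None,
) -> DesignMatrix:
    """Genotype design: mutually exclusive indicators per amino-acid pair."""
    residues = list(residues)
    mask = _resolve_mask(matrix, residues, sample_mask)
    idx = np.flatnonzero(mask)
    ids = [matrix.sample_ids[i] for i in idx]
    status = matrix.status
    data: dict[str, np.ndarray] = {"const": np.ones(len(idx))}
    refs: dict[int, str] = {}
    for pos in residues:
        kept, category = genotype_pair_categories(matrix, pos, mask, min_count)
        totals = Counter(
            category["".join(matrix.pair(i, pos))] for i in idx
        )
        if reference and pos in reference:
            ref = reference[pos]
            if ref not in kept:
                raise ValueError(
                    f"reference category {ref!r} not present at residue {pos}"
                )
        else:
            ref = max(kept, key=lambda c: (totals[c], c))
        refs[pos] = ref
        sample_cat = [category["".join(matrix.pair(i, pos))] for i in idx]
        for cat in kept:
            if cat == ref:
                continue
            col = np.array([1.0 if c == cat else 0.0 for c in sample_cat])
            data[f"p{pos}:{cat}"] = col
    frame = pd.DataFrame(data, index=ids)
    return DesignMatrix(frame=frame, coding="genotype", residues_encoded=residues,
                        references=refs)


# ---------------------------------------------------------------------------
# Logistic maximum likelihood (IRLS) and likelihood-ratio testing
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [labels[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
    if bad:
        raise RankDeficientDesignError(sorted(bad))


def fit_logistic(
    design: DesignMatrix | pd.DataFrame,
    phenotype: Sequence[int] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence: relative change of the Bernoulli log-likelihood below *tol*.
    Complete separation is surfaced as ``converged=False`` with a diagnostic
    message rather than silently returning inflated estimates.
    """
    frame = design.frame if isinstance(design, DesignMatrix) else design
    labels = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} does not match design ({n})")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    if n <= p:
        raise ValueError(f"{n} samples cannot identify {p} parameters")
    constant = [
        lab for j, lab in enumerate(labels)
        if lab != "const" and np.ptp(X[:, j]) == 0
    ]
    if constant:
        raise ValueError(f"constant column(s) in design: {constant}")
    _check_rank(X, labels)

    beta = np.zeros(p)
    ll_old = -np.inf
    ll = -np.inf
    converged = False
    message = ""
    it = 0
    xtwx = None
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        mu_c = np.clip(mu, 1e-12, 1.0 - 1e-12)
        ll = float(y @ np.log(mu_c) + (1.0 - y) @ np.log(1.0 - mu_c))
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
        w = mu_c * (1.0 - mu_c)
        z = eta + (y - mu) / w
        xtw = X.T * w
        xtwx = xtw @ X
        try:
            beta = np.linalg.solve(xtwx, xtw @ z)
        except np.linalg.LinAlgError:
            converged = False
            message = "normal equations singular during IRLS"
            break
    if converged and np.abs(beta).max() > _SEPARATION_BOUND:
        converged = False
        message = (
            "coefficients diverging "
            f"(max |beta| = {np.abs(beta).max():.1f}); possible complete separation"
        )
    elif not converged and not message:
        message = f"log-likelihood not converged after {max_iter} iterations"

    cov = None
    if converged and xtwx is not None:
        try:
            cov = pd.DataFrame(np.linalg.inv(xtwx), index=labels, columns=labels)
        except np.linalg.LinAlgError:
            cov = None
    return LogisticFit(
        params=pd.Series(beta, index=labels),
        loglik=ll,
        n_params=p,
        converged=converged,
        n_iter=it,
        message=message,
        cov_params=cov,
    )


def lrt(base: LogisticFit, full: LogisticFit, tol: float = 1e-6) -> LrtResult:
    """Likelihood-ratio chi-square for nested logistic fits."""
    if not (base.converged and full.converged):
        raise ValueError("both fits must have converged for a valid LRT")
    if not set(base.labels) <= set(full.labels):
        extra = sorted(set(base.labels) - set(full.labels))
        raise ValueError(f"fits are not nested; base-only column(s): {extra}")
    df = full.n_params - base.n_params
    statistic = 2.0 * (full.loglik - base.loglik)
    if statistic < -tol * (1.0 + abs(base.loglik)):
        raise ValueError(
            f"negative LR statistic ({statistic:.3g}); optimization failed"
        )
    statistic = max(statistic, 0.0)
    # identical models (df 0) degenerate to statistic 0, p 1
    p = 1.0 if df == 0 else float(chi2.sf(statistic, df))
    return LrtResult(
        position=-1,
        base_residues=(),
        statistic=statistic,
        df=df,
        p=p,
        n_samples=0,
    )


def _design_for(matrix, residues, coding, mask, min_count):
    if not residues:
        ids = [s for s, m in zip(matrix.sample_ids, mask) if m]
        frame = pd.DataFrame({"const": np.ones(int(mask.sum()))}, index=ids)
        return DesignMatrix(frame=frame, coding=coding, residues_encoded=[],
                            references={})
    if coding == "dosage":
        return dosage_design(matrix, residues, sample_mask=mask)
    return genotype_design(matrix, residues, min_count=min_count, sample_mask=mask)


def scan(
    matrix: ResidueGenotypeMatrix,
    base_residues: Sequence[int] = (),
    coding: Coding = "dosage",
    min_count: int = 2,
) -> ScanResult:
    """Conditional LR scan of every polymorphic residue not in the base model.

    For each candidate, the base model (intercept + base residues) and the
    full model (base + candidate) are fitted on the samples fully observed at
    all involved residues, and compared by a likelihood-ratio test.  Results
    are ranked by ascending p-value; candidates whose fit fails (collinearity
    with the base coding, separation, non-convergence) are recorded as
    failures and excluded from the ranking.
    """
    base_residues = list(base_residues)
    for pos in base_residues:
        if pos not in matrix.positions:
            raise KeyError(f"base residue {pos} not in matrix")
    candidates = [p for p in matrix.positions if p not in base_residues]
    results: list[LrtResult] = []
    failures: list[ScanFailure] = []
    status = matrix.status
    for cand in candidates:
        involved = base_residues + [cand]
        try:
            mask = matrix.valid_mask(involved)
            d_base = _design_for(matrix, base_residues, coding, mask, min_count)
            d_full = _design_for(matrix, involved, coding, mask, min_count)
            y = status[mask]
            f_base = fit_logistic(d_base, y)
            f_full = fit_logistic(d_full, y)
            if not f_base.converged:
                raise ValueError(f"base model: {f_base.message}")
            if not f_full.converged:
                raise ValueError(f"full model: {f_full.message}")
            res = lrt(f_base, f_full)
            res.position = cand
            res.base_residues = tuple(base_residues)
            res.n_samples = int(mask.sum())
            results.append(res)
        except (ValueError, RankDeficientDesignError, KeyError) as exc:
            failures.append(ScanFailure(position=cand, reason=str(exc)))
    results.sort(key=lambda r: (r.p, r.position))
    for rank, res in enumerate(results, start=1):
        res.rank = rank
    return ScanResult(results=results, failures=failures)
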