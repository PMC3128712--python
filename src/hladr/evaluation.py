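"""End-to-end benchmark experiments used by tests and the results script.

Each function runs one self-contained experiment through the package's
public API and returns plain numbers:

* reported-count epidemiology (carrier and allele odds ratios);
* synthetic-cohort scan properties (causal-residue recovery, conditional
  null behavior, p-value uniformity under the null);
* IRLS-vs-grid-search agreement on a fixed suite of toy designs;
* analytic validation of the linearized PB solver (Born ion, Coulomb
  limit, grid focusing, linearity);
* simulator calibration (allele frequencies, Hardy-Weinberg fit).

Independent oracles (closed forms, brute-force grid search) live here too
and deliberately share no code with the implementations they check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, kstest

from . import datasets
from .alignment import translate_cohort
from .association import dosage_design, fit_logistic, lrt, scan
from .epistats import (
    association_test,
    bonferroni,
    table_from_counts,
    woolf_or,
)
from .pqr import ChargeSystem
from .pb import (
    GridGeometry,
    SolverParams,
    boundary_potentials,
    build_maps,
    coulomb_constant,
    debye_kappa,
    focused_solve,
    grid_for_system,
    solve_lpb,
    solve_system,
    spread_charges,
)
from .simulate import demo_spec, generate_cohort, null_spec

BONFERRONI_SCAN = 0.05 / 30  # residue-scan significance over 30 residues


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Reported-count epidemiology
# ---------------------------------------------------------------------------

def reported_carrier_odds_ratios() -> dict[str, dict[str, float]]:
    """Uncorrected Woolf ORs from the published carrier counts at
    residues 37 and 86."""
    out = {}
    for (pos, aa), (cases, ctrls) in datasets.CARRIER_COUNTS.items():
        table = table_from_counts(
            cases, datasets.N_CASES, ctrls, datasets.N_CONTROLS,
            level="carrier", label=f"{aa}{pos}",
        )
        orr = woolf_or(table, correction="none")
        out[f"{aa}{pos}"] = {
            "or": orr.or_point, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
        }
    return out


def reported_allele_odds_ratios() -> dict[str, dict[str, float]]:
    """Haldane-corrected Woolf ORs and association p-values from the
    published chromosome counts of the Asn37-encoding alleles; also the
    uncorrected ORs (which differ visibly for 13:01 and 09:01)."""
    out = {}
    for allele, (cases, ctrls) in datasets.ASN37_ALLELE_COUNTS.items():
        table = table_from_counts(
            cases, 2 * datasets.N_CASES, ctrls, 2 * datasets.N_CONTROLS,
            level="allele", label=allele,
        )
        hald = woolf_or(table, correction="haldane")
        row = {
            "or_haldane": hald.or_point,
            "ci_low": hald.ci_low,
            "ci_high": hald.ci_high,
        }
        if min(table.cells) > 0:
            row["or_uncorrected"] = woolf_or(table, correction="none").or_point
        test = association_test(table)
        row["p"] = test.p
        row["p_bonferroni"] = bonferroni(test.p, datasets.N_ALLELES_OBSERVED)
        out[allele] = row
    return out


# ---------------------------------------------------------------------------
# Synthetic-cohort scan properties
# ---------------------------------------------------------------------------

@dataclass
class ScanRecoveryResult:
    n_replicates: int
    rank1_rate: float  # share of replicates ranking the causal residue first
    conditional_clean_rate: float  # share with no conditional hit at 0.05/30
    causal_position: int


def scan_recovery_experiment(
    n_replicates: int = 100, seed: int = 0, causal_position: int = 37
) -> ScanRecoveryResult:
    """Study-scale recovery experiment: per-copy log-OR ln 3 at residue 37.

    For each replicate, a 356/366 cohort is generated, the single-residue
    dosage scan is run (is the causal residue ranked first?), then the scan
    conditioned on the causal residue (does any other residue reach the
    30-residue Bonferroni threshold?).
    """
    rank1 = 0
    clean = 0
    for s in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(demo_spec(seed=s))
        matrix = translate_cohort(cohort, demo_spec(seed=s).table)
        single = scan(matrix, base_residues=(), coding="dosage")
        if single.top().position == causal_position:
            rank1 += 1
        conditional = scan(matrix, base_residues=(causal_position,), coding="dosage")
        if all(r.p >= BONFERRONI_SCAN for r in conditional.results):
            clean += 1
    return ScanRecoveryResult(
        n_replicates=n_replicates,
        rank1_rate=rank1 / n_replicates,
        conditional_clean_rate=clean / n_replicates,
        causal_position=causal_position,
    )


def null_scan_pvalues(
    n_replicates: int = 200, seed: int = 0, position: int = 37
) -> np.ndarray:
    """Single-residue scan p-values of one residue under the null spec,
    one independent replicate cohort each."""
    ps = []
    for s in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(null_spec(seed=s))
        matrix = translate_cohort(cohort, null_spec(seed=s).table)
        result = scan(matrix, base_residues=(), coding="dosage")
        ps.append(next(r.p for r in result.results if r.position == position))
    return np.array(ps)


def null_scan_ks(n_replicates: int = 200, seed: int = 0) -> float:
    """KS-test p-value for uniformity of the null scan p-values."""
    ps = null_scan_pvalues(n_replicates=n_replicates, seed=seed)
    return float(kstest(ps, "uniform").pvalue)


# ---------------------------------------------------------------------------
# IRLS vs brute-force grid search
# ---------------------------------------------------------------------------

#: Fixed 8-sample toy designs (one covariate each), none separated.
TOY_DESIGNS: list[tuple[list[float], list[int]]] = [
    ([0, 0, 0, 0, 1, 1, 1, 1], [0, 1, 0, 0, 1, 1, 0, 1]),
    ([0, 1, 0, 1, 0, 1, 0, 1], [0, 0, 1, 0, 1, 1, 0, 1]),
    ([0, 0, 1, 1, 1, 2, 2, 2], [0, 1, 0, 1, 0, 1, 0, 1]),
    ([0, 0, 1, 1, 0, 0, 1, 1], [1, 0, 0, 1, 1, 0, 1, 0]),
    ([0, 2, 1, 0, 2, 1, 0, 2], [0, 1, 1, 0, 1, 0, 1, 0]),
    ([1, 0, 1, 0, 1, 0, 1, 0], [1, 1, 0, 0, 1, 0, 0, 1]),
]


def grid_search_logistic(
    x: np.ndarray, y: np.ndarray, span: float = 8.0, steps: int = 41,
    refinements: int = 8,
) -> np.ndarray:
    """Brute-force ML estimate of (intercept, slope) by recursive grid
    refinement of the Bernoulli log-likelihood.  Independent of IRLS."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    center = np.zeros(2)
    width = span
    for _ in range(refinements):
        b0 = np.linspace(center[0] - width, center[0] + width, steps)
        b1 = np.linspace(center[1] - width, center[1] + width, steps)
        eta = (
            b0[:, None, None] + b1[None, :, None] * x[None, None, :]
        )
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        ll = (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        center = np.array([b0[i], b1[j]])
        width = width * 2.0 / (steps - 1) * 2.0  # keep a neighborhood margin
    return center


def irls_grid_agreement() -> float:
    """Max |IRLS - grid search| over the toy-design suite (both params)."""
    import pandas as pd

    worst = 0.0
    for x, y in TOY_DESIGNS:
        frame = pd.DataFrame({"const": np.ones(len(x)), "x": np.asarray(x, float)})
        fit = fit_logistic(frame, np.asarray(y))
        assert fit.converged, fit.message
        oracle = grid_search_logistic(np.asarray(x, float), np.asarray(y, float))
        worst = max(worst, float(np.abs(fit.params.to_numpy() - oracle).max()))
    return worst


# ---------------------------------------------------------------------------
# PB solver analytic validation
# ---------------------------------------------------------------------------

def born_screened_potential(
    r: np.ndarray, q: float, radius: float, params: SolverParams
) -> np.ndarray:
    """Closed-form linearized-PB potential of a single charged sphere.

    Three concentric regions: solute (eps_in, to radius+probe), ion-free
    Stern solvent shell (eps_out, to radius+stern) and screened bulk.
    Derived from continuity of the potential and dielectric flux.
    """
    r = np.asarray(r, dtype=float)
    C = coulomb_constant(params.temperature)
    kappa = debye_kappa(params)
    a = radius + params.probe_radius
    b = max(radius + params.stern_radius, a)
    c2 = -C * q * kappa / (params.eps_out * (1.0 + kappa * b))
    c1 = C * q / (params.eps_out * a) + c2 - C * q / (params.eps_in * a)
    phi = np.empty_like(r)
    inner = r <= a
    shell = (r > a) & (r <= b)
    bulk = r > b
    phi[inner] = C * q / (params.eps_in * r[inner]) + c1
    phi[shell] = C * q / (params.eps_out * r[shell]) + c2
    phi[bulk] = (
        C * q * np.exp(-kappa * (r[bulk] - b))
        / (params.eps_out * (1.0 + kappa * b) * r[bulk])
    )
    return phi


def _born_system(q: float = 1.0, radius: float = 2.0) -> ChargeSystem:
    return ChargeSystem(
        coords=np.zeros((1, 3)), charges=np.array([q]), radii=np.array([radius])
    )


def born_ion_benchmark(
    npts: int = 65, spacing: float = 0.4, r_eval=(6.0, 10.0), n_eval: int = 9
) -> dict[str, float]:
    """Max relative error of the FD solution vs the screened closed form
    along a ray at ``r_eval`` Angstrom from a Born ion (q=+1, radius 2)."""
    params = SolverParams(npts=npts)
    system = _born_system()
    geom = GridGeometry(center=(0.0, 0.0, 0.0), npts=npts, spacing=spacing)
    pmap = solve_system(system, params, geom)
    rs = np.linspace(r_eval[0], r_eval[1], n_eval)
    pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
    numeric = pmap.interpolate(pts)
    analytic = born_screened_potential(rs, 1.0, 2.0, params)
    rel = np.abs(numeric - analytic) / np.abs(analytic)
    return {
        "max_rel_err": float(rel.max()),
        "iterations": pmap.provenance["iterations"],
    }


def coulomb_uniform_benchmark(
    npts: int = 33, spacing: float = 1.0, span=(5, 10)
) -> float:
    """Uniform dielectric, no salt: max relative error vs plain Coulomb at
    ``span`` grid spacings from a unit charge."""
    params = SolverParams(
        eps_in=80.0, eps_out=80.0, ionic_strength=0.0, npts=npts
    )
    system = ChargeSystem(
        coords=np.zeros((1, 3)), charges=np.array([1.0]), radii=np.array([0.0])
    )
    geom = GridGeometry(center=(0.0, 0.0, 0.0), npts=npts, spacing=spacing)
    pmap = solve_system(system, params, geom)
    C = coulomb_constant(params.temperature)
    rs = np.arange(span[0], span[1] + 1) * spacing
    pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
    numeric = pmap.interpolate(pts)
    analytic = C / (80.0 * rs)
    return float(np.max(np.abs(numeric - analytic) / np.abs(analytic)))


def focusing_benchmark(npts: int = 65) -> dict[str, float]:
    """Born-ion analytic error of the focused fine solve vs the single
    coarse solve, along a near-field ray (inside the solute sphere, the
    region the focusing stage is meant to resolve)."""
    params = SolverParams(npts=npts)
    system = _born_system()
    coarse_geom = grid_for_system(system, params, params.fill_coarse)
    coarse = solve_system(system, params, coarse_geom)
    fine = focused_solve(system, params)

    rs = np.linspace(1.0, 2.2, 7)
    pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
    analytic = born_screened_potential(rs, 1.0, 2.0, params)
    err_coarse = float(
        np.max(np.abs(coarse.interpolate(pts) - analytic) / np.abs(analytic))
    )
    err_fine = float(
        np.max(np.abs(fine.interpolate(pts) - analytic) / np.abs(analytic))
    )
    return {"coarse_max_rel_err": err_coarse, "fine_max_rel_err": err_fine}


def linearity_benchmark(npts: int = 33) -> dict[str, float]:
    """Superposition and charge-negation antisymmetry on a two-atom system
    with a shared dielectric geometry."""
    params = SolverParams(npts=npts, tol=1e-7)
    coords = np.array([[-1.5, 0.0, 0.0], [1.5, 0.5, 0.0]])
    radii = np.array([1.5, 1.2])
    geometry = ChargeSystem(coords=coords, charges=[1.0, -0.5], radii=radii)
    geom = grid_for_system(geometry, params, 0.7)

    def solve_with(charges):
        return solve_system(geometry.with_charges(charges), params, geom).values

    both = solve_with([1.0, -0.5])
    first = solve_with([1.0, 0.0])
    second = solve_with([0.0, -0.5])
    negated = solve_with([-1.0, 0.5])
    return {
        "superposition_max_dev": float(np.abs(both - first - second).max()),
        "antisymmetry_max_dev": float(np.abs(both + negated).max()),
        "tol": params.tol,
    }


def pocket_sign_demo(npts: int = 33) -> dict[str, dict]:
    """Toy pocket: a charge buried 3 Angstrom beneath a surface patch.

    With q=+1 the patch classifies positive, with q=-1 negative; the mean
    patch potentials are returned with their labels.
    """
    from .pb import classify_pocket

    params = SolverParams(npts=npts)
    rng = np.arange(-1.0, 1.01, 0.5)
    gx, gy = np.meshgrid(rng, rng)
    patch = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, 3.0)])
    out = {}
    for sign, q in (("positive_charge", 1.0), ("negative_charge", -1.0)):
        system = ChargeSystem(
            coords=np.zeros((1, 3)), charges=np.array([q]), radii=np.array([2.0])
        )
        pmap = focused_solve(system, params)
        cls = classify_pocket(pmap, patch)
        out[sign] = {"mean_kT_e": cls.mean_potential, "label": cls.label}
    return out


# ---------------------------------------------------------------------------
# Simulator calibration
# ---------------------------------------------------------------------------

def control_frequency_max_z(seed: int = 0) -> float:
    """Max |z| between generated control allele frequencies and the spec
    frequencies (binomial SD), under the null spec at study size."""
    spec = null_spec(seed=seed)
    cohort = generate_cohort(spec)
    counts = {a: 0 for a in spec.alleles}
    for _, status, a, b in cohort.records:
        if status == 0:
            counts[a] += 1
            counts[b] += 1
    n_chrom = 2 * spec.n_controls
    worst = 0.0
    for allele, f in spec.allele_freqs.items():
        sd = math.sqrt(f * (1 - f) / n_chrom)
        z = abs(counts[allele] / n_chrom - f) / sd
        worst = max(worst, z)
    return worst


def hwe_goodness_of_fit(
    n_draws: int = 10_000, seed: int = 0
) -> dict[str, float]:
    """Chi-square GOF p of sampled diplotypes against Hardy-Weinberg
    expectations (cells with expected < 5 pooled); frequencies are known,
    so df = classes - 1."""
    spec = null_spec(seed=seed)
    rng = np.random.default_rng(seed)
    freqs = np.array(list(spec.allele_freqs.values()))
    k = len(freqs)
    ia = rng.choice(k, size=n_draws, p=freqs)
    ib = rng.choice(k, size=n_draws, p=freqs)
    lo = np.minimum(ia, ib)
    hi = np.maximum(ia, ib)
    observed: dict[tuple[int, int], int] = {}
    for i in range(k):
        for j in range(i, k):
            observed[(i, j)] = 0
    for a, b in zip(lo, hi):
        observed[(int(a), int(b))] += 1
    expected = {
        (i, j): n_draws * (freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j])
        for (i, j) in observed
    }
    obs_main, exp_main = [], []
    obs_pool = exp_pool = 0.0
    for key in observed:
        if expected[key] >= 5.0:
            obs_main.append(observed[key])
            exp_main.append(expected[key])
        else:
            obs_pool += observed[key]
            exp_pool += expected[key]
    if exp_pool > 0:
        obs_main.append(obs_pool)
        exp_main.append(exp_pool)
    obs_arr = np.array(obs_main, float)
    exp_arr = np.array(exp_main, float)
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = len(obs_arr) - 1
    return {"statistic": stat, "df": df, "p": float(chi2.sf(stat, df))}
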