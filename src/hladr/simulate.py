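"""Synthetic case-control HLA-DRB1 cohorts with residue-driven disease risk.

The population model is Hardy-Weinberg: a diplotype is two independent
draws from the allele-frequency pool.  Disease risk follows the allele
dosage model used by the association scan,

    logit P(case) = baseline + sum over (position, amino acid) of
                    effect * copy number,

and a case-control study is assembled by rejection sampling from that
population until both arms are full.  Everything is reproducible from the
seed carried by the spec.

The default demo spec mirrors the study conditions of the PSC cohort this
package models: 356 cases / 366 controls, a 10-allele pool at healthy
Northern-European control frequencies (Asn37-encoding alleles jointly at
0.26), and a per-copy risk effect of ln 3 for asparagine at residue 37.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .alignment import (
    AlleleSequenceTable,
    CohortGenotypes,
    normalize_allele_name,
    one_letter,
    parse_allele_table,
)
from . import datasets


@dataclass
class SimulationSpec:
    """Complete description of one simulated case-control study."""

    allele_freqs: dict[str, float]
    table: AlleleSequenceTable
    effects: dict[tuple[int, str], float]
    baseline: float
    n_cases: int
    n_controls: int
    seed: int
    draw_budget: int | None = None  # default: 1000 draws per required sample

    def __post_init__(self) -> None:
        self.allele_freqs = {
            normalize_allele_name(a): float(f) for a, f in self.allele_freqs.items()
        }
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total!r}, not 1")
        for a, f in self.allele_freqs.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"allele {a}: frequency {f} outside (0, 1]")
            if a not in self.table.entries:
                raise ValueError(f"allele {a} missing from the sequence table")
        self.effects = {
            (int(pos), one_letter(aa)): float(v)
            for (pos, aa), v in self.effects.items()
        }
        for pos, aa in self.effects:
            if pos not in self.table.positions:
                raise ValueError(f"causal residue {pos} not in the sequence table")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        self.seed = int(self.seed)

    @property
    def alleles(self) -> list[str]:
        return list(self.allele_freqs)

    def allele_scores(self) -> np.ndarray:
        """Per-allele log-odds contribution (sum of matching effects)."""
        scores = np.zeros(len(self.allele_freqs))
        for i, allele in enumerate(self.alleles):
            for (pos, aa), eff in self.effects.items():
                if self.table.residue(allele, pos) == aa:
                    scores[i] += eff
        return scores


def sample_diplotype(spec: SimulationSpec, rng: np.random.Generator) -> tuple[str, str]:
    """Two independent Hardy-Weinberg draws from the allele pool."""
    freqs = np.array(list(spec.allele_freqs.values()))
    i, j = rng.choice(len(freqs), size=2, p=freqs / freqs.sum())
    alleles = spec.alleles
    return alleles[i], alleles[j]


def disease_probability(spec: SimulationSpec, pair: tuple[str, str]) -> float:
    """Logistic disease probability of a diplotype under the dosage model."""
    a, b = (normalize_allele_name(x) for x in pair)
    logit = spec.baseline
    for (pos, aa), eff in spec.effects.items():
        dosage = int(spec.table.residue(a, pos) == aa) + int(
            spec.table.residue(b, pos) == aa
        )
        logit += eff * dosage
    return 1.0 / (1.0 + math.exp(-logit))


def generate_cohort(spec: SimulationSpec) -> CohortGenotypes:
    """Rejection-sample a case-control cohort; reproducible from the seed.

    Diplotypes are drawn from the population model and assigned Bernoulli
    disease status; draws are kept until both arms are full.  A pathological
    spec (disease probability ~0 or ~1 everywhere) exhausts the draw budget
    and aborts with a diagnostic.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array(list(spec.allele_freqs.values()))
    freqs = freqs / freqs.sum()
    scores = spec.allele_scores()
    alleles = spec.alleles
    budget = spec.draw_budget or 1000 * (spec.n_cases + spec.n_controls)

    cases: list[tuple[str, str]] = []
    controls: list[tuple[str, str]] = []
    drawn = 0
    chunk = 4096
    while len(cases) < spec.n_cases or len(controls) < spec.n_controls:
        if drawn >= budget:
            raise RuntimeError(
                f"draw budget of {budget} exhausted with "
                f"{len(cases)}/{spec.n_cases} cases and "
                f"{len(controls)}/{spec.n_controls} controls accrued; "
                "the spec's baseline/effects make one arm unreachable"
            )
        m = min(chunk, budget - drawn)
        ia = rng.choice(len(freqs), size=m, p=freqs)
        ib = rng.choice(len(freqs), size=m, p=freqs)
        logit = spec.baseline + scores[ia] + scores[ib]
        p = 1.0 / (1.0 + np.exp(-logit))
        is_case = rng.random(m) < p
        drawn += m
        for k in range(m):
            pair = (alleles[ia[k]], alleles[ib[k]])
            if is_case[k]:
                if len(cases) < spec.n_cases:
                    cases.append(pair)
            elif len(controls) < spec.n_controls:
                controls.append(pair)

    records = [(1, pair) for pair in cases] + [(0, pair) for pair in controls]
    order = rng.permutation(len(records))
    width = len(str(len(records)))
    out = []
    for row, k in enumerate(order, start=1):
        status, (a, b) = records[k]
        out.append((f"S{row:0{width}d}", status, a, b))
    return CohortGenotypes(records=out)


# ---------------------------------------------------------------------------
# Ready-made specs and flat-file serialization
# ---------------------------------------------------------------------------

#: Per-copy log-odds of the demo risk effect (odds ratio 3 per copy).
DEMO_EFFECT = math.log(3.0)
#: Baseline log-odds of disease (population prevalence 10% for non-carriers).
DEMO_BASELINE = math.log(0.1 / 0.9)


def demo_spec(
    seed: int,
    n_cases: int = datasets.N_CASES,
    n_controls: int = datasets.N_CONTROLS,
    effects: Mapping[tuple[int, str], float] | None = None,
    baseline: float = DEMO_BASELINE,
) -> SimulationSpec:
    """The study-scale demo spec: Asn37 risk effect of ln 3 per copy."""
    if effects is None:
        effects = {(37, "N"): DEMO_EFFECT}
    return SimulationSpec(
        allele_freqs=dict(datasets.DEMO_ALLELE_FREQS),
        table=datasets.demo_allele_table(),
        effects=dict(effects),
        baseline=baseline,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


def null_spec(seed: int, **kwargs) -> SimulationSpec:
    """Demo spec with no causal effects (the simulation null)."""
    kwargs.setdefault("effects", {})
    return demo_spec(seed, **kwargs)


def save_spec(spec: SimulationSpec, stream=None) -> str:
    """Serialize a spec to flat YAML (alignment embedded as TSV text)."""
    doc = {
        "alleles": {a: float(f) for a, f in spec.allele_freqs.items()},
        "effects": {f"{pos}:{aa}": float(v) for (pos, aa), v in spec.effects.items()},
        "baseline": float(spec.baseline),
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "seed": spec.seed,
        "alignment_tsv": spec.table.to_tsv(),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if stream is not None:
        stream.write(text)
    return text


def load_spec(stream) -> SimulationSpec:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    doc = yaml.safe_load(stream)
    effects = {}
    for key, v in (doc.get("effects") or {}).items():
        pos, _, aa = str(key).partition(":")
        effects[(int(pos), aa)] = float(v)
    return SimulationSpec(
        allele_freqs=doc["alleles"],
        table=parse_allele_table(doc["alignment_tsv"]),
        effects=effects,
        baseline=float(doc["baseline"]),
        n_cases=int(doc["n_cases"]),
        n_controls=int(doc["n_controls"]),
        seed=int(doc["seed"]),
    )
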