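# hladr

Residue-level case-control association analysis for **HLA-DRB1**, with a
desk-scale continuum-electrostatics stage for classifying the charge of the
HLA-DR peptide-binding pockets.

The package implements the analysis chain used to fine-map an HLA-DRB1
disease association — here, primary sclerosing cholangitis (PSC) — from the
allele level down to individual amino-acid positions of the DRβ1 chain, and
to interpret the hits physically through the electrostatics of the
peptide-binding groove. It is aimed at statistical geneticists and
immunogeneticists who have four-digit HLA typing for a case-control cohort
and want to ask *which residues* of the molecule drive the association, and
*what they do* to the binding pockets.

## What it computes

**Allele → residue translation** (`hladr.alignment`). An alignment table
maps each four-digit allele (e.g. `DRB1*13:01`) to its exon-2 amino-acid
sequence with explicit mature-protein numbering. Every individual is
assigned two amino acids (one per chromosome) at each polymorphic residue.

**Conditional likelihood-ratio scan** (`hladr.association`). For each
polymorphic residue *r*, a logistic regression of case-control status is
fitted under the *allele dosage* coding — one covariate per non-reference
amino acid *a*, holding its copy number d<sub>a</sub> ∈ {0,1,2}:

    logit P(case) = β₀ + Σ_a β_a d_a

and the overall residue effect is the likelihood-ratio chi-square
2(ℓ₁ − ℓ₀) against the model without residue *r*, on as many degrees of
freedom as covariates added. Conditioning on already-accepted residues
gives the stepwise two- and three-residue scans. A *genotype* coding (one
indicator per unordered amino-acid pair, pairs with n < 2 in cases or
controls pooled) serves as a model check. Fits use in-package IRLS;
separation and collinearity are surfaced, never silently absorbed.

**2×2 epidemiology** (`hladr.epistats`). Carrier-level (individuals with
≥ 1 copy) and allele-level (chromosome) contingency tables; odds ratios
with Woolf's 95% CI, exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), with
Haldane's +0.5-per-cell correction available for tables with empty cells;
Pearson chi-square (no continuity correction) or two-sided Fisher exact
p-values; Bonferroni correction over the number of alleles observed.

**Cohort simulator** (`hladr.simulate`). Hardy-Weinberg diplotypes from a
frequency pool, logistic disease risk on amino-acid dosage, case-control
ascertainment by rejection sampling — fully reproducible from a seed. The
default spec mirrors the PSC study scale: 356 cases / 366 controls and a
per-copy odds ratio of 3 for Asn at residue 37.

**Pocket electrostatics** (`hladr.pqr`, `hladr.pb`, `hladr.dx`). A
finite-difference linearized Poisson-Boltzmann solver: protein dielectric
2 inside a probe-inflated (1.4 Å) atomic surface, water dielectric 80,
0.145 M monovalent salt outside a 2 Å Stern layer, Debye-Hückel boundary
conditions, and two-stage 50% → 90% grid focusing. Potentials are in kT/e;
a pocket patch is classified positive/neutral/negative at the ±5 kT/e
surface-coloring convention. I/O: PQR structures in, OpenDX maps out.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
cohort (no patient-level genotypes are published for the original study;
the simulator stands in for them):

```bash
python analysis/01_simulate_cohort.py   # cohort.csv + alignment.tsv
python analysis/02_residue_scan.py      # stepwise LR scan tables
python analysis/03_allele_epistats.py   # carrier/allele odds ratios
python analysis/04_pocket_potentials.py # PB validation + pocket classes
```

Step 02 prints, for the default seed:

```
single-residue dosage scan: residue 37 ranks first (LR=80.4, df=4, p=1.43e-16)
conditioned on residue 37: best remaining residue 26 (p=0.0216); 0 residue(s) beyond the 0.05/30 threshold
```

— the simulated causal residue (37) tops the scan, and once it is in the
model no other residue survives the 30-residue Bonferroni threshold, i.e.
the conditional scan correctly reports a single independent signal.
Step 03 reproduces the published summary statistics from the reported
counts:

```
  N37: OR = 5.68 (95% CI 4.04-7.98)        # carrier level, uncorrected
  DRB1*13:02: OR = 0.39 (95% CI 0.21-0.71), p = 0.00126, corrected p = 0.0403
```

and step 04 validates the solver and classifies a toy pocket:

```
Born ion (q=+1, r=2 A, 65^3 grid): max analytic error 3.28% at 6-10 A
buried +1e: mean patch potential +7.20 kT/e -> positive
buried -1e: mean patch potential -7.20 kT/e -> negative
```

A thin CLI exposes the same stages: `hladr simulate`, `hladr epistats`,
`hladr pbsolve` (all solver parameters as flags; `--npts 251` reproduces
the full-protocol grid).

## Layout

```
src/hladr/      library (all computation lives here)
analysis/       numbered narrative drivers writing to results/
tests/          pytest suite (unit, property and end-to-end checks)
scripts/        acceptance.py
docs/methods.md model, parameter and design notes
```
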