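# Methods notes

## Statistical model

Case-control status is modeled by logistic regression on amino-acid
content of the DRβ1 chain. Under the **allele dosage** coding, the
covariates for residue *r* are the copy numbers (0/1/2) of every amino
acid observed there except a reference; the per-copy effect is additive on
the log-odds scale, so a homozygote carries twice the log-odds
contribution of a heterozygote. The **genotype** coding relaxes
additivity: one indicator per observed unordered amino-acid pair, with one
pair as reference. The overall effect of a residue is tested by the
likelihood-ratio chi-square between nested fits (with and without the
residue's block), with degrees of freedom equal to the number of columns
added. Stepwise conditioning — scanning every residue on top of one or two
already-accepted residues — separates independent signals from signals
explained by linkage between alleles.

Reference categories are formally arbitrary: the LR statistic is invariant
to the choice (enforced by a property test that permutes references). We
pick the most frequent amino acid / pair deterministically, rather than
randomly, so that runs are bit-reproducible; this is a deliberate change
from picking at random, which has the same sampling properties but not the
same reproducibility.

### Rare genotype pooling

Under the genotype coding, pairs with a count below 2 in cases **or** in
controls at a residue are pooled into a single "rare" category (the
literal reading of the rule; an alternative reading — below 2 in the
combined sample — would pool less). If the pooled category itself still
has fewer than 2 in an arm, it is merged into the reference category with
a warning; this avoids empty cells at the price of diluting the reference,
and happens only at very skewed residues.

### Logistic fits

Maximum likelihood is computed by iteratively reweighted least squares:
start at β = 0, update β ← (XᵀWX)⁻¹XᵀWz with W = diag(μ(1−μ)) and working
response z = Xβ + (y−μ)/W. Convergence is declared when the relative
change of the Bernoulli log-likelihood falls below 1e-10, capped at 100
iterations. Rank deficiency is detected up front by pivoted QR and raised
with the offending column labels (in the conditional scans this is the
normal signature of a candidate residue whose coding is a linear function
of the base residue's columns — those candidates are recorded as failures
and excluded from the ranking, they never abort a scan). Complete
separation is flagged by coefficient divergence (|β| > 15 on the log-odds
scale ≈ OR 3×10⁶) and reported as non-convergence; the scan treats it as a
failure rather than reporting an inflated statistic. No multiple-testing
correction is applied to scan p-values (they are reported raw, ranked);
the Bonferroni factor of 32 (alleles observed) applies only to the
allele-level 2×2 tests.

## 2×2 conventions

Two correction conventions coexist deliberately, matching how such tables
are conventionally reported: carrier-level odds ratios are computed
without continuity correction (all cells are large), while allele-level
tables — which can contain zero cells for rare alleles — use Haldane's
+0.5 on all four cells inside Woolf's formula, applied always, not only
when a zero occurs. The API therefore takes `correction` explicitly and
infers nothing. "Chi-square or Fisher where appropriate" is
operationalized by Cochran's rule: Pearson chi-square without continuity
correction when every expected cell is ≥ 5, otherwise a two-sided Fisher
exact test (sum of tables at most as probable as observed — the dominant
two-sided convention; the mid-p and tail-doubling variants would differ in
the third decimal on these tables).

One reproducibility caveat: for the zero-cell allele table (0, 712, 1,
731) the Woolf/Haldane formula gives an upper confidence limit near 44,
not the published 3.8; the published limit cannot be obtained from the
formula as stated alongside it (an exact or mid-p interval is the likely
source). The formula is implemented as stated and the discrepancy is left
documented rather than patched.

## Cohort simulator

The simulator emulates a two-arm association study at the scale of the PSC
cohort the package models: 356 cases / 366 controls, ten DRB1 alleles at
healthy-Northern-European control magnitudes (Asn37-encoding alleles
jointly at frequency 0.26), baseline disease prevalence 10%, and a
per-copy log-odds of ln 3 for Asn37 — the size of effect implied by the
reported carrier odds ratios. Diplotypes are Hardy-Weinberg (two
independent draws); ascertainment is by rejection sampling from the
population model, which is exact and cheap at this scale (logistic
inversion would avoid the rejection loop but approximates the
case-control likelihood). A draw budget of 1000 × (n_cases + n_controls)
aborts pathological specs with a diagnostic.

The ten-allele pool covers carriers of all five amino acids observed at
residue 37 (Asn/Tyr/Ser/Phe/Leu) and both at 86 (Gly/Val), including the
13:01/13:02 pair that differs only at residue 86. Residues other than
37/86 in the bundled alignment are plausible synthetic values, not an
IMGT extract; they produce realistic linkage between residues (including
exact collinearities in conditional scans, which exercise the failure
path). What the synthetic data deliberately lacks: linkage to other loci
(DQ, DRB3/4/5), population stratification, covariates (age/sex), and
genotyping error — so passing tests demonstrate the statistics are
implemented correctly at study scale, not that the method is robust to
those real-data complications.

## Linearized Poisson-Boltzmann solver

The solver targets the standard DelPhi-style protocol for surface
potentials of MHC molecules. Model: linearized PB,
∇·(ε∇φ) − ε_s κ² φ = −4πCρ, with φ in kT/e, lengths in Å, charges in e,
and C = e²/(4πε₀ k_B T·Å) (≈ 560.7 at 298.15 K). Defaults: ε_in = 2,
ε_s = 80, ionic strength 0.145 mol/L monovalent, T = 298.15 K (the
physiological-pH protocol does not fix a temperature; one must be
chosen and is exposed as a parameter), probe 1.4 Å, Stern ion radius 2 Å,
251 grid points per axis at the full protocol (tests and examples use
65³ and 33³ grids, which already reach percent-level analytic accuracy —
the 251³ grid is supported via `npts` but not exercised routinely).

Geometry: the solute interior is the union of atom spheres inflated by the
probe radius — a van-der-Waals/probe union, not a true rolling-probe
re-entrant surface; for isolated spheres (all validation geometries) the
two coincide, for multi-atom crevices the union is slightly generous. The
ion-exclusion (Stern) region extends to atom radius + ion radius. Grid
sizing for the focusing stages is based on the *structured* extent (atom
radius + probe + Stern), so every non-bulk node is on-grid; the fill
fraction is applied to that extent.

Discretization: node dielectrics, harmonic-mean face dielectrics (flux
continuity across the dielectric jump), trilinear charge spreading, and
the screening term ε_s κ² at ion-accessible nodes with κ from the stated
constants (Debye length ≈ 8.06 Å at defaults — computed, not assumed).
Boundaries are Debye-Hückel sums Σ C q_i e^{−κr_i}/(ε_s r_i). Relaxation
is red-black Gauss-Seidel with over-relaxation (ω = 2/(1+sin(π/n)) unless
overridden), converged when the largest applied node update falls below
1e-6 kT/e (default), hard-capped at 10⁴ iterations with the update history
attached to the error. Focusing solves coarse (solute fills 50% of the
box) then fine (90%), with fine-boundary values trilinearly interpolated
from the coarse map.

Numerical caveats worth knowing:

* The Debye-Hückel boundary form is a point-charge approximation: for a
  finite ion with a Stern layer the true far field carries an extra factor
  e^{κb}/(1+κb). On small boxes this contributes a percent-scale floor to
  the error that does not shrink with grid refinement — which is why the
  refinement-ladder test runs salt-free (where the boundary form is exact
  and convergence is cleanly monotone), while the salted Born-ion check is
  judged against a 10% band on a larger box.
* Region membership at a node exactly on a sphere boundary is inclusive,
  with a 1e-9 Å² tolerance on the squared distance, so tie nodes land
  deterministically.
* Protonation/pKa assignment is out of scope: input charges are taken as
  given in the PQR file. Pocket-patch geometry is likewise an input (a
  3-column coordinate file); the classifier makes no attempt to derive
  patches from structure.

Pocket classification thresholds at ±5 kT/e follow the surface-coloring
convention for these molecules; the classifier reports the mean trilinear
potential over the patch and the resulting label.

## Problem sizes used in examples and checks

Synthetic scan experiments use 100 replicates (recovery and conditional
null) and 200 replicates (null uniformity) at the full 356/366 study size;
Hardy-Weinberg calibration uses 10⁴ diplotype draws; PB validation uses
65³ grids for the Born/focusing benchmarks and 33³ for linearity and the
pocket demonstrations. These sizes give stable rates (recovery and
clean-conditioning rates vary by ≤ 2 percentage points across seeds) while
keeping a full run in the minutes range on one CPU.
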