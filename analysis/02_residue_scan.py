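#!/usr/bin/env python
"""Stepwise conditional LR scan of the synthetic cohort.

Runs the single-residue dosage scan over all polymorphic residues, then
the two-residue scan conditioned on the top residue, then the
three-residue scan conditioned on the top two, and finally repeats the
single-residue scan under the genotype coding as a model check.  Writes
ranked tables under results/ and prints the headline findings.
"""

import warnings
from pathlib import Path

from hladr.alignment import CohortGenotypes, parse_allele_table, translate_cohort
from hladr.association import scan

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run_and_save(matrix, base, coding, name):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare-category merges are expected
        result = scan(matrix, base_residues=base, coding=coding)
    frame = result.to_frame()
    frame.to_csv(RESULTS / name, sep="\t", index=False, float_format="%.4g")
    return result


def main() -> None:
    with open(RESULTS / "cohort.csv") as fh:
        cohort = CohortGenotypes.from_csv(fh)
    with open(RESULTS / "alignment.tsv") as fh:
        table = parse_allele_table(fh)
    matrix = translate_cohort(cohort, table)
    print(f"{len(matrix.positions)} polymorphic residues in "
          f"{matrix.n_samples} samples: {matrix.positions}")

    single = run_and_save(matrix, (), "dosage", "scan_single_dosage.tsv")
    top = single.top()
    print(f"\nsingle-residue dosage scan: residue {top.position} ranks first "
          f"(LR={top.statistic:.1f}, df={top.df}, p={top.p:.3g})")

    conditional = run_and_save(
        matrix, (top.position,), "dosage", "scan_conditional_dosage.tsv"
    )
    second = conditional.top()
    threshold = 0.05 / 30
    n_hits = sum(r.p < threshold for r in conditional.results)
    print(f"conditioned on residue {top.position}: best remaining residue "
          f"{second.position} (p={second.p:.3g}); "
          f"{n_hits} residue(s) beyond the 0.05/30 threshold")
    if conditional.failures:
        for f in conditional.failures:
            print(f"  excluded residue {f.position}: {f.reason}")

    base2 = (top.position, second.position)
    three = run_and_save(matrix, base2, "dosage", "scan_three_residue_dosage.tsv")
    n_hits3 = sum(r.p < threshold for r in three.results)
    print(f"conditioned on residues {base2}: {n_hits3} residue(s) beyond "
          f"the threshold (expected 0: only residue {top.position} is causal)")

    genotype = run_and_save(matrix, (), "genotype", "scan_single_genotype.tsv")
    gtop = genotype.top()
    print(f"\ngenotype-model check: residue {gtop.position} ranks first "
          f"(p={gtop.p:.3g}) — same top residue as the dosage model"
          if gtop.position == top.position
          else f"\ngenotype-model check: top residue {gtop.position} "
               f"differs from dosage top {top.position}")
    print(f"\nwrote 4 scan tables to {RESULTS}")


if __name__ == "__main__":
    main()
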