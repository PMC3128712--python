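"""Bundled reference data.

Two kinds of data live here:

* A small **synthetic** HLA-DRB1 exon-2 alignment and allele-frequency pool
  used by the cohort simulator and the worked examples.  Residues 37 and 86
  (and the fact that DRB1*13:01 and DRB1*13:02 differ only at residue 86)
  follow the published DRB1 protein alignment; the remaining columns are
  plausible synthetic values, not an IMGT extract.

* Published summary counts from a Scandinavian primary sclerosing
  cholangitis (PSC) case-control cohort (356 patients / 366 controls) at
  DR beta-1 residues 37 and 86: carrier counts, chromosome-level amino-acid
  counts, and chromosome counts of the Asn37-encoding alleles.  These are
  the inputs to the carrier/allele odds-ratio analyses.
"""

from __future__ import annotations

from .alignment import AlleleSequenceTable, parse_allele_table

# ---------------------------------------------------------------------------
# Synthetic demo alignment (positions are mature-protein numbers, exon 2)
# ---------------------------------------------------------------------------

DEMO_ALIGNMENT_TSV = """\
# Synthetic HLA-DRB1 exon-2 alignment (one-letter residues).
# Residues 37 and 86 follow the published DRB1 protein alignment;
# other columns are plausible synthetic values.
allele\t9\t11\t13\t26\t28\t30\t37\t47\t57\t67\t70\t71\t74\t86
DRB1*01:01\tW\tL\tF\tL\tD\tC\tS\tY\tD\tL\tQ\tR\tA\tG
DRB1*03:01\tE\tS\tS\tY\tD\tY\tN\tY\tD\tL\tQ\tK\tR\tV
DRB1*04:01\tE\tV\tH\tF\tD\tY\tY\tY\tD\tL\tQ\tK\tA\tG
DRB1*07:01\tW\tG\tY\tF\tD\tL\tF\tF\tV\tI\tD\tR\tQ\tG
DRB1*09:01\tK\tD\tH\tF\tD\tR\tN\tF\tV\tF\tR\tR\tE\tG
DRB1*11:01\tE\tS\tS\tF\tD\tY\tY\tF\tD\tF\tD\tR\tA\tV
DRB1*12:01\tE\tS\tS\tL\tE\tH\tL\tY\tD\tI\tD\tR\tA\tG
DRB1*13:01\tE\tS\tS\tF\tD\tY\tN\tF\tD\tI\tD\tE\tA\tV
DRB1*13:02\tE\tS\tS\tF\tD\tY\tN\tF\tD\tI\tD\tE\tA\tG
DRB1*15:01\tE\tP\tR\tF\tD\tY\tS\tF\tD\tI\tQ\tA\tA\tV
"""

#: Population allele frequencies of the demo pool (sum to 1).  Magnitudes
#: mirror the healthy-control frequencies of a Northern European population
#: (e.g. Asn37-encoding alleles jointly at 0.26).
DEMO_ALLELE_FREQS: dict[str, float] = {
    "DRB1*01:01": 0.10,
    "DRB1*03:01": 0.14,
    "DRB1*04:01": 0.16,
    "DRB1*07:01": 0.11,
    "DRB1*09:01": 0.01,
    "DRB1*11:01": 0.12,
    "DRB1*12:01": 0.02,
    "DRB1*13:01": 0.06,
    "DRB1*13:02": 0.05,
    "DRB1*15:01": 0.23,
}


def demo_allele_table() -> AlleleSequenceTable:
    """Parse and return the bundled synthetic demo alignment."""
    return parse_allele_table(DEMO_ALIGNMENT_TSV)


# ---------------------------------------------------------------------------
# Published PSC case-control summary counts (DR beta-1 residues 37 and 86)
# ---------------------------------------------------------------------------

#: Individuals genotyped per arm.
N_CASES = 356
N_CONTROLS = 366

#: (position, amino acid) -> (case carriers, control carriers):
#: individuals with at least one copy.
CARRIER_COUNTS: dict[tuple[int, str], tuple[int, int]] = {
    (37, "N"): (292, 163),
    (37, "L"): (4, 15),
    (37, "F"): (34, 62),
    (37, "S"): (162, 175),
    (37, "Y"): (80, 197),
    (86, "G"): (164, 284),
    (86, "V"): (335, 282),
}

#: (position, amino acid) -> (case chromosomes, control chromosomes)
#: out of 2n = 712 / 732.
ALLELE_AA_COUNTS: dict[tuple[int, str], tuple[int, int]] = {
    (37, "N"): (398, 199),
    (37, "L"): (4, 16),
    (37, "F"): (35, 67),
    (37, "S"): (192, 208),
    (37, "Y"): (83, 242),
    (86, "G"): (185, 368),
    (86, "V"): (527, 364),
}

#: Chromosome counts of the Asn37-encoding alleles
#: (case chromosomes of 712, control chromosomes of 732).
ASN37_ALLELE_COUNTS: dict[str, tuple[int, int]] = {
    "DRB1*03:01": (254, 106),
    "DRB1*09:01": (12, 6),
    "DRB1*13:01": (117, 47),
    "DRB1*13:02": (15, 39),
    "DRB1*14:02": (0, 1),
}

#: Number of distinct DRB1 alleles observed in the study dataset; the
#: Bonferroni factor for novel allele associations.
N_ALLELES_OBSERVED = 32
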