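"""Allele alignment tables and residue-level translation of HLA-DRB1 cohorts.

The second exon of *HLA-DRB1* encodes the polymorphic part of the DR beta
chain.  Given (i) an alignment table mapping each four-digit allele to its
exon-2 amino-acid sequence with explicit mature-protein position numbering
and (ii) a case-control cohort of diplotypes, every individual can be
assigned two amino acids (one per chromosome) at each polymorphic residue.
That per-residue genotype matrix is the substrate of all downstream
association analyses.

File dialects
-------------
Alignment TSV: first column ``allele``; remaining column headers are integer
residue positions; cell values are single characters; ``-`` means
"same as the reference" (the first data row), following the IMGT alignment
convention; lines starting with ``#`` are comments.

Cohort CSV: header ``sample_id,status,allele1,allele2`` with ``status`` in
{0, 1} (1 = case).
"""

from __future__ import annotations

import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: One-letter codes of the 20 standard amino acids.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: Marker for an unknown / unresolved residue.
UNKNOWN_RESIDUE = "X"

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "XAA": "X",
}
_AA_1TO3 = {v: k.capitalize() for k, v in _AA_3TO1.items()}


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment tables or cohort files."""


def one_letter(aa: str) -> str:
    """Normalize an amino-acid code (``Asn``/``ASN``/``N``) to one letter."""
    aa = aa.strip()
    if len(aa) == 1:
        code = aa.upper()
    else:
        try:
            code = _AA_3TO1[aa.upper()]
        except KeyError:
            raise AlignmentFormatError(f"unknown amino-acid code {aa!r}") from None
    if code not in AMINO_ACIDS and code != UNKNOWN_RESIDUE:
        raise AlignmentFormatError(f"unknown amino-acid code {aa!r}")
    return code


def three_letter(aa: str) -> str:
    """One-letter code to conventional three-letter spelling (``N`` -> ``Asn``)."""
    return _AA_1TO3[one_letter(aa)]


_LEGACY = re.compile(r"^\d{4,5}$")


def normalize_allele_name(name: str, default_locus: str = "DRB1") -> str:
    """Normalize an HLA allele spelling to colon form, e.g. ``DRB1*13:01``.

    Accepts both the colon style (``DRB1*13:01``) and the legacy four-digit
    style (``DRB1*1301`` or bare ``1301``).  A missing locus prefix is filled
    with *default_locus*.
    """
    name = name.strip()
    if not name:
        raise AlignmentFormatError("empty allele name")
    if "*" in name:
        locus, _, fields = name.partition("*")
        locus = locus.strip().upper() or default_locus
    else:
        locus, fields = default_locus, name
    fields = fields.strip().upper()
    if not fields:
        raise AlignmentFormatError(f"allele name {name!r} has no allele fields")
    if ":" not in fields and _LEGACY.match(fields):
        # legacy concatenated digits: first two digits are the allele group
        fields = f"{fields[:2]}:{fields[2:]}"
    return f"{locus}*{fields}"


@dataclass
class AlleleSequenceTable:
    """Aligned exon-2 residue strings for a set of alleles.

    positions : ordered mature-protein residue numbers (one per column)
    entries   : normalized allele name -> one-letter residue string, all the
                same length as ``positions``
    """

    positions: list[int]
    entries: dict[str, str]

    def __post_init__(self) -> None:
        npos = len(self.positions)
        if len(set(self.positions)) != npos:
            raise AlignmentFormatError("duplicate residue positions in table")
        for allele, seq in self.entries.items():
            if len(seq) != npos:
                raise AlignmentFormatError(
                    f"allele {allele}: sequence length {len(seq)} != "
                    f"{npos} positions"
                )
            bad = set(seq) - AMINO_ACIDS - {UNKNOWN_RESIDUE}
            if bad:
                raise AlignmentFormatError(
                    f"allele {allele}: invalid residue character(s) {sorted(bad)}"
                )
        self._colindex = {p: i for i, p in enumerate(self.positions)}

    def __contains__(self, allele: str) -> bool:
        return normalize_allele_name(allele) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def alleles(self) -> list[str]:
        return list(self.entries)

    def residue(self, allele: str, position: int) -> str:
        """One-letter amino acid of *allele* at mature-protein *position*."""
        allele = normalize_allele_name(allele)
        try:
            seq = self.entries[allele]
        except KeyError:
            raise KeyError(f"allele {allele} not in table") from None
        try:
            return seq[self._colindex[position]]
        except KeyError:
            raise KeyError(f"position {position} not in table") from None

    def to_tsv(self) -> str:
        """Serialize in the alignment TSV dialect (explicit characters)."""
        out = io.StringIO()
        out.write("allele\t" + "\t".join(str(p) for p in self.positions) + "\n")
        for allele, seq in self.entries.items():
            out.write(allele + "\t" + "\t".join(seq) + "\n")
        return out.getvalue()


def parse_allele_table(stream) -> AlleleSequenceTable:
    """Parse an allele-alignment table from a text stream or string.

    The first data row is the reference against which ``-`` (identity)
    characters in later rows are expanded.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows: list[tuple[str, list[str]]] = []
    positions: list[int] | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if positions is None:
            if cells[0].strip().lower() != "allele":
                raise AlignmentFormatError(
                    f"line {lineno}: header must start with 'allele'"
                )
            try:
                positions = [int(c) for c in cells[1:]]
            except ValueError:
                raise AlignmentFormatError(
                    f"line {lineno}: non-integer position in header"
                ) from None
            continue
        name = normalize_allele_name(cells[0])
        chars = [c.strip() for c in cells[1:]]
        if len(chars) != len(positions):
            raise AlignmentFormatError(
                f"allele {name}: row has {len(chars)} residue columns, "
                f"expected {len(positions)}"
            )
        rows.append((name, chars))
    if positions is None:
        raise AlignmentFormatError("no header row found")
    if not rows:
        raise AlignmentFormatError("no allele rows found")

    entries: dict[str, str] = {}
    ref_name, ref_chars = rows[0]
    if "-" in ref_chars:
        raise AlignmentFormatError(
            f"reference allele {ref_name} may not contain '-' characters"
        )
    for name, chars in rows:
        if name in entries:
            raise AlignmentFormatError(f"duplicate allele name {name}")
        expanded = []
        for i, c in enumerate(chars):
            c = c if c != "-" else ref_chars[i]
            c = one_letter(c)
            expanded.append(c)
        entries[name] = "".join(expanded)
    return AlleleSequenceTable(positions=list(positions), entries=entries)


@dataclass
class CohortGenotypes:
    """A case-control cohort of four-digit HLA-DRB1 diplotypes.

    records : (sample_id, status, allele_a, allele_b) with status 1 = case.
    """

    records: list[tuple[str, int, str, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sample ids: {dupes[:5]}")
        normed = []
        for sid, status, a, b in self.records:
            status = int(status)
            if status not in (0, 1):
                raise AlignmentFormatError(
                    f"sample {sid}: status must be 0 or 1, got {status}"
                )
            normed.append(
                (str(sid), status, normalize_allele_name(a), normalize_allele_name(b))
            )
        self.records = normed

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def status(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=np.int8)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return len(self) - self.n_cases

    def allele_multiset(self) -> Counter:
        """Chromosome-level allele counts across the cohort."""
        c: Counter = Counter()
        for _, _, a, b in self.records:
            c[a] += 1
            c[b] += 1
        return c

    @classmethod
    def from_csv(cls, stream) -> "CohortGenotypes":
        df = pd.read_csv(stream, dtype={"sample_id": str})
        required = ["sample_id", "status", "allele1", "allele2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise AlignmentFormatError(f"cohort CSV missing column(s) {missing}")
        records = [
            (row.sample_id, int(row.status), row.allele1, row.allele2)
            for row in df.itertuples(index=False)
        ]
        return cls(records=records)

    def to_csv(self) -> str:
        out = io.StringIO()
        out.write("sample_id,status,allele1,allele2\n")
        for sid, status, a, b in self.records:
            out.write(f"{sid},{status},{a},{b}\n")
        return out.getvalue()


@dataclass
class ResidueProfile:
    """Per-position amino-acid multisets over a set of alleles."""

    counts: dict[int, Counter]
    polymorphic: list[int]

    def is_polymorphic(self, position: int) -> bool:
        return position in self._polyset

    def __post_init__(self) -> None:
        self._polyset = set(self.polymorphic)


def find_polymorphic_positions(
    table: AlleleSequenceTable, alleles_present: Iterable[str]
) -> ResidueProfile:
    """Profile residue variability over the alleles present in a dataset.

    A position is polymorphic when two or more distinct known (non-``X``)
    amino acids are observed among *alleles_present*.
    """
    alleles = {normalize_allele_name(a) for a in alleles_present}
    if not alleles:
        raise ValueError("empty allele set")
    unknown = sorted(a for a in alleles if a not in table.entries)
    if unknown:
        raise KeyError(f"allele(s) not in table: {unknown}")
    counts: dict[int, Counter] = {}
    poly: list[int] = []
    for i, pos in enumerate(table.positions):
        c = Counter(table.entries[a][i] for a in sorted(alleles))
        counts[pos] = c
        distinct = set(c) - {UNKNOWN_RESIDUE}
        if len(distinct) >= 2:
            poly.append(pos)
    return ResidueProfile(counts=counts, polymorphic=poly)


@dataclass
class ResidueGenotypeMatrix:
    """Unordered amino-acid pairs per individual at each polymorphic residue.

    ``chrom_a``/``chrom_b`` hold the one-letter residues carried on the two
    chromosomes (columns follow ``positions``); ``valid`` is False where a
    sample carries an allele with an unknown residue at that position, in
    which case the sample is excluded from analyses of that position only.
    """

    sample_ids: list[str]
    status: np.ndarray
    positions: list[int]
    chrom_a: np.ndarray  # (n_samples, n_positions) of '<U1'
    chrom_b: np.ndarray
    valid: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self._col = {p: j for j, p in enumerate(self.positions)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def _j(self, position: int) -> int:
        try:
            return self._col[position]
        except KeyError:
            raise KeyError(f"position {position} not in matrix") from None

    def valid_mask(self, positions: Sequence[int]) -> np.ndarray:
        """Samples fully observed at every position in *positions*."""
        if not positions:
            return np.ones(self.n_samples, dtype=bool)
        cols = [self._j(p) for p in positions]
        return self.valid[:, cols].all(axis=1)

    def pair(self, sample_index: int, position: int) -> tuple[str, str] | None:
        j = self._j(position)
        if not self.valid[sample_index, j]:
            return None
        a, b = self.chrom_a[sample_index, j], self.chrom_b[sample_index, j]
        return tuple(sorted((a, b)))  # order-insensitive

    def dosage(self, position: int, amino_acid: str) -> np.ndarray:
        """Copy number (0/1/2) of *amino_acid* at *position* per sample.

        Excluded samples get 0; mask with :meth:`valid_mask` before use.
        """
        aa = one_letter(amino_acid)
        j = self._j(position)
        d = (self.chrom_a[:, j] == aa).astype(np.int8)
        d += (self.chrom_b[:, j] == aa).astype(np.int8)
        d[~self.valid[:, j]] = 0
        return d

    def amino_acids(self, position: int, mask: np.ndarray | None = None) -> list[str]:
        """Distinct known amino acids observed at *position*, sorted."""
        j = self._j(position)
        use = self.valid[:, j] if mask is None else (mask & self.valid[:, j])
        observed = set(self.chrom_a[use, j]) | set(self.chrom_b[use, j])
        return sorted(observed - {UNKNOWN_RESIDUE})

    def allele_counts(self, position: int, mask: np.ndarray | None = None) -> Counter:
        """Chromosome-level amino-acid counts at *position*."""
        j = self._j(position)
        use = self.valid[:, j] if mask is None else (mask & self.valid[:, j])
        c = Counter(self.chrom_a[use, j])
        c.update(self.chrom_b[use, j])
        return c

    def n_excluded(self, position: int) -> int:
        return int((~self.valid[:, self._j(position)]).sum())


def translate_cohort(
    cohort: CohortGenotypes, table: AlleleSequenceTable
) -> ResidueGenotypeMatrix:
    """Assign each individual two amino acids per polymorphic residue.

    Positions are those polymorphic among the alleles actually present in
    the cohort.  Samples carrying an allele with an unknown residue (``X``)
    at a position are flagged invalid at that position only.
    """
    present = set(cohort.allele_multiset())
    unknown = sorted(a for a in present if a not in table.entries)
    if unknown:
        raise KeyError(f"cohort allele(s) missing from alignment table: {unknown}")
    profile = find_polymorphic_positions(table, present)
    positions = profile.polymorphic
    cols = [table.positions.index(p) for p in positions]

    allele_index = {a: i for i, a in enumerate(table.alleles)}
    seq_matrix = np.array(
        [[seq[c] for c in cols] for seq in table.entries.values()], dtype="<U1"
    )
    ia = np.array([allele_index[r[2]] for r in cohort.records])
    ib = np.array([allele_index[r[3]] for r in cohort.records])
    chrom_a = seq_matrix[ia]
    chrom_b = seq_matrix[ib]
    valid = (chrom_a != UNKNOWN_RESIDUE) & (chrom_b != UNKNOWN_RESIDUE)

    excluded = (~valid).sum(axis=0)
    for j, pos in enumerate(positions):
        if excluded[j]:
            logger.info(
                "position %d: %d sample(s) excluded (unknown residue)",
                pos,
                int(excluded[j]),
            )
    return ResidueGenotypeMatrix(
        sample_ids=cohort.sample_ids,
        status=cohort.status,
        positions=list(positions),
        chrom_a=chrom_a,
        chrom_b=chrom_b,
        valid=valid,
    )
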