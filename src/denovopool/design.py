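"""Random-ORF library design, per-sequence features and null models.

The library expresses 174-nt ORFs (58 codons) in human cells: a start codon
and one further constant codon at the 5' end, 150 random nucleotides
(50 codons), and a C-terminal 6xHis tag, flanked by a HindIII/Kozak context
upstream and a stop codon plus NotI site downstream.  The 150-nt random
insert doubles as the clone barcode.  This module encodes that layout,
parses ORFs out of amplicon reads, translates them, and provides the
closed-form null models for peptide length and sequence uniqueness.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "LibraryDesign",
    "CloneRecord",
    "UnparseableReadError",
    "MalformedInsertError",
    "AmbiguousBaseError",
    "extract_orf",
    "translate_orf",
    "peptide_length_null",
    "unique_combinations",
    "gc_content",
    "positional_nucleotide_freq",
    "amino_acid_composition",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


class UnparseableReadError(ValueError):
    """A read lacks (or duplicates) the constant flank anchors."""


class MalformedInsertError(ValueError):
    """Anchors were found but the enclosed ORF window is not the design length."""


class AmbiguousBaseError(ValueError):
    """A sequence contains a non-ACGT character (e.g. N); the clone is excluded."""


@dataclass(frozen=True)
class LibraryDesign:
    """Layout constants of the random-sequence expression library.

    The ORF is codon 1 = start codon, codon 2 = a second constant codon
    (its identity is configurable; GCC by default, a high-usage human Ala
    codon), codons 3-52 = the random region, codons 53-58 = the His tag.
    ``p_stop`` is the per-random-codon stop probability, 3/64 under uniform
    nucleotide composition.
    """

    random_len_nt: int = 150
    orf_len_nt: int = 174
    orf_len_aa: int = 58
    constant5_codons: tuple[str, str] = ("ATG", "GCC")
    histag_codons: tuple[str, ...] = ("CAC",) * 6
    stop_codons: frozenset[str] = STOP_CODONS
    hindiii_site: str = "AAGCTT"
    noti_site: str = "GCGGCCGC"
    kozak_context: str = "GCCACC"
    stop_codon_3p: str = "TAA"
    p_stop: float = 3.0 / 64.0

    def __post_init__(self) -> None:
        if self.random_len_nt % 3 != 0:
            raise ValueError("random region length must be divisible by 3")
        if self.orf_len_aa * 3 != self.orf_len_nt:
            raise ValueError("orf_len_aa * 3 must equal orf_len_nt")
        if 2 + self.random_len_nt // 3 + len(self.histag_codons) != self.orf_len_aa:
            raise ValueError("constant + random + His codons must total orf_len_aa")
        if self.constant5_codons[0] != "ATG":
            raise ValueError("codon 1 must be the start codon ATG")
        if not 0.0 < self.p_stop <= 1.0:
            raise ValueError("p_stop must lie in (0, 1]")

    @property
    def n_random_codons(self) -> int:
        return self.random_len_nt // 3

    @property
    def anchor5(self) -> str:
        """Constant 5' context through the start codon."""
        return self.kozak_context + self.constant5_codons[0]

    @property
    def histag_nt(self) -> str:
        return "".join(self.histag_codons)

    @property
    def read_prefix(self) -> str:
        """Constant sequence upstream of the ORF in a full amplicon."""
        return self.hindiii_site + self.kozak_context

    @property
    def read_suffix(self) -> str:
        """Constant sequence downstream of the ORF in a full amplicon."""
        return self.stop_codon_3p + self.noti_site

    @property
    def insert_offset_in_orf(self) -> int:
        return 3 * len(self.constant5_codons)

    @property
    def insert_offset_in_read(self) -> int:
        return len(self.read_prefix) + self.insert_offset_in_orf

    @property
    def read_len(self) -> int:
        return len(self.read_prefix) + self.orf_len_nt + len(self.read_suffix)

    def orf_from_insert(self, insert_nt: str) -> str:
        """Assemble the 174-nt ORF around a 150-nt random insert."""
        if len(insert_nt) != self.random_len_nt:
            raise ValueError(
                f"insert length {len(insert_nt)} != design {self.random_len_nt}"
            )
        return "".join(self.constant5_codons) + insert_nt + self.histag_nt

    def read_from_insert(self, insert_nt: str) -> str:
        """Assemble a full clean amplicon read around a 150-nt insert."""
        return self.read_prefix + self.orf_from_insert(insert_nt) + self.read_suffix


@dataclass
class CloneRecord:
    """One library member with its derived sequence features.

    ``peu`` (PASTA energy units, cross-beta aggregation free energy) and
    ``ids`` (intrinsic disorder score in [0,1]) come from external
    predictors and are ingested, never computed here.
    """

    clone_id: str
    insert_nt: str
    orf_nt: str
    peptide: str
    length_aa: int
    gc_insert: float
    gc_orf: float
    peu: float | None = None
    ids: float | None = None

    @classmethod
    def from_insert(
        cls,
        clone_id: str,
        insert_nt: str,
        design: LibraryDesign | None = None,
        peu: float | None = None,
        ids: float | None = None,
    ) -> "CloneRecord":
        design = design or LibraryDesign()
        orf = design.orf_from_insert(insert_nt)
        pep = translate_orf(orf, design)
        return cls(
            clone_id=clone_id,
            insert_nt=insert_nt,
            orf_nt=orf,
            peptide=pep,
            length_aa=len(pep),
            gc_insert=gc_content(insert_nt),
            gc_orf=gc_content(orf),
            peu=peu,
            ids=ids,
        )


def _find_unique(haystack: str, needle: str, start: int = 0) -> int:
    i = haystack.find(needle, start)
    if i == -1:
        raise UnparseableReadError(f"anchor {needle!r} not found")
    if haystack.find(needle, i + 1) != -1:
        raise UnparseableReadError(f"anchor {needle!r} is ambiguous (multiple hits)")
    return i


def extract_orf(read_nt: str, design: LibraryDesign | None = None) -> str:
    """Extract the 174-nt ORF window from an amplicon read.

    The window runs from the start codon (located via the constant Kozak
    context) through the last His codon (delimited by the downstream
    stop/NotI context).  Raises :class:`UnparseableReadError` when either
    anchor is missing or ambiguous, :class:`MalformedInsertError` when the
    anchors are present but the enclosed window is not ``orf_len_nt`` long.
    """
    design = design or LibraryDesign()
    read_nt = read_nt.upper()
    i5 = _find_unique(read_nt, design.anchor5)
    start = i5 + len(design.kozak_context)
    anchor3 = design.histag_nt + design.stop_codon_3p
    i3 = _find_unique(read_nt, anchor3, start)
    end = i3 + len(design.histag_nt)
    orf = read_nt[start:end]
    if len(orf) != design.orf_len_nt:
        raise MalformedInsertError(
            f"ORF window is {len(orf)} nt, expected {design.orf_len_nt}"
        )
    return orf


def translate_orf(orf_nt: str, design: LibraryDesign | None = None) -> str:
    """Translate an ORF with the standard genetic code, stopping at the
    first in-frame stop codon; an ORF without internal stops yields the
    full 58-residue peptide."""
    design = design or LibraryDesign()
    if len(orf_nt) != design.orf_len_nt:
        raise ValueError(f"ORF must be {design.orf_len_nt} nt, got {len(orf_nt)}")
    orf_nt = orf_nt.upper()
    if set(orf_nt) - set(_NT):
        raise AmbiguousBaseError(f"non-ACGT character in ORF: {set(orf_nt) - set(_NT)}")
    if orf_nt[:3] != design.constant5_codons[0]:
        raise ValueError("ORF does not begin with the start codon")
    return str(Seq(orf_nt).translate(to_stop=True))


def peptide_length_null(
    p_stop: float,
    n_random_codons: int = 50,
    library_size: int | float = 1,
    n_constant5: int = 2,
    n_histag: int = 6,
) -> pd.Series:
    """Expected peptide-length spectrum of an unbiased random library.

    A peptide is truncated at the first stop among the random codons; the
    probability that the first stop is at random codon k is the geometric
    mass (1-P)^(k-1) * P, giving peptide length ``n_constant5 + k - 1``.
    The no-internal-stop event has mass (1-P)^n and yields the full-length
    class (constant + random + His residues).  Masses sum to one; scaled by
    ``library_size`` they are expected clone counts per length.
    """
    if not 0.0 < p_stop <= 1.0:
        raise ValueError("p_stop must lie in (0, 1]")
    if n_random_codons < 1:
        raise ValueError("need at least one random codon")
    k = np.arange(1, n_random_codons + 1)
    mass = (1.0 - p_stop) ** (k - 1) * p_stop
    lengths = n_constant5 + k - 1
    full_len = n_constant5 + n_random_codons + n_histag
    out = pd.Series(mass, index=pd.Index(lengths, name="length_aa"))
    out.loc[full_len] = (1.0 - p_stop) ** n_random_codons
    return out * library_size


def unique_combinations(k: int) -> int:
    """Number of possible peptide sequences of length k over the 20 amino
    acids, as an exact integer 20**k."""
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    return 20 ** int(k)


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in a non-empty ACGT sequence."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(_NT)
    if bad:
        raise AmbiguousBaseError(f"non-ACGT characters: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def positional_nucleotide_freq(
    inserts: Iterable[str], length: int = 150
) -> pd.DataFrame:
    """Per-position nucleotide frequencies across a set of equal-length
    inserts, as a 4 x length table (rows A, C, G, T; columns sum to 1)."""
    counts = np.zeros((4, length), dtype=np.int64)
    n = 0
    idx = {c: i for i, c in enumerate(_NT)}
    for name_or_seq in inserts:
        seq = str(name_or_seq).upper()
        if len(seq) != length:
            raise ValueError(
                f"insert {seq[:12]}... has length {len(seq)}, expected {length}"
            )
        if set(seq) - set(_NT):
            raise AmbiguousBaseError(f"non-ACGT in insert {seq[:12]}...")
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        for c, i in idx.items():
            counts[i] += codes == ord(c)
        n += 1
    if n == 0:
        raise ValueError("no inserts supplied")
    freq = counts / n
    return pd.DataFrame(freq, index=list(_NT), columns=np.arange(1, length + 1))


def amino_acid_composition(peptides: Iterable[str]) -> pd.Series:
    """Pooled amino-acid frequencies over all residues of all peptides."""
    counter: collections.Counter[str] = collections.Counter()
    for pep in peptides:
        counter.update(pep)
    total = sum(counter.values())
    if total == 0:
        raise ValueError("all peptides are empty")
    bad = set(counter) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unexpected residues: {sorted(bad)}")
    return pd.Series(
        {aa: counter.get(aa, 0) / total for aa in AMINO_ACIDS}, name="frequency"
    )


def feature_table(records: Sequence["CloneRecord"]) -> pd.DataFrame:
    """Per-clone feature table (one row per clone) from CloneRecords."""
    return pd.DataFrame(
        {
            "clone_id": [r.clone_id for r in records],
            "length_aa": [r.length_aa for r in records],
            "gc_insert": [r.gc_insert for r in records],
            "gc_orf": [r.gc_orf for r in records],
            "peu": [r.peu for r in records],
            "ids": [r.ids for r in records],
        }
    )


def expected_aa_composition(design: LibraryDesign | None = None) -> pd.Series:
    """Amino-acid frequencies expected from uniform random codons,
    conditional on the codon not being a stop (the random-region model)."""
    design = design or LibraryDesign()
    counter: collections.Counter[str] = collections.Counter()
    for c1 in _NT:
        for c2 in _NT:
            for c3 in _NT:
                codon = c1 + c2 + c3
                if codon in design.stop_codons:
                    continue
                counter[str(Seq(codon).translate())] += 1
    total = sum(counter.values())
    return pd.Series({aa: counter.get(aa, 0) / total for aa in AMINO_ACIDS})
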