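"""Reference building and read-to-clone assignment for barcode amplicons.

The 150-nt random insert is the barcode: the reference is built from the
first-timepoint samples by ranking distinct inserts by abundance and
greedily absorbing sequencing-error variants into more abundant centers
within a small Hamming radius.  Reads are then assigned to the unique
nearest reference insert within a mismatch budget.  Amplicons are fixed
length, so only substitutions are modelled and Hamming distance suffices;
candidate centers are found with a pigeonhole chunk index (a read within
m mismatches of a center matches at least one of m+1 disjoint chunks
exactly), which keeps mapping linear in read count.
"""

from __future__ import annotations

import collections
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import LibraryDesign
from .simulate import ReadBatch, _encode

__all__ = [
    "ReferenceLibrary",
    "CountMatrix",
    "MappingStats",
    "build_reference",
    "map_reads",
    "assemble_count_matrix",
    "filter_low_representation",
]

_NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _chunk_bounds(length: int, n_chunks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, length, n_chunks + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_chunks)]


class _HammingIndex:
    """Pigeonhole index over fixed-length sequences supporting nearest-
    neighbour queries within a fixed radius."""

    def __init__(self, length: int, radius: int):
        self.length = length
        self.radius = radius
        self.bounds = _chunk_bounds(length, radius + 1)
        self.chunk_maps: list[dict[bytes, list[int]]] = [
            collections.defaultdict(list) for _ in self.bounds
        ]
        self.rows: list[np.ndarray] = []

    def add(self, row: np.ndarray) -> int:
        idx = len(self.rows)
        self.rows.append(row)
        for (a, b), cmap in zip(self.bounds, self.chunk_maps):
            cmap[row[a:b].tobytes()].append(idx)
        return idx

    def candidates(self, row: np.ndarray) -> list[int]:
        seen: set[int] = set()
        for (a, b), cmap in zip(self.bounds, self.chunk_maps):
            seen.update(cmap.get(row[a:b].tobytes(), ()))
        return list(seen)

    def query(self, row: np.ndarray) -> tuple[int, int, int]:
        """Return (best index, best distance, number of centers at best
        distance) among centers within radius; (-1, radius+1, 0) if none."""
        cand = self.candidates(row)
        if not cand:
            return -1, self.radius + 1, 0
        mat = np.stack([self.rows[i] for i in cand])
        d = (mat != row[None, :]).sum(axis=1)
        order = np.argmin(d)
        best = int(d[order])
        if best > self.radius:
            return -1, self.radius + 1, 0
        ties = int((d == best).sum())
        return cand[int(order)], best, ties


@dataclass
class ReferenceLibrary:
    """Clone reference: insert sequences with founding abundances."""

    inserts: pd.Series  # index clone_id, values 150-nt insert
    founding_abundance: pd.Series
    collapse_radius: int
    n_candidate_inserts: int = 0
    n_reads_used: int = 0
    n_unparseable: int = 0

    def __len__(self) -> int:
        return len(self.inserts)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.inserts.index)

    def matrix(self) -> np.ndarray:
        return np.stack([_encode(s) for s in self.inserts])

    def to_fasta(self, path: str | os.PathLike) -> None:
        from .io import write_fasta

        write_fasta(self.inserts.items(), path)

    @classmethod
    def from_fasta(
        cls, path: str | os.PathLike, collapse_radius: int = 2
    ) -> "ReferenceLibrary":
        from .io import read_fasta

        m = read_fasta(path)
        inserts = pd.Series(m, name="insert_nt")
        ab = pd.Series(0, index=inserts.index, name="founding_abundance")
        return cls(inserts=inserts, founding_abundance=ab,
                   collapse_radius=collapse_radius)


@dataclass
class MappingStats:
    total_reads: int
    assigned_reads: int
    n_unparseable: int = 0
    n_ambiguous: int = 0

    @property
    def mapping_rate(self) -> float:
        return self.assigned_reads / self.total_reads if self.total_reads else 0.0


def _insert_matrix(
    reads: ReadBatch | Sequence[str] | str | os.PathLike,
    design: LibraryDesign,
) -> tuple[np.ndarray, int, int]:
    """Extract the insert window from each read as an index matrix.

    Returns (matrix, n_total, n_unparseable).  Amplicons are fixed length,
    so the insert is taken positionally; reads of the wrong length are
    dropped as unparseable.
    """
    if isinstance(reads, (str, os.PathLike)):
        from .io import read_fastq_seqs

        reads = read_fastq_seqs(reads)
    off = design.insert_offset_in_read
    L = design.random_len_nt
    if isinstance(reads, ReadBatch):
        total = len(reads)
        if reads.read_len != design.read_len:
            return np.empty((0, L), np.uint8), total, total
        return reads.matrix[:, off : off + L], total, 0
    total = len(reads)
    good = [r for r in reads if len(r) == design.read_len and not set(r) - set("ACGT")]
    if not good:
        return np.empty((0, L), np.uint8), total, total
    batch = ReadBatch.from_strings(good)
    return batch.matrix[:, off : off + L], total, total - len(good)


def _count_rows(matrix: np.ndarray) -> collections.Counter[bytes]:
    c: collections.Counter[bytes] = collections.Counter()
    for row in matrix:
        c[row.tobytes()] += 1
    return c


def build_reference(
    t1_reads: Iterable[ReadBatch | Sequence[str] | str | os.PathLike],
    design: LibraryDesign | None = None,
    min_count: int = 2,
    collapse_radius: int = 2,
) -> ReferenceLibrary:
    """Build the clone reference from first-timepoint samples.

    Distinct inserts are ranked by total abundance (ties broken
    lexicographically); walking down the ranking, a candidate within
    ``collapse_radius`` mismatches of an already retained center is
    absorbed into the nearest such center, otherwise it is retained if its
    own count is at least ``min_count``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if collapse_radius < 0:
        raise ValueError("collapse_radius must be >= 0")
    design = design or LibraryDesign()
    if isinstance(t1_reads, (ReadBatch, str, os.PathLike)):
        t1_reads = [t1_reads]

    counts: collections.Counter[bytes] = collections.Counter()
    n_total = n_unparseable = 0
    for sample in t1_reads:
        mat, total, bad = _insert_matrix(sample, design)
        n_total += total
        n_unparseable += bad
        counts.update(_count_rows(mat))
    if not counts:
        raise ValueError("empty reference: no parseable first-timepoint reads")

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    index = _HammingIndex(design.random_len_nt, collapse_radius)
    retained: list[bytes] = []
    abundance: list[int] = []
    for key, cnt in ranked:
        row = np.frombuffer(key, dtype=np.uint8)
        if collapse_radius > 0 and retained:
            hit, dist, _ties = index.query(row)
            if hit >= 0:
                abundance[hit] += cnt
                continue
        if cnt >= min_count:
            index.add(row)
            retained.append(key)
            abundance.append(cnt)
    if not retained:
        raise ValueError("empty reference: no candidate passed min_count")

    width = max(5, len(str(len(retained))))
    ids = [f"clone{i:0{width}d}" for i in range(1, len(retained) + 1)]
    seqs = [
        _NT_BYTES[np.frombuffer(k, dtype=np.uint8)].tobytes().decode("ascii")
        for k in retained
    ]
    return ReferenceLibrary(
        inserts=pd.Series(seqs, index=ids, name="insert_nt"),
        founding_abundance=pd.Series(abundance, index=ids, name="founding_abundance"),
        collapse_radius=collapse_radius,
        n_candidate_inserts=len(ranked),
        n_reads_used=n_total,
        n_unparseable=n_unparseable,
    )


def map_reads(
    reads: ReadBatch | Sequence[str] | str | os.PathLike,
    reference: ReferenceLibrary,
    design: LibraryDesign | None = None,
    max_mismatch: int = 2,
) -> tuple[pd.Series, MappingStats]:
    """Assign reads to reference clones by insert Hamming distance.

    A read is assigned to the unique nearest insert within ``max_mismatch``
    mismatches; a distance tie between two clones leaves the read unmapped.
    Exact matches are resolved by hashing; only inexact reads touch the
    pigeonhole index.
    """
    if len(reference) == 0:
        raise ValueError("reference is empty")
    design = design or LibraryDesign()
    mat, n_total, n_unparseable = _insert_matrix(reads, design)

    counts = np.zeros(len(reference), dtype=np.int64)
    exact = {
        row.tobytes(): i for i, row in enumerate(reference.matrix())
    }
    index: _HammingIndex | None = None
    n_ambiguous = 0
    misses: collections.Counter[bytes] = collections.Counter()
    for row in mat:
        key = row.tobytes()
        hit = exact.get(key)
        if hit is not None:
            counts[hit] += 1
        else:
            misses[key] += 1
    if misses and max_mismatch > 0:
        index = _HammingIndex(design.random_len_nt, max_mismatch)
        for row in reference.matrix():
            index.add(row)
        for key, cnt in misses.items():
            row = np.frombuffer(key, dtype=np.uint8)
            hit, _dist, ties = index.query(row)
            if hit >= 0 and ties == 1:
                counts[hit] += cnt
            elif ties > 1:
                n_ambiguous += cnt

    assigned = int(counts.sum())
    stats = MappingStats(
        total_reads=n_total,
        assigned_reads=assigned,
        n_unparseable=n_unparseable,
        n_ambiguous=n_ambiguous,
    )
    return pd.Series(counts, index=reference.inserts.index, name="count"), stats


@dataclass
class CountMatrix:
    """Clone x sample integer counts with per-sample metadata.

    ``samples`` is indexed by sample name with columns ``replicate``,
    ``timepoint``, and (when produced by mapping) ``total_reads`` and
    ``mapped_reads``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match count columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("replicate", "timepoint"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")

    @property
    def clone_ids(self) -> list[str]:
        return list(self.counts.index)

    def condition_mask(self, timepoint: int) -> np.ndarray:
        return (self.samples["timepoint"] == timepoint).to_numpy()

    def subset_timepoints(self, timepoints: Sequence[int]) -> "CountMatrix":
        keep = self.samples["timepoint"].isin(timepoints)
        return CountMatrix(
            counts=self.counts.loc[:, keep.to_numpy()],
            samples=self.samples.loc[keep],
        )

    def to_tsv(self, counts_path: str | os.PathLike,
               samples_path: str | os.PathLike) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="clone_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path: str | os.PathLike,
                 samples_path: str | os.PathLike) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="clone_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts=counts, samples=samples)


def assemble_count_matrix(
    per_sample_counts: Mapping[str, pd.Series],
    sample_metadata: pd.DataFrame,
    mapping_stats: Mapping[str, MappingStats] | None = None,
) -> CountMatrix:
    """Combine per-sample clone counts into one matrix.

    Clone/sample combinations absent from a sample are filled with zero;
    duplicate sample labels are an error.
    """
    names = list(per_sample_counts)
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample labels")
    if sample_metadata.index.has_duplicates:
        raise ValueError("duplicate sample labels in metadata")
    missing = set(names) - set(sample_metadata.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    counts = pd.DataFrame(per_sample_counts).fillna(0).astype(np.int64)
    counts = counts[names]
    samples = sample_metadata.loc[names].copy()
    if mapping_stats is not None:
        samples["total_reads"] = [mapping_stats[s].total_reads for s in names]
        samples["mapped_reads"] = [mapping_stats[s].assigned_reads for s in names]
    return CountMatrix(counts=counts, samples=samples)


def filter_low_representation(matrix: CountMatrix, min_total: int = 50) -> CountMatrix:
    """Keep clones whose total count across all samples is >= min_total."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = matrix.counts.sum(axis=1) >= min_total
    return CountMatrix(counts=matrix.counts.loc[keep], samples=matrix.samples)
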