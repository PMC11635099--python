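"""Synthetic libraries, serial-passage competitive growth, and amplicon reads.

The simulator mirrors the study design end to end: a library of 150-nt
random inserts (optionally with positional nucleotide bias) is expressed in
a pooled cell population; at each two-day passage one-fourth of the cells
are reseeded and the rest sampled; amplicon sequencing of each sample
produces fixed-length reads with substitution errors.  Clone fitness enters
as a growth-rate multiplier (1+s) per doubling, so clone frequencies update
as f_i proportional to f_i (1+s_i)^d per passage with d doublings.

A deterministic mode propagates expected frequencies exactly (for
closed-form tests); the stochastic mode draws the reseeded cells
multinomially, which is the drift model for the bottleneck.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CloneRecord, LibraryDesign

__all__ = [
    "GrowthSimConfig",
    "SimTruth",
    "ReadBatch",
    "generate_library",
    "simulate_growth",
    "simulate_reads",
    "iter_sample_reads",
    "make_mdng_pool",
]

_NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GrowthSimConfig:
    """Parameters of the serial-passage growth and sequencing experiment.

    Defaults follow the pooled-library study design: 5 replicate flasks,
    10 sampled timepoints, one-fourth carryover every passage, 3e6 cells
    seeded per flask, and amplicon samples of ~7e5 reads.
    """

    n_replicates: int = 5
    n_timepoints: int = 10
    carryover_fraction: float = 0.25
    doublings_per_passage: float = 2.0
    cells_per_passage: int = 3_000_000
    read_depth: int = 700_000
    error_rate: float = 0.001
    quality: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.carryover_fraction < 1.0:
            raise ValueError("carryover_fraction must lie in (0, 1)")
        if min(self.n_replicates, self.n_timepoints, self.cells_per_passage,
               self.read_depth) < 1:
            raise ValueError("replicates, timepoints, cells and depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a growth simulation.

    ``freq`` and ``cells`` have shape (n_clones, n_replicates,
    n_timepoints); ``s`` is the per-clone fitness.  The true class is UP
    for s > 0, DOWN for s < 0, NS for neutral clones.
    """

    clone_ids: list[str]
    s: np.ndarray
    freq: np.ndarray
    cells: np.ndarray
    config: GrowthSimConfig

    @property
    def true_class(self) -> pd.Series:
        lab = np.where(self.s > 0, "UP", np.where(self.s < 0, "DOWN", "NS"))
        return pd.Series(lab, index=self.clone_ids, name="true_class")

    def sample_name(self, rep: int, tp: int) -> str:
        return f"rep{rep + 1}_T{tp + 1}"

    def frequencies(self, rep: int, tp: int) -> np.ndarray:
        return self.freq[:, rep, tp]

    def to_frame(self) -> pd.DataFrame:
        n, r, t = self.freq.shape
        idx = pd.MultiIndex.from_product(
            [self.clone_ids, range(1, r + 1), range(1, t + 1)],
            names=["clone_id", "replicate", "timepoint"],
        )
        return pd.DataFrame(
            {
                "frequency": self.freq.ravel(),
                "s": np.repeat(self.s, r * t),
            },
            index=idx,
        ).reset_index()

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sample_inserts(
    n: int, length: int, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n, length) matrix of base indices with per-position probs."""
    u = rng.random((n, length))
    cum = np.cumsum(probs, axis=0)  # (4, length)
    return (u[:, None, :] > cum[None, :-1, :]).sum(axis=1).astype(np.uint8)


def _rows_to_strings(idx_matrix: np.ndarray) -> list[str]:
    chars = _NT_BYTES[idx_matrix]
    return [row.tobytes().decode("ascii") for row in chars]


def generate_library(
    n_clones: int,
    design: LibraryDesign | None = None,
    positional_bias: Sequence[float] | np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CloneRecord]:
    """Generate a library of unique random inserts.

    ``positional_bias`` is either a length-4 probability vector over
    (A, C, G, T) applied at every position, or a 4 x random_len matrix of
    per-position probabilities; None means uniform.  Inserts containing an
    internal HindIII or NotI motif, or duplicating an earlier insert, are
    resampled so the library is clonable and uniquely barcoded.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    design = design or LibraryDesign()
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = design.random_len_nt

    if positional_bias is None:
        probs = np.full((4, L), 0.25)
    else:
        bias = np.asarray(positional_bias, dtype=float)
        if bias.ndim == 1:
            if bias.shape != (4,):
                raise ValueError("positional_bias vector must have 4 entries")
            probs = np.tile(bias[:, None], (1, L))
        elif bias.shape == (4, L):
            probs = bias.copy()
        else:
            raise ValueError(f"positional_bias must be (4,) or (4, {L})")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("positional_bias columns must be probability vectors")

    forbidden = (design.hindiii_site, design.noti_site)
    seen: set[str] = set()
    inserts: list[str] = []
    while len(inserts) < n_clones:
        batch = max(n_clones - len(inserts), 1)
        mat = _sample_inserts(batch, L, probs, rng)
        for s in _rows_to_strings(mat):
            if len(inserts) >= n_clones:
                break
            if any(m in s for m in forbidden) or s in seen:
                continue
            seen.add(s)
            inserts.append(s)

    width = max(4, len(str(n_clones)))
    return [
        CloneRecord.from_insert(f"clone{i:0{width}d}", ins, design)
        for i, ins in enumerate(inserts, start=1)
    ]


def _growth_factor(s: np.ndarray, doublings: float) -> np.ndarray:
    if np.any(1.0 + s <= 0):
        raise ValueError("1 + s must be positive for every clone")
    return (1.0 + s) ** doublings


def simulate_growth(
    n_clones_or_library: int | Sequence[CloneRecord],
    fitness: Sequence[float] | Mapping[str, float] | np.ndarray,
    config: GrowthSimConfig | None = None,
    seed: int | None = None,
    deterministic: bool = False,
    initial_freq: Sequence[float] | None = None,
) -> SimTruth:
    """Simulate serial-passage competitive growth of a clone pool.

    Per passage the expected frequency update is f_i -> f_i (1+s_i)^d
    (normalized), after which ``cells_per_passage`` reseeded cells are drawn
    multinomially; in deterministic mode expectations are propagated
    without sampling.  Timepoint 1 is the initial seeding; each later
    timepoint follows one passage.
    """
    config = config or GrowthSimConfig()
    if isinstance(n_clones_or_library, int):
        n = n_clones_or_library
        clone_ids = [f"clone{i:04d}" for i in range(1, n + 1)]
    else:
        clone_ids = [c.clone_id for c in n_clones_or_library]
        n = len(clone_ids)

    if isinstance(fitness, Mapping):
        s = np.array([float(fitness.get(cid, 0.0)) for cid in clone_ids])
    else:
        s = np.asarray(fitness, dtype=float)
    if s.shape != (n,):
        raise ValueError("fitness must be defined for every clone")

    if config.cells_per_passage < n and not deterministic:
        import warnings

        warnings.warn(
            f"cells_per_passage ({config.cells_per_passage}) < n_clones ({n}): "
            "severe bottleneck",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed if seed is None else seed)
    f0 = (
        np.full(n, 1.0 / n)
        if initial_freq is None
        else np.asarray(initial_freq, dtype=float)
    )
    if f0.shape != (n,) or np.any(f0 < 0) or abs(f0.sum() - 1.0) > 1e-9:
        raise ValueError("initial_freq must be a probability vector over clones")

    g = _growth_factor(s, config.doublings_per_passage)
    R, T = config.n_replicates, config.n_timepoints
    freq = np.empty((n, R, T))
    cells = np.empty((n, R, T))
    for r in range(R):
        if deterministic:
            f = f0.copy()
        else:
            c = rng.multinomial(config.cells_per_passage, f0)
            f = c / c.sum()
        freq[:, r, 0] = f
        cells[:, r, 0] = f * config.cells_per_passage if deterministic else c
        for t in range(1, T):
            expected = f * g
            expected /= expected.sum()
            if deterministic:
                f = expected
                cells[:, r, t] = f * config.cells_per_passage
            else:
                c = rng.multinomial(config.cells_per_passage, expected)
                f = c / c.sum()
                cells[:, r, t] = c
            freq[:, r, t] = f
    return SimTruth(clone_ids=clone_ids, s=s, freq=freq, cells=cells, config=config)


@dataclass
class ReadBatch:
    """A batch of equal-length amplicon reads, stored as a base-index
    matrix for fast downstream counting; convertible to strings/FASTQ."""

    matrix: np.ndarray  # (n_reads, read_len) uint8 indices into ACGT
    sample: str = "sample"

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def read_len(self) -> int:
        return self.matrix.shape[1]

    def to_strings(self) -> list[str]:
        return _rows_to_strings(self.matrix)

    def write_fastq(self, path: str | os.PathLike, quality: int = 30) -> None:
        from .io import write_fastq

        write_fastq(self.to_strings(), path, quality=quality,
                    name_prefix=f"{self.sample}_read")

    @classmethod
    def from_strings(cls, reads: Sequence[str], sample: str = "sample") -> "ReadBatch":
        if not reads:
            return cls(np.empty((0, 0), dtype=np.uint8), sample)
        L = len(reads[0])
        if any(len(r) != L for r in reads):
            raise ValueError("ReadBatch requires equal-length reads")
        raw = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
        raw = raw.reshape(len(reads), L)
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        return cls(lut[raw], sample)


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _apply_substitutions(
    matrix: np.ndarray, error_rate: float, rng: np.random.Generator
) -> None:
    """In-place independent per-base substitutions at ``error_rate``.

    Error positions are drawn with replacement over the flat matrix;
    coincident draws collapse to one substitution, a negligible effect at
    the rates simulated here.  A substitution always changes the base.
    """
    if error_rate == 0.0 or matrix.size == 0:
        return
    n_err = rng.binomial(matrix.size, error_rate)
    if n_err == 0:
        return
    flat = rng.integers(0, matrix.size, size=n_err)
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    r, c = np.unravel_index(flat, matrix.shape)
    matrix[r, c] = (matrix[r, c] + shift) % 4


def simulate_reads(
    frequencies: Sequence[float] | np.ndarray,
    library: Sequence[CloneRecord],
    config: GrowthSimConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample: str = "sample",
    design: LibraryDesign | None = None,
) -> ReadBatch:
    """Draw one amplicon sample: ``read_depth`` full-length reads drawn
    multinomially from clone frequencies, with substitution errors."""
    config = config or GrowthSimConfig()
    design = design or LibraryDesign()
    f = np.asarray(frequencies, dtype=float)
    if f.shape != (len(library),) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be a probability vector over the library")
    rng = rng if rng is not None else np.random.default_rng(seed)

    templates = np.stack(
        [_encode(design.read_from_insert(c.insert_nt)) for c in library]
    )
    counts = rng.multinomial(config.read_depth, f)
    source = np.repeat(np.arange(len(library)), counts)
    matrix = templates[source]
    _apply_substitutions(matrix, config.error_rate, rng)
    return ReadBatch(matrix=matrix, sample=sample)


def iter_sample_reads(
    truth: SimTruth,
    library: Sequence[CloneRecord],
    config: GrowthSimConfig | None = None,
    seed: int | None = None,
    timepoints: Sequence[int] | None = None,
    design: LibraryDesign | None = None,
) -> Iterator[ReadBatch]:
    """Yield one ReadBatch per (replicate, timepoint) sample of a
    simulation, in replicate-major order.  ``timepoints`` selects 1-based
    timepoints (default: all)."""
    config = config or truth.config
    design = design or LibraryDesign()
    rng = np.random.default_rng(seed)
    tps = list(range(truth.config.n_timepoints)) if timepoints is None else [
        t - 1 for t in timepoints
    ]
    templates = np.stack(
        [_encode(design.read_from_insert(c.insert_nt)) for c in library]
    )
    for r in range(truth.config.n_replicates):
        for t in tps:
            f = truth.frequencies(r, t)
            counts = rng.multinomial(config.read_depth, f)
            source = np.repeat(np.arange(len(library)), counts)
            matrix = templates[source]
            _apply_substitutions(matrix, config.error_rate, rng)
            yield ReadBatch(matrix=matrix, sample=truth.sample_name(r, t))


def make_mdng_pool(
    fitness: Sequence[float] | np.ndarray,
    n_clones: int = 14,
    n_replicates: int = 3,
    n_cycles: int = 5,
    cells_per_passage: int = 700_000,
    seed: int | None = None,
    deterministic: bool = False,
) -> SimTruth:
    """Simulate the small common-growth pool: ``n_clones`` gene clones grown
    jointly in ``n_replicates`` flasks over ``n_cycles`` passages (timepoint
    1 is the start, timepoint n_cycles+1 is cycle n_cycles)."""
    config = GrowthSimConfig(
        n_replicates=n_replicates,
        n_timepoints=n_cycles + 1,
        cells_per_passage=cells_per_passage,
    )
    return simulate_growth(
        n_clones, fitness, config=config, seed=seed, deterministic=deterministic
    )
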