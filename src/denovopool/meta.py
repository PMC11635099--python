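"""Cross-gene meta-analyses over the printed per-gene summary tables.

The heterologous-expression arm of the study produces, per mouse de novo
gene (Mdng) clone, a relative expression level, a count of differentially
expressed (DE) human genes, a mean intrinsic disorder score (IDS), and a
rank in the pooled common-growth experiment.  This module performs the
cross-gene analyses on those tables: tie-aware Spearman correlations,
foldability classification from IDS, DE-gene filtering and
reference-normalized expression semantics, and the recurrence matrix of
top up/down-regulated genes across the per-gene DE sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_table1",
    "load_table2",
    "spearman_with_ties",
    "classify_foldability",
    "de_filter",
    "normalize_to_reference",
    "top_n_sets",
    "recurrence_matrix",
]

logger = logging.getLogger(__name__)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("denovopool.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_table1() -> pd.DataFrame:
    """Per-Mdng expression level (relative to hygromycin), DE-gene count
    and top GO term, as published."""
    return _load_packaged("table1.tsv")


def load_table2() -> pd.DataFrame:
    """Per-Mdng peptide length, IDS, foldability label and common-growth
    rank, as published ('n.a.' ranks become missing)."""
    df = _load_packaged("table2.tsv")
    df["rank"] = pd.to_numeric(df["rank"].replace("n.a.", np.nan), errors="coerce")
    return df


def spearman_with_ties(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float, int]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value are dropped.  rho is the Pearson correlation
    of the rank vectors; the two-tailed p-value comes from
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom
    (``method="t"``), or from exhaustive/Monte-Carlo permutation for small
    n (``method="permutation"``).  Returns (rho, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    elif method == "permutation":
        res = stats.permutation_test(
            (rx,),
            lambda perm: np.corrcoef(perm, ry)[0, 1],
            permutation_type="pairings",
            n_resamples=9999,
            alternative="two-sided",
            rng=np.random.default_rng(0),
        )
        p = float(res.pvalue)
    else:
        raise ValueError("method must be 't' or 'permutation'")
    return rho, p, n


FOLDABILITY_LOW_IDS = 0.4   # disorder above this: poorly foldable
FOLDABILITY_HIGH_IDS = 0.1  # disorder below this: well foldable


def classify_foldability(ids: float | Sequence[float] | pd.Series):
    """Foldability label from the mean intrinsic disorder score.

    'low' when IDS > 0.4, 'high' when IDS < 0.1, 'intermediate' otherwise;
    the inequalities are strict, so a value exactly at a boundary is
    intermediate.
    """
    def one(v: float) -> str:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"IDS must lie in [0, 1], got {v}")
        if v > FOLDABILITY_LOW_IDS:
            return "low"
        if v < FOLDABILITY_HIGH_IDS:
            return "high"
        return "intermediate"

    if np.isscalar(ids):
        return one(float(ids))
    out = [one(float(v)) for v in ids]
    if isinstance(ids, pd.Series):
        return pd.Series(out, index=ids.index, name="foldability")
    return out


def de_filter(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    log2fc_column: str = "log2fc",
    padj_column: str = "padj",
) -> pd.DataFrame:
    """Differentially expressed genes: padj < alpha and at least
    ``min_fold``-fold change in either direction (|log2fc| >= log2(min_fold))."""
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    lfc = results[log2fc_column].abs()
    keep = (results[padj_column] < alpha) & (lfc >= np.log2(min_fold))
    return results.loc[keep.fillna(False)]


def normalize_to_reference(
    gene_counts: float | np.ndarray | pd.Series,
    reference_counts: float | np.ndarray | pd.Series,
):
    """Expression of a transcript relative to a reference transcript
    (e.g. the hygromycin resistance gene) in the same sample.  Any common
    library-size factor cancels in the ratio."""
    ref = np.asarray(reference_counts, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference counts must be positive")
    out = np.asarray(gene_counts, dtype=float) / ref
    if isinstance(gene_counts, pd.Series):
        return pd.Series(out, index=gene_counts.index)
    return out if out.ndim else float(out)


def top_n_sets(
    de_results: Mapping[str, pd.DataFrame],
    n: int = 10,
    gene_column: str = "gene_id",
    log2fc_column: str = "log2fc",
) -> dict[str, pd.Series]:
    """Per experiment, the top-n up- and top-n down-regulated genes.

    Genes are ranked by log2 fold change, descending for the up set and
    ascending for the down set, ties broken by gene identifier.  Returns,
    per experiment, a Series mapping gene id -> sign (+1 up, -1 down).  If
    fewer than n genes exist in a direction, all are taken (logged).
    """
    out: dict[str, pd.Series] = {}
    for name, df in de_results.items():
        df = df[[gene_column, log2fc_column]].dropna()
        up = df[df[log2fc_column] > 0].sort_values(
            [log2fc_column, gene_column], ascending=[False, True], kind="mergesort"
        )
        down = df[df[log2fc_column] < 0].sort_values(
            [log2fc_column, gene_column], ascending=[True, True], kind="mergesort"
        )
        if len(up) < n or len(down) < n:
            logger.info(
                "%s: only %d up / %d down genes available for top-%d selection",
                name, len(up), len(down), n,
            )
        chosen = pd.concat(
            [
                pd.Series(1, index=up.head(n)[gene_column]),
                pd.Series(-1, index=down.head(n)[gene_column]),
            ]
        )
        chosen.index.name = "gene_id"
        out[name] = chosen
    return out


@dataclass
class RecurrenceMatrix:
    """Signed membership of recurrent genes across per-experiment top sets.

    ``matrix`` holds +1 (up), -1 (down) or 0 (absent) for genes that occur
    in at least two sets, ordered by descending occurrence count N;
    ``conflict`` marks genes appearing with both signs; ``per_set_totals``
    counts recurrent genes per set.
    """

    matrix: pd.DataFrame
    n_occurrences: pd.Series
    conflict: pd.Series
    per_set_totals: pd.Series


def recurrence_matrix(sets: Mapping[str, pd.Series]) -> RecurrenceMatrix:
    """Build the recurrence matrix of genes present in two or more top sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    signed = pd.DataFrame(
        {name: s for name, s in sets.items()}
    ).fillna(0).astype(int)
    n_occ = (signed != 0).sum(axis=1)
    keep = n_occ >= 2
    signed = signed.loc[keep]
    n_occ = n_occ.loc[keep]
    order = sorted(signed.index, key=lambda g: (-n_occ[g], str(g)))
    signed = signed.loc[order]
    n_occ = n_occ.loc[order]
    conflict = ((signed > 0).any(axis=1)) & ((signed < 0).any(axis=1))
    per_set = (signed != 0).sum(axis=0)
    n_occ.name = "N"
    conflict.name = "conflict"
    per_set.name = "n_recurrent"
    return RecurrenceMatrix(
        matrix=signed, n_occurrences=n_occ, conflict=conflict, per_set_totals=per_set
    )
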