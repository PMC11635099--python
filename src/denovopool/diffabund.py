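"""Count-based differential clone abundance between two timepoints.

A simplified negative-binomial Wald workflow in the DESeq2 spirit:
median-of-ratios size factors, method-of-moments dispersion with shrinkage
toward a fitted mean-dispersion trend, a per-clone NB log-link GLM with a
condition indicator fitted by IRLS, a two-sided normal Wald p-value on the
condition coefficient, Benjamini-Hochberg adjustment, and classification
into UP / DOWN / NS.  No fold-change shrinkage and no outlier filtering are
applied.  Also provides the common-growth pool ranking used for the small
gene pool (relative frequency change start -> final cycle, averaged over
replicates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountMatrix

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "wald_test",
    "adjust_bh",
    "classify_clones",
    "run_differential_abundance",
    "rank_pool_growth",
]

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


def _counts_frame(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, CountMatrix) else matrix


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The per-clone geometric mean over samples is computed on clones with
    all-positive counts; each sample's factor is the median over those
    clones of count / geometric mean.
    """
    counts = _counts_frame(matrix)
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("size factors undefined: no clone has all-positive counts")
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1)
    ratios = logx - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu over clones with positive
    raw dispersion estimates; coefficients clipped at zero."""
    use = (alpha > 0) & (mu > 0)
    if use.sum() < 2:
        return float(np.clip(np.nanmedian(alpha[alpha > 0]) if (alpha > 0).any()
                             else 0.0, 0.0, None)), 0.0
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
    a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    return a0, a1


def estimate_dispersion(
    matrix: CountMatrix | pd.DataFrame,
    sf: pd.Series,
    condition: Sequence | np.ndarray | None = None,
    shrinkage_weight: float = 0.5,
) -> pd.Series:
    """Per-clone NB dispersion by method of moments with trend shrinkage.

    Raw estimates alpha = max(0, (s^2 - mu)/mu^2) are computed on
    normalized counts pooled within condition (variance is the pooled
    within-condition variance), then shrunk toward the fitted trend
    a0 + a1/mu with weight ``shrinkage_weight``.  All-zero clones get NaN
    (untestable).
    """
    counts = _counts_frame(matrix)
    if condition is None:
        if not isinstance(matrix, CountMatrix):
            raise ValueError("condition labels required for a bare count frame")
        condition = matrix.samples["timepoint"].to_numpy()
    condition = np.asarray(condition)
    if not 0.0 <= shrinkage_weight <= 1.0:
        raise ValueError("shrinkage_weight must lie in [0, 1]")

    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    levels = np.unique(condition)
    n_clones = norm.shape[0]
    ss = np.zeros(n_clones)
    df = 0
    for lev in levels:
        cols = condition == lev
        k = int(cols.sum())
        if k < 2:
            continue
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += k - 1
    if df < 1:
        raise ValueError("need at least 2 samples in some condition")
    s2 = ss / df
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), np.nan)
    a0, a1 = _dispersion_trend(mu, np.nan_to_num(raw, nan=0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, np.nan)
    alpha = (1.0 - shrinkage_weight) * raw + shrinkage_weight * trend
    alpha = np.where(mu > 0, np.maximum(alpha, 0.0), np.nan)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _irls_two_group(
    norm: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-clone NB GLM log(mu) = b0 + b1 x on the
    normalized-count scale.

    Fitting on normalized counts (rather than raw counts with per-sample
    offsets) makes the estimates depend on the data only through the
    normalized matrix, so a depth rescaling absorbed by the size factors
    leaves the fit bit-identical.  With the log link and a two-group
    design the working weights are equal within each group, so the MLE of
    the group means does not depend on the dispersion.  Returns
    (b0, b1, se_b1); non-converged clones get NaN.
    """
    y = norm
    n_clones, n_samp = y.shape
    m0 = y[:, x == 0].mean(axis=1)
    m1 = y[:, x == 1].mean(axis=1)
    eps = 0.5
    b0 = np.log(m0 + eps)
    b1 = np.log(m1 + eps) - b0
    converged = np.zeros(n_clones, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (y - mu) / mu
        resp = eta + z
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * x[None, :] ** 2).sum(axis=1)
        swr = (w * resp).sum(axis=1)
        swxr = (w * x[None, :] * resp).sum(axis=1)
        det = sw * swxx - swx**2
        with np.errstate(divide="ignore", invalid="ignore"):
            nb0 = (swxx * swr - swx * swxr) / det
            nb1 = (sw * swxr - swx * swr) / det
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, nb1)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        newly = step < tol
        converged |= newly
        if converged.all():
            break
    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -700, 700))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    swxx = (w * x[None, :] ** 2).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se = np.sqrt(np.where(det > 0, var_b1, np.nan))
    b0 = np.where(converged, b0, np.nan)
    b1 = np.where(converged, b1, np.nan)
    se = np.where(converged, se, np.nan)
    return b0, b1, se


def wald_test(
    matrix: CountMatrix | pd.DataFrame,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    baseline_timepoint: int = 1,
    contrast_timepoint: int = 10,
    condition: Sequence | None = None,
    max_iter: int = 50,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-clone Wald test of the contrast timepoint against baseline.

    Fits log(mu) = b0 + b1 * [sample in contrast] to size-factor-
    normalized counts by IRLS with fixed NB dispersion; reports base_mean
    (mean normalized count over the tested samples), log2fc = b1/ln 2,
    its SE, and the two-sided normal Wald p-value.  Clones that cannot be
    fitted (all-zero or non-convergent) have NaN p-values.
    """
    if isinstance(matrix, CountMatrix) and condition is None:
        sub = matrix.subset_timepoints([baseline_timepoint, contrast_timepoint])
        counts = sub.counts
        cond = (sub.samples["timepoint"] == contrast_timepoint).to_numpy().astype(int)
    else:
        counts = _counts_frame(matrix)
        if condition is None:
            raise ValueError("condition labels required for a bare count frame")
        cond = np.asarray(condition).astype(int)
    if (cond == 0).sum() < 2 or (cond == 1).sum() < 2:
        raise ValueError("both conditions need at least 2 samples")

    if sf is None:
        sf = size_factors(counts)
    sf = sf.loc[counts.columns]
    if dispersions is None:
        dispersions = estimate_dispersion(
            counts, sf, condition=cond, shrinkage_weight=shrinkage_weight
        )
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)

    y = counts.to_numpy(dtype=float)
    testable = np.isfinite(alpha) & (y.sum(axis=1) > 0)
    n = y.shape[0]
    b0 = np.full(n, np.nan)
    b1 = np.full(n, np.nan)
    se = np.full(n, np.nan)
    norm_all = y / sf.to_numpy(dtype=float)[None, :]
    if testable.any():
        b0[testable], b1[testable], se[testable] = _irls_two_group(
            norm_all[testable], cond.astype(float),
            alpha[testable], max_iter=max_iter,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = norm_all.mean(axis=1)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": b1 / LN2,
            "se": se / LN2,
            "wald_p": p,
        },
        index=counts.index,
    )
    out.index.name = "clone_id"
    n_failed = int((~np.isfinite(out["wald_p"].to_numpy())).sum())
    if n_failed:
        logger.info("wald_test: %d clones untestable or non-convergent", n_failed)
    return out


def adjust_bh(pvalues: Sequence[float] | pd.Series | np.ndarray) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values are excluded from the adjustment and returned missing;
    monotonicity is enforced by the running minimum from the largest p.
    """
    arr = np.asarray(pvalues, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    p = arr[ok]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m:
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out[ok] = adj
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="padj")
    return out


def classify_clones(
    results: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify clones as UP / DOWN / NS from adjusted p and fold-change sign.

    UP: padj < alpha and log2fc > 0; DOWN: padj < alpha and log2fc < 0;
    everything else (including untestable clones) is NS.  Returns the
    augmented results and the three group counts (a partition).
    """
    res = results.copy()
    if "padj" not in res.columns:
        res["padj"] = adjust_bh(res["wald_p"])
    sig = res["padj"].to_numpy() < alpha
    lfc = res["log2fc"].to_numpy()
    label = np.where(
        sig & np.isfinite(lfc) & (lfc > 0),
        "UP",
        np.where(sig & np.isfinite(lfc) & (lfc < 0), "DOWN", "NS"),
    )
    res["class"] = label
    counts = res["class"].value_counts().reindex(["UP", "DOWN", "NS"], fill_value=0)
    return res, counts


def run_differential_abundance(
    matrix: CountMatrix,
    baseline_timepoint: int = 1,
    contrast_timepoint: int = 10,
    alpha: float = 0.05,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """Full pipeline: size factors, dispersion, Wald test, BH, classes."""
    res = wald_test(
        matrix,
        baseline_timepoint=baseline_timepoint,
        contrast_timepoint=contrast_timepoint,
        shrinkage_weight=shrinkage_weight,
    )
    res["padj"] = adjust_bh(res["wald_p"])
    res, _ = classify_clones(res, alpha=alpha)
    return res


def rank_pool_growth(
    matrix: CountMatrix,
    start_timepoint: int | None = None,
    end_timepoint: int | None = None,
) -> pd.DataFrame:
    """Rank clones of a small common-growth pool by mean relative change.

    Per replicate the relative change is (frequency at the final cycle) /
    (frequency at the start); ranks order the mean change descending
    (rank 1 = largest increase), ties broken by clone id.  Clones with zero
    counts at the final cycle in every replicate are flagged
    ``failed_to_grow`` and left unranked; clones with a zero start
    frequency in any replicate are excluded with a warning.
    """
    tps = matrix.samples["timepoint"]
    t0 = int(tps.min()) if start_timepoint is None else start_timepoint
    t1 = int(tps.max()) if end_timepoint is None else end_timepoint
    start = matrix.counts.loc[:, matrix.condition_mask(t0)]
    end = matrix.counts.loc[:, matrix.condition_mask(t1)]
    reps_start = matrix.samples.loc[start.columns, "replicate"].to_numpy()
    reps_end = matrix.samples.loc[end.columns, "replicate"].to_numpy()
    order = np.argsort(reps_end)
    end = end.iloc[:, order]
    start = start.iloc[:, np.argsort(reps_start)]
    if not np.array_equal(np.sort(reps_start), np.sort(reps_end)):
        raise ValueError("start and end timepoints cover different replicates")

    f_start = start.to_numpy(float) / start.to_numpy(float).sum(axis=0, keepdims=True)
    f_end = end.to_numpy(float) / end.to_numpy(float).sum(axis=0, keepdims=True)

    zero_start = (f_start == 0).any(axis=1)
    if zero_start.any():
        warnings.warn(
            f"excluding {int(zero_start.sum())} clone(s) with zero start frequency",
            stacklevel=2,
        )
    failed = (f_end == 0).all(axis=1) & ~zero_start
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(f_start > 0, f_end / np.where(f_start > 0, f_start, np.nan), np.nan)
    mean_change = rel.mean(axis=1)

    out = pd.DataFrame(rel, index=matrix.counts.index,
                       columns=[f"rel_change_rep{r}" for r in np.sort(reps_end)])
    out["mean_change"] = mean_change
    out["failed_to_grow"] = failed
    rankable = ~failed & ~zero_start
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    sub = out.loc[rankable, ["mean_change"]].copy()
    sub["_id"] = sub.index
    sub = sub.sort_values(["mean_change", "_id"], ascending=[False, True],
                          kind="mergesort")
    out.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1)
    out.index.name = "clone_id"
    return out
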