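"""Feature-distribution comparisons between clone reaction groups.

After classification, per-clone features (peptide length, GC content,
PASTA aggregation energy, disorder score) are compared between the UP /
DOWN / NS groups and the whole-library background with two-sample
Kolmogorov-Smirnov tests, summarized per length class with Tukey-style
boxplot statistics (whiskers at the furthest points within 1.5 IQR of the
hinges), and flagged for aggregation propensity at the -5 PEU cutoff.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ks_two_sample",
    "group_feature_tests",
    "length_class_boxstats",
    "flag_aggregation_prone",
]

logger = logging.getLogger(__name__)

PEU_AGGREGATION_CUTOFF = -5.0


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of the absolute ECDF difference; the p-value uses the
    asymptotic Kolmogorov distribution with the effective sample size
    n_x n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def group_feature_tests(
    features: pd.DataFrame,
    feature_name: str,
    class_column: str = "class",
    background: str = "inclusive",
    min_group_n: int = 5,
) -> pd.DataFrame:
    """KS test of each group's feature distribution against the background.

    By default the background is the whole table including the tested
    group, mirroring comparisons of each class against the full library;
    ``background="exclusive"`` tests each group against all other clones,
    and ``background="pairwise"`` tests every group pair.  Groups smaller
    than ``min_group_n`` are flagged low-n but still tested.
    """
    if feature_name not in features.columns:
        raise ValueError(f"unknown feature {feature_name!r}")
    vals = features[[class_column, feature_name]].dropna()
    groups = vals.groupby(class_column, sort=True)
    if len(groups) < 1:
        raise ValueError("no groups present")
    all_vals = vals[feature_name].to_numpy()

    rows = []
    if background == "pairwise":
        names = list(groups.groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                xa = groups.get_group(a)[feature_name].to_numpy()
                xb = groups.get_group(b)[feature_name].to_numpy()
                d, p = ks_two_sample(xa, xb)
                rows.append(
                    {"group": f"{a} vs {b}", "n": len(xa), "n_background": len(xb),
                     "D": d, "p": p, "low_n": min(len(xa), len(xb)) < min_group_n}
                )
    elif background in ("inclusive", "exclusive"):
        for name, sub in groups:
            xg = sub[feature_name].to_numpy()
            bg = (
                all_vals
                if background == "inclusive"
                else vals.loc[vals[class_column] != name, feature_name].to_numpy()
            )
            if bg.size == 0:
                bg = xg  # single-group table: background is itself
            d, p = ks_two_sample(xg, bg)
            low = len(xg) < min_group_n
            if low:
                logger.info("group %s has n=%d < %d", name, len(xg), min_group_n)
            rows.append(
                {"group": name, "n": len(xg), "n_background": len(bg),
                 "D": d, "p": p, "low_n": low}
            )
    else:
        raise ValueError("background must be inclusive, exclusive or pairwise")
    return pd.DataFrame(rows).set_index("group")


def _boxstats(values: np.ndarray) -> dict[str, float | list[float]]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "n": int(values.size),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(v) for v in values[(values < lo_fence) | (values > hi_fence)]),
    }


def length_class_boxstats(
    features: pd.DataFrame,
    feature_name: str,
    bins: Sequence[float],
    length_column: str = "length_aa",
) -> pd.DataFrame:
    """Boxplot statistics of a feature stratified by peptide-length class.

    ``bins`` are sorted edges; classes are [b0,b1), [b1,b2), ..., the last
    bin closed.  Quartiles interpolate linearly between order statistics;
    whiskers reach the furthest data points within 1.5 IQR of the hinges,
    points beyond are listed as outliers.  Empty bins are omitted (noted in
    the log).
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be a sorted sequence of at least 2 edges")
    vals = features[[length_column, feature_name]].dropna()
    which = np.digitize(vals[length_column].to_numpy(), edges, right=False) - 1
    # close the last bin on the right
    which[vals[length_column].to_numpy() == edges[-1]] = len(edges) - 2
    rows = []
    for b in range(len(edges) - 1):
        sub = vals[feature_name].to_numpy()[which == b]
        label = f"[{edges[b]:g},{edges[b + 1]:g})"
        if sub.size == 0:
            logger.info("length class %s is empty; omitted", label)
            continue
        rows.append({"length_class": label, **_boxstats(sub)})
    return pd.DataFrame(rows).set_index("length_class")


def flag_aggregation_prone(
    peu: float | Sequence[float] | pd.Series,
) -> bool | pd.Series | np.ndarray:
    """True where the PASTA best-pairing energy is -5 PEU or lower
    (aggregation/amyloid propensity); missing energies give missing flags."""
    if np.isscalar(peu):
        return None if pd.isna(peu) else bool(peu <= PEU_AGGREGATION_CUTOFF)
    arr = pd.Series(peu, dtype=float) if not isinstance(peu, pd.Series) else peu.astype(float)
    out = arr <= PEU_AGGREGATION_CUTOFF
    return out.where(arr.notna(), other=pd.NA)
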