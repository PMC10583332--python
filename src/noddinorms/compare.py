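"""Nonparametric group comparisons of robust z-scores.

Per (ROI, metric) cell: Kruskal-Wallis omnibus across all group levels with
Benjamini-Hochberg FDR correction within a configurable family (default: the
6 ROIs of each metric x tissue-class block), pairwise two-group follow-up
restricted to cells passing the omnibus gate, Cliff's delta dominance effect
sizes with a consistent-variance normal-approximation 95% CI, and Spearman
rank correlation for z-score vs CSF-analyte associations.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "bh_fdr",
    "cliffs_delta",
    "spearman_correlation",
    "compare_groups",
]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value (k-1 df).

    Raises if fewer than 2 groups, any group is empty, total n < 3, or all
    pooled values are identical (the tie correction degenerates).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise ValueError("all pooled values identical: H undefined")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-free input)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cliffs_delta(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Cliff's dominance delta with a consistent-variance normal CI.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y), in [-1, 1].
    The variance uses the unbiased consistent estimate built from the row
    means, column means and individual dominance indicators; the interval is
    delta +/- z * sd, truncated to [-1, 1]. The effect is called significant
    when the interval excludes 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    m, n = x.size, y.size
    d_ij = np.sign(x[:, None] - y[None, :])
    delta = float(d_ij.mean())
    if m == 1 or n == 1:
        # No replication to estimate the variance; return the point estimate.
        return delta, -1.0, 1.0
    d_i = d_ij.mean(axis=1)
    d_j = d_ij.mean(axis=0)
    var = (n ** 2 * np.sum((d_i - delta) ** 2)
           + m ** 2 * np.sum((d_j - delta) ** 2)
           - np.sum((d_ij - delta) ** 2)) / (m * n * (m - 1) * (n - 1))
    var = max(float(var), 0.0)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var)
    return delta, max(delta - half, -1.0), min(delta + half, 1.0)


def spearman_correlation(z_values, csf_values) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with a two-sided t-based p-value."""
    z = np.asarray(z_values, float)
    c = np.asarray(csf_values, float)
    if z.size != c.size:
        raise ValueError("inputs must be paired")
    if z.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(z).size == 1 or np.unique(c).size == 1:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(z, c)
    return float(rho), float(p)


def compare_groups(
    ztable: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    family: str = "per_metric_tissue",
) -> pd.DataFrame:
    """Omnibus + gated pairwise comparison of z-scores across group levels.

    Parameters
    ----------
    ztable : rows keyed (participant_id, roi_name, metric, tissue_class, z).
    groups : participant_id -> group level; participants absent from the
        mapping are ignored. Levels with zero members in some cell are
        skipped with a warning, never silently.
    alpha : omnibus gate on the FDR-adjusted p.
    family : "per_metric_tissue" adjusts within each (metric, tissue_class)
        block of ROIs; "all" adjusts across every cell jointly.

    Returns one row per cell for the omnibus test (contrast="omnibus") and,
    for cells passing the gate, one row per group pair with the two-group
    Kruskal-Wallis p and Cliff's delta (first-named level as x).
    """
    if family not in ("per_metric_tissue", "all"):
        raise ValueError(f"unknown FDR family {family!r}")
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("grouping must define at least 2 levels")

    zt = ztable[ztable["participant_id"].isin(groups.index)].copy()
    zt["group"] = groups.loc[zt["participant_id"]].to_numpy()

    omnibus_rows = []
    cell_values: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}
    for (roi, metric, tissue), grp in zt.groupby(
            ["roi_name", "metric", "tissue_class"], sort=True):
        by_level = {lv: grp.loc[grp["group"] == lv, "z"].to_numpy()
                    for lv in levels}
        present = {lv: v for lv, v in by_level.items() if v.size > 0}
        skipped = sorted(set(levels) - set(present))
        if skipped:
            warnings.warn(
                f"cell ({roi}, {metric}): empty group level(s) {skipped}; "
                "omnibus computed on the remaining levels", stacklevel=2)
        if len(present) < 2:
            warnings.warn(
                f"cell ({roi}, {metric}): fewer than 2 non-empty levels; "
                "skipped", stacklevel=2)
            continue
        h, p = kruskal_wallis(list(present.values()))
        cell_values[(roi, metric, tissue)] = present
        omnibus_rows.append({
            "roi_name": roi, "metric": metric, "tissue_class": tissue,
            "contrast": "omnibus", "h_statistic": h, "p_raw": p,
            "n_per_group": "/".join(str(present[lv].size) for lv in sorted(present)),
        })

    omnibus = pd.DataFrame(omnibus_rows)
    if omnibus.empty:
        return omnibus
    if family == "all":
        omnibus["p_fdr"] = bh_fdr(omnibus["p_raw"].to_numpy())
    else:
        omnibus["p_fdr"] = np.nan
        for _, idx in omnibus.groupby(["metric", "tissue_class"]).groups.items():
            omnibus.loc[idx, "p_fdr"] = bh_fdr(omnibus.loc[idx, "p_raw"].to_numpy())

    pairwise_rows = []
    for row in omnibus.itertuples():
        if row.p_fdr >= alpha:
            continue
        present = cell_values[(row.roi_name, row.metric, row.tissue_class)]
        for a, b in itertools.combinations(sorted(present), 2):
            h, p = kruskal_wallis([present[a], present[b]])
            delta, lo, hi = cliffs_delta(present[a], present[b])
            pairwise_rows.append({
                "roi_name": row.roi_name, "metric": row.metric,
                "tissue_class": row.tissue_class,
                "contrast": f"{a} vs {b}", "h_statistic": h, "p_raw": p,
                "p_fdr": np.nan, "cliffs_delta": delta,
                "delta_ci_low": lo, "delta_ci_high": hi,
                "n_per_group": f"{present[a].size}/{present[b].size}",
            })

    out = pd.concat([omnibus, pd.DataFrame(pairwise_rows)], ignore_index=True)
    for col in ("cliffs_delta", "delta_ci_low", "delta_ci_high"):
        if col not in out.columns:
            out[col] = np.nan
    return out
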