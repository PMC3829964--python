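"""Caste and subcaste differential expression.

Per contig: a one-way fixed-effects ANOVA across the three castes (or a
two-tailed unpaired Student t-test for the two worker subcastes) on
log-scale values, Benjamini-Hochberg control of the false discovery rate
across all expressed contigs, and a Student-Newman-Keuls step-down
post-hoc grouping of the castes for significant contigs.

The filter cascade reproduces the screening conventions of absolute-
intensity arrays: contigs whose largest group mean (linear scale) falls
below ``min_mean_intensity`` (default 100) are excluded as not
expressed, and a difference is treated as biologically relevant only
when the largest pairwise ratio of linear group means is at least
``min_fold`` (default 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arrayproc import ContigExpressionTable, log_transform


@dataclass(frozen=True)
class Thresholds:
    """Filter-cascade settings for the DE table."""

    min_mean_intensity: float = 100.0
    min_fold: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def one_way_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects F test over k >= 2 groups.

    Degenerate inputs are resolved explicitly: zero total sum of squares
    (all observations identical) yields (F=0, p=1); zero within-group
    variance with distinct group means yields (F=inf, p=0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least two observations")
    allv = np.concatenate(groups)
    ss_total = float(((allv - allv.mean()) ** 2).sum())
    if ss_total == 0.0:
        return 0.0, 1.0
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ss_within == 0.0:
        return np.inf, 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def two_group_ttest(a, b) -> tuple[float, float]:
    """Classical pooled-variance two-sided Student t-test.

    Identical inputs give (t=0, p=1); a zero pooled variance with unequal
    means is degenerate and reported as (t=±inf, p=0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("every group needs at least two observations")
    pooled_ss = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    if pooled_ss == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} m * p_(j) / j, capped at 1, mapped back to
    the original positions.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def snk_posthoc(means, sizes, mse: float, df_error: int,
                alpha: float = 0.05) -> list[tuple[int, ...]]:
    """Student-Newman-Keuls step-down grouping of k >= 2 group means.

    Means are ordered; stretches of length r = k .. 2 are tested against
    q(alpha, r, df_error) * sqrt(MSE / n_h) with n_h the harmonic mean of
    the stretch's group sizes.  A stretch declared homogeneous is never
    subdivided.  Returns the homogeneous subsets as tuples of the
    original group indices (singletons for fully separated groups);
    subsets may overlap.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least two groups")
    if sizes.size != k or (sizes < 1).any():
        raise ValueError("sizes must match means and be positive")
    if mse <= 0:
        raise ValueError("within-group mean square must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")

    order = np.argsort(means, kind="stable")
    m_sorted = means[order]
    n_sorted = sizes[order]

    homogeneous: list[tuple[int, int]] = []   # inclusive (i, j) in sorted order

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homogeneous)

    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            if covered(i, j):
                continue
            nh = r / (1.0 / n_sorted[i:j + 1]).sum()
            crit = stats.studentized_range.ppf(1 - alpha, r, df_error)
            if (m_sorted[j] - m_sorted[i]) <= crit * np.sqrt(mse / nh):
                homogeneous.append((i, j))

    subsets: list[tuple[int, ...]] = []
    in_subset = np.zeros(k, dtype=bool)
    for a, b in sorted(homogeneous):
        subsets.append(tuple(sorted(int(order[t]) for t in range(a, b + 1))))
        in_subset[a:b + 1] = True
    for t in range(k):
        if not in_subset[t]:
            subsets.append((int(order[t]),))
    # report in order of the smallest mean each subset contains
    subsets.sort(key=lambda s: (min(float(means[i]) for i in s), s))
    return subsets


def letter_display(subsets: list[tuple[int, ...]], k: int) -> list[str]:
    """Compact letter display: groups sharing a letter are homogeneous."""
    letters = [""] * k
    for s, letter in zip(subsets, "abcdefghijklmnopqrstuvwxyz"):
        for i in s:
            letters[i] += letter
    return letters


def de_table(table: ContigExpressionTable, design, thresholds: Thresholds,
             log_base: float = 2.0, log_offset: float = 1.0) -> pd.DataFrame:
    """Run the full DE cascade on one dataset's contig expression table.

    ``design`` is the ordered list of group names to compare (2 groups:
    t-test; >= 3: ANOVA + SNK).  Group means and the fold gate use the
    linear scale; tests run on log-scale values.  BH adjustment spans all
    expressed contigs.  Technical replicates count as ordinary
    observations.
    """
    if table.log_scale:
        raise ValueError("de_table expects linear-scale intensities")
    design = list(design)
    known = set(table.samples["group"])
    unknown = [g for g in design if g not in known]
    if unknown:
        raise KeyError(f"unknown groups in design: {unknown}")
    if len(design) < 2:
        raise ValueError("design needs at least two groups")

    group_cols = {g: table.group_samples(g) for g in design}
    logged = log_transform(table, base=log_base, offset=log_offset)

    means = pd.DataFrame({g: table.values[cols].mean(axis=1)
                          for g, cols in group_cols.items()})
    max_mean = means.max(axis=1)
    min_mean = means.min(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(min_mean > 0, max_mean / min_mean, np.inf)
    expressed = max_mean >= thresholds.min_mean_intensity

    pvals = np.full(len(means), np.nan)
    mse = np.full(len(means), np.nan)
    dfe = np.zeros(len(means), dtype=int)
    logvals = {g: logged.values[cols].to_numpy() for g, cols in group_cols.items()}
    expressed_idx = np.flatnonzero(expressed.to_numpy())
    for i in expressed_idx:
        obs = [logvals[g][i] for g in design]
        if len(design) == 2:
            _, pvals[i] = two_group_ttest(obs[0], obs[1])
        else:
            _, pvals[i] = one_way_anova(obs)
        n_total = sum(len(o) for o in obs)
        dfe[i] = n_total - len(design)
        mse[i] = sum(((o - o.mean()) ** 2).sum() for o in obs) / dfe[i]

    p_adj = np.full(len(means), np.nan)
    if expressed_idx.size:
        p_adj[expressed_idx] = bh_adjust(pvals[expressed_idx])

    snk_strings = [""] * len(means)
    if len(design) > 2:
        log_group_means = {g: logvals[g].mean(axis=1) for g in design}
        sizes = [len(group_cols[g]) for g in design]
        for i in expressed_idx:
            if p_adj[i] <= thresholds.alpha and mse[i] > 0:
                subsets = snk_posthoc([log_group_means[g][i] for g in design],
                                      sizes, mse[i], dfe[i], thresholds.alpha)
                snk_strings[i] = "|".join(
                    letter_display(subsets, len(design)))

    relevant = (expressed.to_numpy()
                & (p_adj <= thresholds.alpha)
                & (ratio >= thresholds.min_fold))

    out = pd.DataFrame({"contig_id": means.index})
    for g in design:
        out[f"mean_{g}"] = means[g].to_numpy()
    out["ratio"] = ratio
    out["p"] = pvals
    out["p_adj"] = p_adj
    out["snk_groups"] = snk_strings
    out["expressed"] = expressed.to_numpy()
    out["relevant"] = relevant
    return out


def heatmap_matrix(records: pd.DataFrame, log_base: float = 2.0,
                   log_offset: float = 1.0) -> pd.DataFrame:
    """Masked log-mean table: rows contigs, columns groups.

    Cells of contigs that are not expressed above cutoff or not
    differentially expressed at a relevant level are emitted as missing.
    """
    groups = [c[len("mean_"):] for c in records.columns if c.startswith("mean_")]
    values = np.log(records[[f"mean_{g}" for g in groups]].to_numpy()
                    + log_offset) / np.log(log_base)
    mat = pd.DataFrame(values, index=records["contig_id"], columns=groups)
    mat[~records["relevant"].to_numpy()] = np.nan
    return mat
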