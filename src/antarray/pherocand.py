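"""Expression-factor screening of pheromone-receptor candidates.

Within one group (the phenotype carrying a macroglomerulus: large
workers, or males), each odorant-receptor gene's expression level is
summarized as its log-transformed intensity (LTI; mean over biological
replicates) and standardized against the whole OR-related gene set:

    EF = (LTI_cand - LTI_mean) / SD

i.e. a z-score within the OR gene set, using the sample standard
deviation (n-1) of the LTI vector.  A gene is a screening candidate
when it is both highly expressed overall (EF >= ef_min, default 2) and
enriched in the focal group beyond the grey band of biologically
irrelevant log-fold differences (log_fold >= band half-width, default
0.5 on the log2 scale, i.e. about 1.4-fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrayproc import ContigExpressionTable


def compute_lti(table: ContigExpressionTable, group: str, gene_set) -> pd.Series:
    """Per-gene mean of log-scale values over a group's biological replicates.

    Technical replicates are excluded by definition of the LTI.
    """
    if not table.log_scale:
        raise ValueError("LTI requires a log-scale expression table")
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set must be nonempty")
    missing = [g for g in gene_set if g not in table.values.index]
    if missing:
        raise KeyError(f"genes absent from table: {missing[:10]}")
    cols = table.group_samples(group, biological_only=True)
    lti = table.values.loc[gene_set, cols].mean(axis=1)
    lti.name = f"lti_{group}"
    return lti


@dataclass
class EFContext:
    """LTI vector of one gene set in one group, with its mean and SD."""

    group: str
    lti: pd.Series
    lti_mean: float
    sd: float


def build_ef_context(table: ContigExpressionTable, group: str, gene_set) -> EFContext:
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("gene set needs at least two members")
    lti = compute_lti(table, group, gene_set)
    sd = float(lti.std(ddof=1))
    if sd == 0.0:
        raise ValueError(f"degenerate gene set in group {group!r}: "
                         "all LTIs identical (SD = 0)")
    return EFContext(group=group, lti=lti, lti_mean=float(lti.mean()), sd=sd)


def expression_factor(context: EFContext, gene: str) -> float:
    """EF of one gene: (LTI_cand - LTI_mean) / SD."""
    if gene not in context.lti.index:
        raise KeyError(f"gene {gene!r} not in the EF context's gene set")
    return (float(context.lti[gene]) - context.lti_mean) / context.sd


def expression_factors(context: EFContext) -> pd.Series:
    """EF for the whole gene set (mean 0, sample SD 1 by construction)."""
    ef = (context.lti - context.lti_mean) / context.sd
    ef.name = "ef"
    return ef


def log_fold(table: ContigExpressionTable, group_a: str, group_b: str,
             gene: str) -> float:
    """LTI difference between two groups; antisymmetric under swapping."""
    lti_a = compute_lti(table, group_a, [gene])
    lti_b = compute_lti(table, group_b, [gene])
    return float(lti_a.iloc[0] - lti_b.iloc[0])


def candidate_screen(table: ContigExpressionTable, group_a: str, group_b: str,
                     gene_set, ef_min: float = 2.0,
                     band_halfwidth: float = 0.5) -> pd.DataFrame:
    """Rank a gene set by EF in the focal group and flag candidates.

    Candidates satisfy EF >= ``ef_min`` and a focal-vs-comparison log-fold
    difference of at least ``band_halfwidth`` (outside the grey band, and
    enriched in the focal group).  Output is sorted by EF descending,
    ties broken by log_fold descending, then gene id.
    """
    if ef_min < 0 or band_halfwidth < 0:
        raise ValueError("ef_min and band_halfwidth must be nonnegative")
    gene_set = sorted(gene_set)
    ctx = build_ef_context(table, group_a, gene_set)
    ef = expression_factors(ctx)
    lti_b = compute_lti(table, group_b, gene_set)
    lfold = ctx.lti - lti_b
    base = table.log_base if table.log_base is not None else 2.0
    out = pd.DataFrame({
        "gene_id": gene_set,
        "lti_cand": ctx.lti.to_numpy(),
        "ef": ef.to_numpy(),
        "log_fold": lfold.to_numpy(),
        "fold_linear": np.power(base, lfold.to_numpy()),
        "candidate": (ef.to_numpy() >= ef_min)
                     & (lfold.to_numpy() >= band_halfwidth),
    })
    out = out.sort_values(["ef", "log_fold", "gene_id"],
                          ascending=[False, False, True], kind="stable")
    return out.reset_index(drop=True)


def percentile_rank(table: ContigExpressionTable, group: str, gene: str,
                    reference_set) -> float:
    """Percentile of a gene's LTI within a reference gene set (0..100).

    Counts reference genes strictly below the gene's LTI; ties (including
    the gene itself if it belongs to the reference set) count one half.
    """
    reference_set = list(reference_set)
    if not reference_set:
        raise ValueError("reference set must be nonempty")
    ref = compute_lti(table, group, reference_set).to_numpy()
    val = float(compute_lti(table, group, [gene]).iloc[0])
    below = np.count_nonzero(ref < val)
    ties = np.count_nonzero(ref == val)
    return 100.0 * (below + 0.5 * ties) / len(reference_set)
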