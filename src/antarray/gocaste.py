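"""GO-term summaries and per-term presence/absence comparisons.

Term frequencies slice the annotation table by ontology category and
level (a contig counts once per distinct term it carries).  The caste
comparison asks, term by term, whether the proportion of detectably
expressed contigs carrying the term differs between groups: a contig is
group-present when it is called present on at least half of that
group's arrays, and each term's 2 x k table (annotated vs not, among
present contigs, per group) is tested with Pearson's chi-square without
continuity correction.  Tests are per term, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class TermComparison:
    term_id: str
    table: pd.DataFrame          # rows: annotated/not_annotated, cols: groups
    chi2: float
    df: int
    p: float
    low_expected: bool
    skipped: bool = False
    note: str = ""


def term_frequencies(annotations: pd.DataFrame, category: str,
                     level: int) -> pd.Series:
    """Distinct-contig counts per term within one (category, level) slice."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of "
                         f"{CATEGORIES}")
    sub = annotations[(annotations["category"] == category)
                      & (annotations["level"] == level)]
    sub = sub.drop_duplicates(["contig_id", "term_id"])
    counts = sub.groupby("term_id")["contig_id"].nunique().sort_index()
    counts.name = "n_contigs"
    return counts


def group_presence(presence: pd.DataFrame, samples: pd.DataFrame,
                   groups) -> pd.DataFrame:
    """Majority-rule group-level presence from per-array calls.

    A contig is present in a group when called present on >= 50% of that
    group's arrays (technical replicates included like any array).
    """
    out = {}
    for g in groups:
        cols = samples.index[samples["group"] == g].tolist()
        if not cols:
            raise KeyError(f"no samples for group {g!r}")
        out[g] = presence[cols].mean(axis=1) >= 0.5
    return pd.DataFrame(out)


def _presence_counts(presence: pd.DataFrame, samples: pd.DataFrame,
                     groups, unit: str) -> pd.DataFrame:
    """Per-group observation weights per contig.

    ``unit='contigs'``: 0/1 by the majority rule (each present contig is
    one observation).  ``unit='arrays'``: the number of arrays the contig
    is called present on (each present contig x array cell counts).
    """
    if unit == "contigs":
        return group_presence(presence, samples, groups).astype(int)
    if unit == "arrays":
        out = {}
        for g in groups:
            cols = samples.index[samples["group"] == g].tolist()
            if not cols:
                raise KeyError(f"no samples for group {g!r}")
            out[g] = presence[cols].sum(axis=1)
        return pd.DataFrame(out)
    raise ValueError(f"unknown observation unit {unit!r}")


def _term_table(term: str, gpresence: pd.DataFrame,
                annotations: pd.DataFrame) -> pd.DataFrame:
    annotated = set(annotations.loc[annotations["term_id"] == term, "contig_id"])
    is_annot = gpresence.index.isin(annotated)
    n_present = gpresence.sum(axis=0)
    n_annot_present = gpresence[is_annot].sum(axis=0)
    return pd.DataFrame({g: [int(n_annot_present[g]),
                             int(n_present[g] - n_annot_present[g])]
                         for g in gpresence.columns},
                        index=["annotated", "not_annotated"])


def _compare_term(term: str, gpres: pd.DataFrame, annotations: pd.DataFrame,
                  groups) -> TermComparison:
    tab = _term_table(term, gpres, annotations)
    obs = tab.to_numpy(dtype=float)
    df = (len(groups) - 1) * (2 - 1)
    if (obs.sum(axis=0) == 0).any():
        empty = [g for g, s in zip(groups, obs.sum(axis=0)) if s == 0]
        return TermComparison(term, tab, np.nan, df, np.nan, False,
                              skipped=True,
                              note=f"no present contigs in {empty}")
    if (obs.sum(axis=1) == 0).any():
        return TermComparison(term, tab, 0.0, df, 1.0, True,
                              note="degenerate table (all-zero row)")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    return TermComparison(term, tab, float(chi2), int(dof), float(p),
                          bool((expected < 5).any()))


def per_term_chisq(term: str, presence: pd.DataFrame,
                   annotations: pd.DataFrame, samples: pd.DataFrame,
                   groups, unit: str = "contigs") -> TermComparison:
    """Pearson chi-square on one term's 2 x k presence table.

    ``unit`` selects the observation: distinct present contigs (default,
    majority rule per group) or present contig-array cells.  Expected
    counts below 5 are flagged, not corrected.  A group with no present
    contigs makes the test undefined; it is skipped and flagged.
    Degenerate tables with an all-zero row (term never or always carried)
    have statistic 0 and p = 1 by convention.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gpres = _presence_counts(presence, samples, groups, unit)
    return _compare_term(term, gpres, annotations, groups)


def screen_all_terms(annotations: pd.DataFrame, presence: pd.DataFrame,
                     samples: pd.DataFrame, groups, alpha: float = 0.05,
                     unit: str = "contigs") -> tuple[pd.DataFrame, str]:
    """One uncorrected chi-square per term, sorted by p ascending.

    Returns the per-term results and a one-line summary stating whether
    any term differs at the given alpha.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    terms = sorted(annotations["term_id"].unique())
    gpres = _presence_counts(presence, samples, groups, unit)
    rows = []
    for term in terms:
        r = _compare_term(term, gpres, annotations, groups)
        rows.append({"term_id": term, "chi2": r.chi2, "df": r.df, "p": r.p,
                     "low_expected": r.low_expected, "skipped": r.skipped,
                     **{f"annotated_{g}": int(r.table.loc["annotated", g])
                        for g in groups},
                     **{f"not_annotated_{g}": int(r.table.loc["not_annotated", g])
                        for g in groups}})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    n_sig = int((out["p"] <= alpha).sum()) if len(out) else 0
    if n_sig:
        summary = (f"{n_sig}/{len(out)} terms differ between groups "
                   f"{groups} at p <= {alpha}")
    else:
        summary = (f"no term differs between groups {groups} at "
                   f"p <= {alpha} (all p-values > {alpha})")
    return out, summary


def levels_from_edges(edges: pd.DataFrame, roots) -> pd.Series:
    """Optional helper: level = 1 + shortest-path distance from a root.

    ``edges`` has columns (term_id, parent_id); ``roots`` are the category
    root terms (level 1).  Terms unreachable from any root get no level.
    """
    parents: dict[str, list[str]] = {}
    for child, parent in edges[["term_id", "parent_id"]].itertuples(index=False):
        parents.setdefault(parent, []).append(child)
    level: dict[str, int] = {r: 1 for r in roots}
    frontier = list(roots)
    while frontier:
        nxt = []
        for node in frontier:
            for child in parents.get(node, ()):
                if child not in level:
                    level[child] = level[node] + 1
                    nxt.append(child)
        frontier = nxt
    return pd.Series(level, name="level").sort_index()
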