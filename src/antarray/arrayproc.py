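"""Probe-level preprocessing for single-color expression arrays.

The processing chain mirrors standard one-color microarray practice:
quantile-normalize the probe intensities of each hybridization batch
(dataset) so all arrays share one intensity distribution, average the
probes designed against the same contig, log-transform, and derive
per-array presence/absence calls against an absolute intensity cutoff.

Two thin containers carry the data through the chain:

``IntensityMatrix``
    probes x samples nonnegative intensities plus a sample sheet
    (group, dataset, replicate type).
``ContigExpressionTable``
    contigs x samples aggregated intensities; the unit on which all
    downstream statistics operate.  Carries a flag (and base/offset)
    once log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIOLOGICAL = "biological"
TECHNICAL = "technical"

#: required sample-sheet columns
SAMPLE_COLUMNS = ("group", "dataset", "replicate_type")


def _check_sample_sheet(values: pd.DataFrame, samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns: {missing}")
    if not values.columns.equals(samples.index):
        if set(values.columns) != set(samples.index):
            raise ValueError("sample sheet does not cover the value columns")


@dataclass
class IntensityMatrix:
    """Probe intensities with sample annotations.

    Parameters
    ----------
    values : DataFrame
        Rows are probe ids, columns sample ids; nonnegative, no missing
        values (background-subtracted fluorescence, floor-clipped).
    samples : DataFrame
        Indexed by sample id with columns ``group``, ``dataset``,
        ``replicate_type``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_sample_sheet(self.values, self.samples)
        if self.values.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensity matrix contains negative values")

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        sample_ids = list(sample_ids)
        return IntensityMatrix(self.values[sample_ids], self.samples.loc[sample_ids])


@dataclass
class ContigExpressionTable:
    """Per-contig expression values (linear or log scale) per sample."""

    values: pd.DataFrame
    samples: pd.DataFrame
    log_scale: bool = False
    log_base: float | None = None
    log_offset: float | None = None

    def __post_init__(self) -> None:
        _check_sample_sheet(self.values, self.samples)

    def subset_samples(self, sample_ids) -> "ContigExpressionTable":
        sample_ids = list(sample_ids)
        return replace(self, values=self.values[sample_ids],
                       samples=self.samples.loc[sample_ids])

    def group_samples(self, group: str, biological_only: bool = False) -> list[str]:
        sheet = self.samples
        mask = sheet["group"] == group
        if biological_only:
            mask &= sheet["replicate_type"] == BIOLOGICAL
        ids = sheet.index[mask].tolist()
        if not ids:
            raise KeyError(f"no samples for group {group!r}")
        return ids


def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-order-statistics quantile normalization (Bolstad).

    Every column receives the identical multiset of values: the vector of
    row-wise means of the per-column order statistics.  Ties within a
    column are assigned the mean of the normalized values over their tied
    ranks, so the map is well defined and rank-preserving.
    """
    arr = values.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(col)
        ranked[order] = mean_sorted
        # average over tied ranks
        tied = pd.Series(ranked).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: IntensityMatrix, dataset) -> IntensityMatrix:
    """Quantile-normalize the samples belonging to one dataset.

    Datasets are hybridization batches and are normalized separately;
    mixing samples across datasets violates the contract.
    """
    in_ds = matrix.samples["dataset"] == dataset
    if not in_ds.any():
        raise ValueError(f"no samples with dataset id {dataset!r}")
    sample_ids = matrix.samples.index[in_ds].tolist()
    if len(sample_ids) < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    sub = matrix.subset_samples(sample_ids)
    return IntensityMatrix(_quantile_normalize_frame(sub.values), sub.samples)


def quantile_normalize_within_datasets(matrix: IntensityMatrix) -> IntensityMatrix:
    """Normalize each dataset separately and re-join the columns."""
    parts = [quantile_normalize(matrix, ds)
             for ds in pd.unique(matrix.samples["dataset"])]
    values = pd.concat([p.values for p in parts], axis=1)[matrix.values.columns]
    return IntensityMatrix(values, matrix.samples)


def aggregate_probes(matrix: IntensityMatrix, probes: pd.DataFrame) -> ContigExpressionTable:
    """Pool a contig's probes into one value per (contig, sample).

    Pooling is the unweighted arithmetic mean of the probe intensities,
    including both reading directions for unknown-ORF contigs.
    """
    if "probe_id" not in probes.columns or "contig_id" not in probes.columns:
        raise ValueError("probe map needs probe_id and contig_id columns")
    pmap = probes.set_index("probe_id")["contig_id"]
    unknown = matrix.values.index.difference(pmap.index)
    if len(unknown) > 0:
        raise KeyError(f"probes missing from probe map: {sorted(unknown)[:10]}"
                       f" ({len(unknown)} total)")
    contig_of = pmap.reindex(matrix.values.index)
    values = matrix.values.groupby(contig_of.to_numpy()).mean()
    values.index.name = "contig_id"
    return ContigExpressionTable(values, matrix.samples)


def log_transform(table: ContigExpressionTable, base: float = 2.0,
                  offset: float = 1.0) -> ContigExpressionTable:
    """Elementwise value -> log_base(value + offset).

    The default ``offset=1`` maps floor-clipped zero intensities to 0 on
    the log scale.  Already log-scaled tables are rejected.
    """
    if table.log_scale:
        raise ValueError("table is already on the log scale")
    if base <= 1:
        raise ValueError("log base must exceed 1")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    shifted = table.values + offset
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("value + offset must be positive for log transform")
    values = np.log(shifted) / np.log(base)
    return ContigExpressionTable(values, table.samples, log_scale=True,
                                 log_base=base, log_offset=offset)


def presence_calls(table: ContigExpressionTable, threshold: float = 100.0) -> pd.DataFrame:
    """Per-sample boolean present/absent calls on aggregated intensities.

    A contig is called present on an individual array when its aggregated
    linear-scale intensity is at or above ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("presence threshold must be positive")
    if table.log_scale:
        raise ValueError("presence calls operate on linear-scale intensities")
    return table.values >= threshold
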