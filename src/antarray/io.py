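"""Plain-text (TSV) readers and writers for all pipeline artifacts."""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .arrayproc import ContigExpressionTable, IntensityMatrix


def write_probe_map(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "contig_id": str})


def write_intensity_matrix(matrix: IntensityMatrix, values_path,
                           samples_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.samples.to_csv(samples_path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_intensity_matrix(values_path, samples_path) -> IntensityMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    return IntensityMatrix(values, read_sample_sheet(samples_path))


def write_contig_table(table: ContigExpressionTable, values_path,
                       samples_path=None) -> None:
    table.values.to_csv(values_path, sep="\t")
    if samples_path is not None:
        table.samples.to_csv(samples_path, sep="\t")


def read_contig_table(values_path, samples_path) -> ContigExpressionTable:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    return ContigExpressionTable(values, read_sample_sheet(samples_path))


def write_truth(truth, spikes_path, baselines_path=None) -> None:
    truth.spikes.to_csv(spikes_path, sep="\t", index=False)
    if baselines_path is not None:
        truth.baselines.to_csv(baselines_path, sep="\t")


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"contig_id": str, "term_id": str,
                              "category": str, "level": int})


def read_geo_series_matrix(path, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a GEO series-matrix text file into a probes x samples frame.

    Lines starting with ``!`` (metadata) are skipped; the remaining block
    is tab-separated with an ``ID_REF`` first column.  Quoted fields are
    handled by the CSV reader.
    """
    text = Path(path).read_text()
    data_lines = [ln for ln in text.splitlines()
                  if ln.strip() and not ln.startswith("!")]
    frame = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep="\t",
                        index_col=0)
    frame.index.name = "probe_id"
    return frame
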