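import numpy as np
import pandas as pd
import pytest

from antarray import arrayproc, simdata


def run_to_contigs(cfg: simdata.SimConfig) -> arrayproc.ContigExpressionTable:
    """Simulate, quantile-normalize per dataset, and aggregate to contigs."""
    probes = simdata.design_probes(cfg)
    matrix, _ = simdata.simulate_intensities(probes, cfg)
    norm = arrayproc.quantile_normalize_within_datasets(matrix)
    return arrayproc.aggregate_probes(norm, probes)


def make_matrix(values: np.ndarray, groups=None, dataset=1) -> arrayproc.IntensityMatrix:
    """Small hand-built IntensityMatrix with a minimal sample sheet."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if groups is None:
        groups = ["g"] * n_samples
    sheet = pd.DataFrame({
        "group": groups,
        "dataset": [dataset] * n_samples,
        "replicate_type": [arrayproc.BIOLOGICAL] * n_samples,
    }, index=pd.Index(sample_ids, name="sample_id"))
    frame = pd.DataFrame(values, index=[f"p{i}" for i in range(n_probes)],
                         columns=sample_ids)
    return arrayproc.IntensityMatrix(frame, sheet)


def make_log_table(values: np.ndarray, groups, replicate_types=None,
                   dataset=1) -> arrayproc.ContigExpressionTable:
    """Hand-built log2-scale contig table (genes x samples)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if replicate_types is None:
        replicate_types = [arrayproc.BIOLOGICAL] * n_samples
    sheet = pd.DataFrame({
        "group": groups,
        "dataset": [dataset] * n_samples,
        "replicate_type": replicate_types,
    }, index=pd.Index(sample_ids, name="sample_id"))
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                         columns=sample_ids)
    return arrayproc.ContigExpressionTable(frame, sheet, log_scale=True,
                                           log_base=2.0, log_offset=0.0)


@pytest.fixture
def tiny_config() -> simdata.SimConfig:
    return simdata.SimConfig(
        n_contigs=12, n_or_contigs=3, frac_known_orf=0.5,
        groups=(simdata.GroupSpec("queens", 1, 4),
                simdata.GroupSpec("males", 1, 4),
                simdata.GroupSpec("workers", 1, 3, 1)),
        seed=7,
    )
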