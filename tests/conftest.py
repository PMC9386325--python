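import numpy as np
import pandas as pd
import pytest

from telohallmark import synthdata


@pytest.fixture
def small_expression_params() -> synthdata.ExpressionParams:
    """A reduced panel that keeps the four TERT probes and the planted
    candidate genes but runs in well under a second."""
    return synthdata.ExpressionParams(
        n_disease_free=20,
        n_aggressive=16,
        n_genes=40,
        n_probes=50,
        total_reads=60_000,
    )


@pytest.fixture
def small_cfg(small_expression_params) -> synthdata.SynthConfig:
    return synthdata.SynthConfig(
        seed=11,
        expression=small_expression_params,
        methylation=synthdata.MethylationParams(
            class_sizes={"high": 5, "moderate": 6, "low": 6}, coverage=500
        ),
        telomere=synthdata.TelomereParams(
            n_normal_specimens=5,
            n_tumours_normal=4,
            n_tumours_short=4,
            nuclei_per_specimen=50,
            signals_per_nucleus=10,
        ),
        genome=synthdata.GenomeParams(
            n_chromosomes=2, chrom_length=30_000_000, centromere=(13_000_000, 17_000_000),
            genes_per_window=20, n_short=6, n_normal=4,
        ),
        pairs=synthdata.PairParams(nuclei_per_specimen=120),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_log2cpm(values: np.ndarray, genes=None, samples=None):
    """Wrap a plain array as a Log2CpmMatrix for fence/outlier tests."""
    from telohallmark.panelexpr import Log2CpmMatrix

    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return Log2CpmMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        target_total=None,
        pseudocount=0.5,
    )
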