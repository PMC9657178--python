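from pathlib import Path

import numpy as np
import pytest

from degconsensus import CountMatrix, Dataset, SampleInfo
from degconsensus.simulate import SimDesign, simulate_dataset

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def counts_path() -> Path:
    return DATA / "cts_table1.tsv"


@pytest.fixture(scope="session")
def coldata_path() -> Path:
    return DATA / "coldata_table2.tsv"


@pytest.fixture(scope="session")
def small_sim():
    """Small two-condition simulation with true DEGs, shared across tests."""
    return simulate_dataset(
        SimDesign(G=400, n_ref=4, n_trt=4, pi_de=0.1, lfc_magnitude=2.0,
                  dispersion=0.1, seed=42)
    )


@pytest.fixture(scope="session")
def recovery_sim():
    """The reference recovery design: 2000 genes, 5+5, 10% DEGs at |lfc|=2."""
    return simulate_dataset(
        SimDesign(G=2000, n_ref=5, n_trt=5, pi_de=0.1, lfc_magnitude=2.0,
                  dispersion=0.1, seed=1)
    )


def toy_dataset(counts: np.ndarray, n_ref: int, n_trt: int) -> Dataset:
    """Tiny in-memory dataset, reference samples first."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[1]
    assert n == n_ref + n_trt
    names = tuple(f"ref{i+1}" for i in range(n_ref)) + tuple(
        f"trt{i+1}" for i in range(n_trt)
    )
    cond = ("ref",) * n_ref + ("trt",) * n_trt
    cm = CountMatrix(
        gene_ids=tuple(f"g{i+1}" for i in range(counts.shape[0])),
        sample_names=names,
        counts=counts,
    )
    info = SampleInfo(sample_names=names, condition=cond)
    return Dataset(counts=cm, design=info, condition_order=("ref", "trt"))
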