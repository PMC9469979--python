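import numpy as np
import pandas as pd
import pytest

from sarcoseq import CountMatrix, MarkerConfig, SimulationConfig, simulate_counts


def make_cm(counts: np.ndarray, labels: list[str],
            genes: list[str] | None = None,
            samples: list[str] | None = None) -> CountMatrix:
    """Small handmade count matrix with one label per sample."""
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    md = pd.DataFrame(
        {"subtype": labels},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), md
    )


@pytest.fixture
def tiny_cm() -> CountMatrix:
    counts = np.array(
        [
            [10, 12, 4, 5],
            [100, 90, 110, 95],
            [0, 1, 50, 40],
        ]
    )
    return make_cm(counts, ["A", "A", "B", "B"])


@pytest.fixture
def small_config() -> SimulationConfig:
    """Downscaled simulation for fast unit tests."""
    return SimulationConfig(
        n_genes=400,
        group_sizes=(5, 5, 5),
        n_degs_per_group=30,
        deg_log2fc=2.5,
        dispersion=0.1,
        marker_config=MarkerConfig(n_single=1, n_pairs=1),
        seed=11,
    )


@pytest.fixture
def small_study(small_config):
    return simulate_counts(small_config)
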