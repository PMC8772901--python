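import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hybridexpr import CountMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SAMPLES = ["PC_1", "PC_2", "PB_1", "PB_2", "F1BC_1", "F1BC_2", "F1CB_1", "F1CB_2"]
TYPES = ["PC", "PC", "PB", "PB", "F1BC", "F1BC", "F1CB", "F1CB"]


def make_count_matrix(counts: np.ndarray, lengths=None, gene_ids=None) -> CountMatrix:
    """Wrap a raw gene x 8-sample array in a validated CountMatrix."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(n)]
    if lengths is None:
        lengths = np.full(n, 1000)
    idx = pd.Index(gene_ids, name="gene_id")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=SAMPLES),
        lengths=pd.Series(lengths, index=idx, name="length_bp"),
        type_map=pd.Series(TYPES, index=pd.Index(SAMPLES, name="sample_id")),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng) -> CountMatrix:
    """20 genes x 8 samples of modest random counts."""
    return make_count_matrix(
        rng.integers(0, 500, size=(20, 8)), lengths=rng.integers(200, 3000, size=20)
    )
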