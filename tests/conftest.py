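import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from reosig import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with distinct values."""
    return ExpressionMatrix.from_arrays(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ["G1", "G2", "G3"],
        ["S1", "S2"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_matrix(rng, n_genes, n_samples, prefix="G", ties=False, noise_sd=0.4):
    """Structured random cohort: per-gene log-means spread wide enough
    that many pair orderings are stable across samples."""
    mu = rng.normal(0.0, 2.0, n_genes)
    values = np.exp(mu[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples)))
    if ties:
        # quantize to force exact ties, including zeros
        values = np.round(values, 1)
    return ExpressionMatrix.from_arrays(
        values,
        [f"{prefix}{i:03d}" for i in range(n_genes)],
        [f"S{j:02d}" for j in range(n_samples)],
    )
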