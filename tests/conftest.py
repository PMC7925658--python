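import numpy as np
import pandas as pd
import pytest

from refstab.cq_data import CqDataset


def dataset_from_matrix(
    cq: np.ndarray,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
    tissues: list[str] | None = None,
    stages: list[str] | None = None,
) -> CqDataset:
    """Build a collapsed CqDataset from a gene x sample Cq matrix."""
    cq = np.asarray(cq, float)
    k, n = cq.shape
    genes = genes or [f"g{i}" for i in range(k)]
    samples = samples or [f"s{j}" for j in range(n)]
    tissues = tissues or ["root"] * n
    stages = stages or ["May"] * n
    rows = [
        (samples[j], genes[i], 1, 1, cq[i, j])
        for i in range(k)
        for j in range(n)
    ]
    data = pd.DataFrame(rows, columns=["sample", "gene", "bio_rep", "tech_rep", "cq"])
    design = pd.DataFrame(
        {"sample": samples, "tissue": tissues, "stage": stages}
    )
    return CqDataset(data, design)


@pytest.fixture
def abc_dataset() -> CqDataset:
    """Three genes over four samples: A and B share a profile, C deviates."""
    return dataset_from_matrix(
        [[20, 21, 22, 23], [20, 21, 22, 23], [20, 22, 21, 23]],
        genes=["A", "B", "C"],
    )


@pytest.fixture
def random_matrix_dataset():
    """Factory for random complete Cq matrices (seeded)."""

    def make(k: int, n: int, seed: int = 0) -> CqDataset:
        rng = np.random.default_rng(seed)
        cq = 20.0 + rng.normal(0.0, 1.5, size=(k, n)).round(4)
        return dataset_from_matrix(cq)

    return make
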