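import numpy as np
import pytest

from oncophase import (
    ConnectivityMatrix,
    MutationMatrix,
    VariantClass,
    VariantRecord,
)


@pytest.fixture
def four_sample_matrix() -> MutationMatrix:
    """Two genes, four samples: three consistent with A-before-B progression,
    one (s4) carrying only the late gene."""
    return MutationMatrix(
        ("s1", "s2", "s3", "s4"),
        ("A", "B"),
        np.array([[1, 0], [1, 0], [1, 1], [0, 1]]),
    )


@pytest.fixture
def unit_connectivity() -> ConnectivityMatrix:
    """One expression gene per mutation gene, one-hot wired."""
    return ConnectivityMatrix(
        ("e1", "e2"), ("A", "B"), np.eye(2), normalized=True
    )


@pytest.fixture
def oncogene_records() -> list[VariantRecord]:
    """25 variants: 10 missense at one hotspot residue, 5 missense at distinct
    residues, 5 nonsense, 5 silent. Hand count: gof=10, lof=5."""
    recs = [
        VariantRecord("GENE1", f"s{i}", VariantClass.MISSENSE, 1047) for i in range(10)
    ]
    recs += [
        VariantRecord("GENE1", f"s{10 + i}", VariantClass.MISSENSE, 100 + i)
        for i in range(5)
    ]
    recs += [
        VariantRecord("GENE1", f"s{15 + i}", VariantClass.NONSENSE, 50 + i)
        for i in range(5)
    ]
    recs += [
        VariantRecord("GENE1", f"s{20 + i}", VariantClass.SILENT, None) for i in range(5)
    ]
    return recs


def random_small_instance(rng: np.random.Generator, allow_zero_rows: bool = True):
    """A random (M, C normalized, K, W) quadruple small enough for exhaustive search."""
    K = int(rng.integers(2, 4))
    n = int(rng.integers(K, 7))
    m = int(rng.integers(2, 9))
    r = int(rng.integers(1, 7))
    M = MutationMatrix(
        tuple(f"s{i}" for i in range(m)),
        tuple(f"g{j}" for j in range(n)),
        (rng.random((m, n)) < 0.35).astype(np.int8),
    )
    C_raw = rng.random((r, n)) * (rng.random((r, n)) < 0.7)
    if allow_zero_rows and r > 1 and rng.random() < 0.3:
        C_raw[0] = 0.0
    sums = C_raw.sum(axis=1, keepdims=True)
    C_vals = np.divide(C_raw, sums, out=np.zeros_like(C_raw), where=sums > 0)
    C = ConnectivityMatrix(
        tuple(f"e{h}" for h in range(r)),
        M.gene_ids,
        C_vals,
        normalized=True,
    )
    W = float(rng.choice([0.0, 0.5, 1.0]))
    return M, C, K, W
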