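import numpy as np
import pandas as pd
import pytest

import basecomp as bc


@pytest.fixture(scope="session")
def small_cfg() -> bc.SimulationConfig:
    """Scaled-down cohort for fast unit tests (structure, not power)."""
    return bc.SimulationConfig(
        n_samples=40,
        n_genes=400,
        n_tumor_targets=12,
        n_env_targets=17,
        n_nonspecific_targets=9,
        n_pos_background=40,
        n_neg_background=40,
        n_decoy_bindings=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return bc.simulate_two_compartment(small_cfg)


@pytest.fixture(scope="session")
def small_profile(small_cohort):
    em = bc.median_normalize(small_cohort.expression)
    return bc.build_profile(small_cohort.binding, em, small_cohort.purity, tf_name="TF")


@pytest.fixture()
def toy_expression() -> bc.ExpressionMatrix:
    values = pd.DataFrame(
        {
            "s1": [1.0, 4.0, 2.0, 0.0],
            "s2": [2.0, 3.0, 2.0, 1.0],
            "s3": [3.0, 5.0, 2.0, -1.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="gene"),
    )
    return bc.ExpressionMatrix(values=values)


def naive_base(g: np.ndarray, w: np.ndarray, gene_ids=None):
    """Independent O(n^2) recomputation of f, b and the signed max deviation.

    Sorts by expression descending with gene-id tie-break, then evaluates the
    two cumulative-distribution definitions term by term.
    """
    n = len(g)
    if gene_ids is None:
        gene_ids = [f"x{i}" for i in range(n)]
    idx = sorted(range(n), key=lambda i: (-g[i], gene_ids[i]))
    gg = np.array([g[i] for i in idx], dtype=float)
    ww = np.array([w[i] for i in idx], dtype=float)
    f = np.zeros(n)
    b = np.zeros(n)
    denom_f = sum(abs(gg[k] * ww[k]) for k in range(n))
    denom_b = sum(abs(gg[k] * (1.0 - ww[k])) for k in range(n))
    for i in range(n):
        f[i] = sum(abs(gg[k] * ww[k]) for k in range(i + 1)) / denom_f
        b[i] = sum(abs(gg[k] * (1.0 - ww[k])) for k in range(i + 1)) / denom_b
    d = f - b
    best = 0
    for i in range(1, n):
        if abs(d[i]) > abs(d[best]):
            best = i
    return f, b, float(d[best])
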