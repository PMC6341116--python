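"""Shared fixtures and independent reference implementations (oracles).

The oracles are deliberately naive — exact fractions, explicit loops,
textbook formulas — so they stay independent of the vectorised code paths
they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import gosweep as gs


# ---------------------------------------------------------------------------
# oracles


def hypergeom_tail_bruteforce(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact-fraction enumeration of the full upper support."""
    total = math.comb(N, n)
    num = 0
    for i in range(k, min(n, K) + 1):
        if n - i <= N - K:
            num += math.comb(K, i) * math.comb(N - K, n - i)
    return num / total


def bh_reference(p: list[float]) -> list[float]:
    """Step-up BH by the literal definition: adj_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order):  # rank_pos 0-based
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def welch_p_reference(a, b) -> float:
    """Welch's two-sample two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(tstat), df)


def size_factors_bruteforce(K: np.ndarray) -> np.ndarray:
    """Median-of-ratios with explicit python loops."""
    n_genes, n_samples = K.shape
    geomeans = []
    for g in range(n_genes):
        row = K[g].astype(float)
        if np.all(row > 0):
            geomeans.append((g, math.exp(sum(math.log(v) for v in row) / n_samples)))
    out = []
    for j in range(n_samples):
        ratios = [K[g, j] / gm for g, gm in geomeans]
        out.append(float(np.median(ratios)))
    return np.array(out)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment at the default study conditions."""
    config = gs.SimulationConfig(seed=11)
    annotation, truth, counts = gs.simulate_experiment(config)
    return config, annotation, truth, counts


@pytest.fixture(scope="session")
def default_de_table(default_experiment):
    _, _, _, counts = default_experiment
    return gs.run_de(counts)


@pytest.fixture
def tiny_counts():
    """4 genes x (2+2) samples, hand-sized for exact checks."""
    counts = np.array(
        [
            [100, 110, 95, 400],
            [50, 55, 60, 45],
            [10, 12, 9, 11],
            [500, 480, 510, 490],
        ],
        dtype=np.int64,
    )
    return gs.CountMatrix(
        genes=["gA", "gB", "gC", "gD"],
        samples=["c1", "c2", "t1", "t2"],
        counts=counts,
        groups={"c1": 0, "c2": 0, "t1": 1, "t2": 1},
    )
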