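"""Shared fixtures: toy parcellations, tiny cohorts, naive oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rsfcnet.atlas import AtlasParcellation, load_parcellation


def make_toy_parcellation(network_sizes: dict[str, int]) -> AtlasParcellation:
    """Small non-strict parcellation with the given nodes per network."""
    rows = []
    nid = 0
    for net, size in network_sizes.items():
        for k in range(size):
            nid += 1
            rows.append({"node_id": nid, "node_name": f"{net.lower()}_{k}",
                         "hemisphere": "left" if nid % 2 else "right",
                         "network": net})
    return AtlasParcellation(table=pd.DataFrame(rows), strict=False)


@pytest.fixture(scope="session")
def default_parc() -> AtlasParcellation:
    return load_parcellation()


@pytest.fixture()
def toy_parc() -> AtlasParcellation:
    """Ten nodes in three networks, used by the oracle-equivalence tests."""
    return make_toy_parcellation({"VSN": 4, "SMN": 3, "DGN": 3})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_symmetric_z(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with zero diagonal (a synthetic z matrix)."""
    a = rng.normal(size=(n, n))
    z = (a + a.T) / 2
    np.fill_diagonal(z, 0.0)
    return z


# ---------------------------------------------------------------------------
# naive double-loop oracles, kept deliberately independent of the package
# implementations they check
# ---------------------------------------------------------------------------

def oracle_pearson(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    return sxy / (sxx * syy) ** 0.5


def oracle_integrity(conv: np.ndarray) -> np.ndarray:
    n = conv.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = sum(conv[i, j] for j in range(n) if j != i) / (n - 1)
    return out


def oracle_network_fc(z: np.ndarray, labels: list[str],
                      order: list[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for net in order:
        vals = [z[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
                if labels[i] == net and labels[j] == net]
        out[f"intra_{net}"] = sum(vals) / len(vals) if vals else float("nan")
    for ai, a in enumerate(order):
        for b in order[ai + 1:]:
            vals = [z[i, j] for i in range(len(labels))
                    for j in range(len(labels))
                    if labels[i] == a and labels[j] == b]
            out[f"inter_{a}_{b}"] = sum(vals) / len(vals)
    return out


def oracle_pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa = sum((x - ma) ** 2 for x in a) / (na - 1)
    sb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    return (mb - ma) / (sp * (1 / na + 1 / nb)) ** 0.5


def oracle_bh(p: list[float], q: float) -> list[bool]:
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank / m * q:
            k = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k:
            reject[i] = True
    return reject


def exact_summary_values(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rescale a vector so its sample mean/SD (ddof=1) are exactly as given."""
    v = np.asarray(values, dtype=float)
    z = (v - v.mean()) / v.std(ddof=1)
    return mean + sd * z
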