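"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: shortest
paths by exhaustive simple-path enumeration, modularity optima by
exhaustive set-partition search, classical ANOVA by ordinary least squares
on a subject-blocked design.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles


def enumerate_shortest_paths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by exhaustive simple-path search.

    Edge length is 1/weight, matching the analysis convention.  Only
    feasible for small n; used to validate the Floyd-Warshall route.
    """
    n = adjacency.shape[0]
    with np.errstate(divide="ignore"):
        length = np.where(adjacency > 0, 1.0 / np.where(adjacency > 0, adjacency, 1), np.inf)
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def extend(node, target, visited, acc):
        if node == target:
            best[start, target] = min(best[start, target], acc)
            return
        if acc >= best[start, target]:
            return
        for nxt in range(n):
            if nxt not in visited and np.isfinite(length[node, nxt]):
                extend(nxt, target, visited | {nxt}, acc + length[node, nxt])

    for start in range(n):
        for target in range(n):
            if start != target:
                extend(start, target, {start}, 0.0)
    return best


def set_partitions(items):
    """All partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def exhaustive_best_modularity(adjacency: np.ndarray, gamma: float = 1.0):
    """Globally optimal modularity over every partition (small n only)."""
    from plvnet.graphs import modularity_value

    n = adjacency.shape[0]
    best_q, best_member = -np.inf, None
    for partition in set_partitions(range(n)):
        member = np.empty(n, dtype=int)
        for ci, block in enumerate(partition):
            member[block] = ci
        q = modularity_value(adjacency, member, gamma)
        if q > best_q:
            best_q, best_member = q, member
    return best_q, best_member


def classical_anova_f(table, metric: str):
    """Two-way within-subject ANOVA via OLS with subject as a blocking
    factor: F for each fixed term against the pooled residual."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    sub = table[table["metric"] == metric].copy()
    model = ols(
        "value ~ C(condition, Sum) * C(emotion, Sum) + C(subject)", data=sub
    ).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    out = {}
    resid_df = float(aov.loc["Residual", "df"])
    for row, term in [
        ("C(condition, Sum)", "condition"),
        ("C(emotion, Sum)", "emotion"),
        ("C(condition, Sum):C(emotion, Sum)", "condition:emotion"),
    ]:
        out[term] = (float(aov.loc[row, "F"]), float(aov.loc[row, "df"]), resid_df)
    return out


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.4):
    """Random symmetric weighted adjacency with the given edge density."""
    from plvnet.graphs import ThresholdedGraph

    w = rng.uniform(0.05, 1.0, size=(n, n))
    w = (w + w.T) / 2
    mask = rng.uniform(size=(n, n)) < density
    mask = np.triu(mask, k=1)
    adj = np.where(mask | mask.T, w, 0.0)
    np.fill_diagonal(adj, 0.0)
    n_edges = int(np.count_nonzero(np.triu(adj, k=1)))
    return ThresholdedGraph(
        adjacency=adj, density=n_edges / (n * (n - 1) / 2), n_edges=n_edges
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
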