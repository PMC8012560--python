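"""Network construction, density, and node-strength centrality.

Density is the proportion of present edges relative to all possible
unordered pairs.  Node strength — the sum of the absolute weights of a
node's incident edges — is the centrality index used to pick which
nodes a targeted perturbation hits (strong- vs weak-node conditions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import IsingNetwork, NetworkValidationError, make_network

__all__ = [
    "uniform_network",
    "random_density_network",
    "density",
    "node_strength",
    "select_extreme_nodes",
    "incident_edges",
]


def uniform_network(n: int, tau: float, w: float, labels=None) -> IsingNetwork:
    """Fully connected network with identical thresholds and weights.

    ``uniform_network(9, -2.0, 0.5)`` is the canonical 9-symptom model
    (mimicking the DSM MDD symptoms) used as the density-1 baseline.
    """
    if n < 1:
        raise ValueError(f"need at least one node, got n={n}")
    W = np.full((n, n), float(w))
    np.fill_diagonal(W, 0.0)
    return make_network(np.full(n, float(tau)), W, labels=labels)


def random_density_network(
    n: int, density: float, tau: float, w: float, seed: int | None = None, labels=None
) -> IsingNetwork:
    """Random structure with exactly ``round(density * C(n,2))`` edges.

    Edges are placed uniformly at random without replacement, each with
    weight ``w``; reproducible under ``seed``.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    if n < 1:
        raise ValueError(f"need at least one node, got n={n}")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = int(round(density * len(pairs)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=m, replace=False) if m else []
    W = np.zeros((n, n))
    for k in chosen:
        i, j = pairs[int(k)]
        W[i, j] = W[j, i] = float(w)
    return make_network(np.full(n, float(tau)), W, labels=labels)


def density(net: IsingNetwork) -> float:
    """Present-edge proportion: nonzero unordered pairs over C(n,2)."""
    n = net.n_nodes
    if n < 2:
        raise NetworkValidationError("density is undefined for fewer than 2 nodes")
    iu = np.triu_indices(n, k=1)
    present = int(np.count_nonzero(net.W[iu]))
    return present / (n * (n - 1) / 2)


def node_strength(net: IsingNetwork) -> pd.DataFrame:
    """Per-node strength table: label, strength, z, rank.

    Strength is the sum of absolute incident edge weights; ``z`` is the
    standardized score (0 when all strengths are equal); rank 1 is the
    strongest, ties broken by label order (recorded by the stable sort).
    """
    strength = np.abs(net.W).sum(axis=1)
    sd = strength.std()
    z = (strength - strength.mean()) / sd if sd > 0 else np.zeros_like(strength)
    table = pd.DataFrame(
        {"label": list(net.labels), "strength": strength, "z": z}
    )
    order = table.sort_values("strength", ascending=False, kind="stable")
    table["rank"] = pd.Series(
        np.arange(1, net.n_nodes + 1), index=order.index
    )
    return table


def select_extreme_nodes(table: pd.DataFrame, k: int, which: str = "strongest") -> tuple:
    """Labels of the top-k (or bottom-k) nodes by strength.

    Ties are broken deterministically by the table's label order; the
    returned tuple preserves selection order (most extreme first).
    """
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if which == "strongest":
        picked = table.sort_values("strength", ascending=False, kind="stable")
    elif which == "weakest":
        picked = table.sort_values("strength", ascending=True, kind="stable")
    else:
        raise ValueError(f"which must be 'strongest' or 'weakest', got {which!r}")
    return tuple(picked["label"].head(k))


def incident_edges(net: IsingNetwork, nodes, within_only: bool = False) -> frozenset:
    """Present edges touching the given nodes — the moderator target set.

    By default an edge qualifies when at least one endpoint is in
    ``nodes`` (the targeted-condition semantics); ``within_only=True``
    restricts to edges with both endpoints inside the set.
    """
    idx = {net.index(v) for v in nodes}
    out = set()
    n = net.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if net.W[i, j] == 0.0:
                continue
            hit = (i in idx) and (j in idx) if within_only else (i in idx) or (j in idx)
            if hit:
                out.add(frozenset((net.labels[i], net.labels[j])))
    return frozenset(out)
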