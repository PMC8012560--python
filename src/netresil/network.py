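"""Binary (Ising) symptom networks and their exact distributions.

An Ising symptom network assigns each binary symptom :math:`X_i` a
*threshold* :math:`\\tau_i` (its autonomous disposition toward activation;
more negative means harder to activate) and each unordered pair an
edge weight :math:`W_{ij}` (the strength of the pairwise interaction).
In the ``{0,1}`` domain the joint distribution is

.. math::

   P(x) = \\frac{1}{Z} \\exp\\Big(\\sum_i \\tau_i x_i
           + \\sum_{i<j} W_{ij} x_i x_j\\Big),

with :math:`Z` the sum of the potentials of all :math:`2^n` states.  Up to
roughly 20 nodes the distribution is computed here by full state
enumeration, in log space, so strongly activated regimes (potentials of
order :math:`e^{36}`) do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DOMAIN_01",
    "DOMAIN_PM1",
    "IsingNetwork",
    "StateDistribution",
    "SumScoreDistribution",
    "NetworkValidationError",
    "EnumerationLimitError",
    "make_network",
    "state_probability",
    "joint_distribution",
    "sumscore_distribution",
    "convert_domain",
    "enumerate_states",
]

DOMAIN_01 = "{0,1}"
DOMAIN_PM1 = "{-1,1}"

#: Default cap on exact enumeration (2**20 states is ~1M rows).
DEFAULT_ENUMERATION_LIMIT = 20

_CHUNK = 1 << 14  # states per enumeration block


class NetworkValidationError(ValueError):
    """Raised when thresholds/weights do not form a valid network."""


class EnumerationLimitError(ValueError):
    """Raised when a network is too large to enumerate exactly.

    Use :mod:`netresil.sampler` for networks above the limit.
    """


@dataclass(frozen=True)
class IsingNetwork:
    """An undirected binary network: labels, thresholds tau, weights W.

    ``W`` is symmetric with a zero diagonal; each unordered pair
    contributes once to the potential.  ``domain`` tags the state coding
    (``{0,1}`` by default; ``{-1,1}`` via :func:`convert_domain`).
    """

    labels: tuple
    tau: np.ndarray
    W: np.ndarray
    domain: str = DOMAIN_01

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float).copy()
        W = np.asarray(self.W, dtype=float).copy()
        tau.setflags(write=False)
        W.setflags(write=False)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise NetworkValidationError(f"unknown node label: {label!r}") from None

    def with_params(self, tau=None, W=None) -> "IsingNetwork":
        """Copy of the network with replaced parameter arrays."""
        return make_network(
            self.tau if tau is None else tau,
            self.W if W is None else W,
            labels=self.labels,
            domain=self.domain,
        )


@dataclass(frozen=True)
class StateDistribution:
    """Exact joint distribution over all 2**n states of a network.

    States are implicit by index: bit ``i`` of the state index gives node
    ``i``'s coding bit (bit 1 maps to value 1 in either domain, bit 0 to
    0 or -1 depending on ``domain``).
    """

    n: int
    probs: np.ndarray
    logZ: float
    domain: str = DOMAIN_01

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class SumScoreDistribution:
    """P(Y = i) for the sum score Y = number of active symptoms, i = 0..n."""

    n: int
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)


def make_network(tau, W, labels=None, domain=DOMAIN_01, *, atol=1e-12) -> IsingNetwork:
    """Validate thresholds and a symmetric weight matrix into a network.

    Parameters
    ----------
    tau : array-like, shape (n,)
        Per-node threshold parameters.
    W : array-like, shape (n, n)
        Symmetric edge-weight matrix with zero diagonal.
    labels : sequence, optional
        Node identifiers; defaults to ``X1..Xn``.
    domain : str
        State coding, ``"{0,1}"`` (default) or ``"{-1,1}"``.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = tau.shape[0]
    if domain not in (DOMAIN_01, DOMAIN_PM1):
        raise NetworkValidationError(f"unknown domain tag: {domain!r}")
    if W.shape != (n, n):
        raise NetworkValidationError(
            f"dimension mismatch: tau has {n} entries but W has shape {W.shape}"
        )
    asym = np.abs(W - W.T)
    if asym.max(initial=0.0) > atol:
        i, j = np.unravel_index(np.argmax(asym), W.shape)
        raise NetworkValidationError(
            f"W is not symmetric: W[{i},{j}]={W[i, j]} != W[{j},{i}]={W[j, i]}"
        )
    diag = np.abs(np.diag(W))
    if diag.max(initial=0.0) > atol:
        i = int(np.argmax(diag))
        raise NetworkValidationError(f"nonzero diagonal entry W[{i},{i}]={W[i, i]}")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    if labels is None:
        labels = tuple(f"X{i + 1}" for i in range(n))
    labels = tuple(labels)
    if len(labels) != n:
        raise NetworkValidationError(
            f"{len(labels)} labels for {n} nodes"
        )
    if len(set(labels)) != n:
        raise NetworkValidationError("node labels must be unique")
    return IsingNetwork(labels=labels, tau=tau, W=W, domain=domain)


def enumerate_states(n: int, start: int = 0, stop: int | None = None) -> np.ndarray:
    """Bit matrix of state indices ``start..stop`` (rows) by node (columns)."""
    if stop is None:
        stop = 1 << n
    idx = np.arange(start, stop, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(np.float64)


def _check_enumerable(n: int, limit: int | None):
    limit = DEFAULT_ENUMERATION_LIMIT if limit is None else limit
    if n > limit:
        raise EnumerationLimitError(
            f"{n}-node network is too large to enumerate exactly "
            f"(limit {limit}); use netresil.sampler.sample_chain instead"
        )


def _log_potentials(net: IsingNetwork, limit: int | None = None) -> np.ndarray:
    n = net.n_nodes
    _check_enumerable(n, limit)
    total = 1 << n
    out = np.empty(total)
    offset = -1.0 if net.domain == DOMAIN_PM1 else 0.0
    for start in range(0, total, _CHUNK):
        stop = min(start + _CHUNK, total)
        S = enumerate_states(n, start, stop)
        if offset:
            S = 2.0 * S - 1.0
        out[start:stop] = S @ net.tau + 0.5 * np.einsum("si,ij,sj->s", S, net.W, S)
    return out


def joint_distribution(net: IsingNetwork, limit: int | None = None) -> StateDistribution:
    """Exact joint distribution by full state enumeration.

    Log-sum-exp normalization keeps large potentials finite.  Raises
    :class:`EnumerationLimitError` above ``limit`` nodes (default 20).
    """
    logp = _log_potentials(net, limit)
    logZ = float(logsumexp(logp))
    return StateDistribution(n=net.n_nodes, probs=np.exp(logp - logZ),
                             logZ=logZ, domain=net.domain)


def state_probability(net: IsingNetwork, state, limit: int | None = None) -> float:
    """Probability of one configuration under the exact distribution."""
    state = np.asarray(state, dtype=float)
    n = net.n_nodes
    if state.shape != (n,):
        raise NetworkValidationError(
            f"state has shape {state.shape}, expected ({n},)"
        )
    allowed = {0.0, 1.0} if net.domain == DOMAIN_01 else {-1.0, 1.0}
    if not set(np.unique(state)) <= allowed:
        raise NetworkValidationError(
            f"state entries must lie in {net.domain}"
        )
    logp = state @ net.tau + 0.5 * state @ net.W @ state
    logZ = float(logsumexp(_log_potentials(net, limit)))
    return float(np.exp(logp - logZ))


def sumscore_distribution(dist: StateDistribution) -> SumScoreDistribution:
    """Collapse a joint distribution onto the sum score Y = #active nodes.

    In either domain a node is *active* when its coding bit is 1
    (value 1 in ``{0,1}``, value +1 in ``{-1,1}``).
    """
    n = dist.n
    total = 1 << n
    counts = np.zeros(total, dtype=np.int64)
    for k in range(n):
        counts += (np.arange(total, dtype=np.int64) >> k) & 1
    probs = np.bincount(counts, weights=dist.probs, minlength=n + 1)
    return SumScoreDistribution(n=n, probs=probs)


def convert_domain(net: IsingNetwork, target: str) -> IsingNetwork:
    """Reparameterize between the ``{0,1}`` and ``{-1,1}`` state codings.

    The two codings describe the same distribution once parameters are
    transformed: under ``x = (s + 1)/2`` the ``{0,1}`` probability of a
    state equals the ``{-1,1}`` probability of its image.  The transform
    is exact and involutive.
    """
    if target not in (DOMAIN_01, DOMAIN_PM1):
        raise NetworkValidationError(f"unknown domain tag: {target!r}")
    if target == net.domain:
        raise NetworkValidationError(
            f"network is already in domain {target}"
        )
    row = net.W.sum(axis=1)
    if net.domain == DOMAIN_01:  # -> {-1,1}
        W = net.W / 4.0
        tau = net.tau / 2.0 + row / 4.0
    else:  # {-1,1} -> {0,1}
        W = 4.0 * net.W
        tau = 2.0 * net.tau - 2.0 * row
    return make_network(tau, W, labels=net.labels, domain=target)
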