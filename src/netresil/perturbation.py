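"""Multiplicative perturbations of network parameters by RP factors.

Risk and protective (RP) factors are modelled as multiplicative changes
to the parameters of a symptom network.  Factors acting on *thresholds*
are causal main effects; factors acting on *edge weights* are causal
moderators.  With the usual sign conventions (negative thresholds,
positive weights): a constant below 1 on thresholds or above 1 on edges
is a risk influence; the reverse directions are protective.

The canonical sweep multiplies parameters by an 11-point grid built from
0.5..1 in steps of 0.1 together with the exact inverses of those steps
(so the grid is symmetric on the log scale, 0.5 .. 2 around 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import resilience_exact
from .network import IsingNetwork, NetworkValidationError, joint_distribution, sumscore_distribution

__all__ = [
    "TARGET_THRESHOLDS",
    "TARGET_EDGES",
    "TARGET_BOTH",
    "PerturbationSpec",
    "multiplier_grid",
    "apply_main_effect",
    "apply_moderator",
    "apply_perturbation",
    "perturbation_sweep",
]

TARGET_THRESHOLDS = "thresholds"
TARGET_EDGES = "edges"
TARGET_BOTH = "both"
_TARGETS = (TARGET_THRESHOLDS, TARGET_EDGES, TARGET_BOTH)


def multiplier_grid() -> tuple:
    """The canonical 11 multiplier constants, ascending.

    0.5, 0.6, 0.7, 0.8, 0.9, 1 and the exact inverses 1/0.9, 1/0.8,
    1/0.7, 1/0.6, 1/0.5.  The printed two-decimal forms (1.11, 1.25,
    1.43, 1.67, 2) are display roundings of these inverses.  The middle
    constant 1 is the unperturbed baseline.
    """
    lows = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    highs = [1.0 / c for c in (0.9, 0.8, 0.7, 0.6, 0.5)]
    return tuple(lows + highs)


@dataclass(frozen=True)
class PerturbationSpec:
    """One multiplicative perturbation: constant, target type, subsets.

    Empty subsets mean "all nodes" / "all present edges" (the global
    targeting of a whole-network sweep); non-empty subsets give the
    targeted designs (e.g. strong/weak-node conditions).
    """

    multiplier: float
    target_type: str = TARGET_BOTH
    node_subset: frozenset = frozenset()
    edge_subset: frozenset = frozenset()

    def __post_init__(self):
        if not self.multiplier > 0:
            raise ValueError(f"multiplier must be positive, got {self.multiplier}")
        if self.target_type not in _TARGETS:
            raise ValueError(
                f"target_type must be one of {_TARGETS}, got {self.target_type!r}"
            )
        object.__setattr__(self, "node_subset", frozenset(self.node_subset))
        object.__setattr__(
            self, "edge_subset",
            frozenset(frozenset(e) for e in self.edge_subset),
        )


def _node_indices(net: IsingNetwork, nodes) -> np.ndarray:
    if not nodes:
        return np.arange(net.n_nodes)
    return np.array(sorted(net.index(v) for v in nodes), dtype=int)


def apply_main_effect(net: IsingNetwork, multiplier: float, nodes=()) -> IsingNetwork:
    """Multiply the thresholds of the targeted nodes by a constant.

    Empty ``nodes`` targets every node.  The input network is not
    mutated.  For negative thresholds a constant < 1 raises activation
    disposition (risk); > 1 lowers it (protective).
    """
    if not multiplier > 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    idx = _node_indices(net, nodes)
    tau = net.tau.copy()
    tau[idx] *= multiplier
    return net.with_params(tau=tau)


def apply_moderator(net: IsingNetwork, multiplier: float, edges=()) -> IsingNetwork:
    """Multiply the weights of the targeted present edges by a constant.

    Empty ``edges`` targets every present edge; absent edges (weight 0)
    stay absent under any constant.  Symmetry is preserved.
    """
    if not multiplier > 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    W = net.W.copy()
    if not edges:
        W *= multiplier
    else:
        for pair in edges:
            a, b = tuple(pair)
            i, j = net.index(a), net.index(b)
            if i == j:
                raise NetworkValidationError(f"self-edge ({a!r}, {b!r}) is not valid")
            W[i, j] *= multiplier
            W[j, i] *= multiplier
    return net.with_params(W=W)


def apply_perturbation(net: IsingNetwork, spec: PerturbationSpec) -> IsingNetwork:
    """Apply one spec: main effect, moderator, or both with one constant."""
    out = net
    if spec.target_type in (TARGET_THRESHOLDS, TARGET_BOTH):
        out = apply_main_effect(out, spec.multiplier, spec.node_subset)
    if spec.target_type in (TARGET_EDGES, TARGET_BOTH):
        out = apply_moderator(out, spec.multiplier, spec.edge_subset)
    return out


def influence_label(target_type: str, multiplier: float) -> str:
    """Derived risk/protective label under the usual sign conventions."""
    if multiplier == 1.0:
        return "baseline"
    if target_type == TARGET_BOTH:
        return "both"
    if target_type == TARGET_THRESHOLDS:
        return "risk" if multiplier < 1.0 else "protective"
    return "risk" if multiplier > 1.0 else "protective"


def perturbation_sweep(
    net: IsingNetwork,
    grid=None,
    target_types=_TARGETS,
    node_subset=(),
    edge_subset=(),
    mode: str = "exact",
    chain_config=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """ESA/SAS for every (multiplier x target type) perturbed copy.

    Parameters
    ----------
    grid : sequence of floats, optional
        Multiplier constants; defaults to :func:`multiplier_grid`.
    mode : "exact" | "sampled"
        Exact enumeration, or chain sampling via :mod:`netresil.sampler`
        for networks too large to enumerate.
    chain_config : ChainConfig, optional
        Sampler settings in sampled mode.

    Returns a tidy DataFrame with one row per condition (columns:
    target, multiplier, influence, esa, sas, degenerate, source,
    n_samples, seed).
    """
    if grid is None:
        grid = multiplier_grid()
    rows = []
    for target in target_types:
        for c in grid:
            spec = PerturbationSpec(
                multiplier=c, target_type=target,
                node_subset=node_subset, edge_subset=edge_subset,
            )
            pert = apply_perturbation(net, spec)
            if mode == "exact":
                report = resilience_exact(sumscore_distribution(joint_distribution(pert)))
            elif mode == "sampled":
                from .sampler import ChainConfig, chain_resilience

                cfg = chain_config if chain_config is not None else ChainConfig()
                if seed is not None:
                    cfg = cfg.with_seed(seed)
                report = chain_resilience(pert, cfg)
            else:
                raise ValueError(f"mode must be 'exact' or 'sampled', got {mode!r}")
            rows.append(
                {
                    "target": target,
                    "multiplier": c,
                    "influence": influence_label(target, c),
                    "esa": report.esa,
                    "sas": report.sas,
                    "degenerate": report.degenerate,
                    "source": report.source,
                    "n_samples": report.n_samples,
                    "seed": report.seed,
                }
            )
    return pd.DataFrame(rows)
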