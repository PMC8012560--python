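"""End-to-end study designs: global sweeps, targeted sweeps, conditioning.

Three reusable experiment drivers mirror the three analysis designs:

* :func:`run_study1` — exact-enumeration perturbation sweeps of a
  uniform 9-node network at several densities (global RP influence);
* :func:`run_study2` — centrality-targeted sweeps of a larger,
  heterogeneous network with chain sampling (strong- vs weak-node
  conditions);
* :func:`run_study3` — conditioning of a hybrid symptom + RP-factor
  model on presence/absence scenarios.

Each driver returns a tidy DataFrame (one row per condition) carrying
the seed and a config hash, and can write CSV and optional plots.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditioning import (
    ConditioningScenario,
    condition_means,
    conditioned_esa,
    esa_delta,
    presence_scenario,
)
from .network import make_network
from .perturbation import multiplier_grid, perturbation_sweep
from .sampler import ChainConfig
from .topology import (
    incident_edges,
    node_strength,
    random_density_network,
    select_extreme_nodes,
    uniform_network,
)

__all__ = [
    "ExperimentConfig",
    "run_study1",
    "run_study2",
    "run_study3",
    "synthetic_study2_network",
    "plot_sweep",
]



@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment settings; study-specific fields are optional.

    ``grid="canonical11"`` selects the canonical 11-constant grid.  The
    sampler settings apply to sampled-mode sweeps only.
    """

    study: str = "study1"
    seed: int = 0
    grid: object = "canonical11"
    densities: tuple = (1.0, 0.5, 0.3)
    n: int = 9
    tau: float = -2.0
    w: float = 0.5
    k: int = 5
    iterations: int = 20000
    burn_in: int = 2000
    out_dir: str | None = None
    network_json: str | None = None
    model_json: str | None = None
    scenarios_yaml: str | None = None

    def multipliers(self) -> tuple:
        if self.grid == "canonical11" or self.grid is None:
            return multiplier_grid()
        return tuple(float(c) for c in self.grid)

    def hash(self) -> str:
        doc = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def _stamp(df: pd.DataFrame, cfg: ExperimentConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = cfg.hash()
    df["run_seed"] = cfg.seed
    df["version"] = __version__
    return df


def _maybe_write(df: pd.DataFrame, cfg: ExperimentConfig, name: str):
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)


def run_study1(cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    """Global exact sweeps over densities x 11 constants x 3 target types.

    Density 1 uses the uniform fully connected network (exact reference
    condition); lower densities regenerate a random structure from the
    run seed, so their cells are trend-level, not fixed, quantities.
    Exact-mode results are independent of the seed at density 1.
    """
    cfg = cfg or ExperimentConfig(study="study1")
    frames = []
    for d_i, d in enumerate(cfg.densities):
        if d >= 1.0:
            net = uniform_network(cfg.n, cfg.tau, cfg.w)
        else:
            net = random_density_network(cfg.n, d, cfg.tau, cfg.w,
                                         seed=cfg.seed * 1000 + d_i)
        sweep = perturbation_sweep(net, grid=cfg.multipliers(), mode="exact")
        sweep.insert(0, "density", d)
        frames.append(sweep)
    table = _stamp(pd.concat(frames, ignore_index=True), cfg)
    _maybe_write(table, cfg, "study1.csv")
    return table


def synthetic_study2_network(n: int = 27, seed: int = 0,
                             density: float = 0.25):
    """Heterogeneous sparse network for targeted-sweep experiments.

    Random structure at the given density, positive weights drawn
    log-uniform in [0.05, 1.0] and thresholds normal around -2.5, so
    nodes genuinely differ in strength (as an empirically estimated
    checklist network would) while the unperturbed network stays in a
    mostly healthy, low-activity regime.
    """
    rng = np.random.default_rng(seed)
    base = random_density_network(n, density, tau=-1.5, w=1.0, seed=seed,
                                  labels=[f"S{i + 1}" for i in range(n)])
    W = base.W.copy()
    iu = np.triu_indices(n, k=1)
    mask = W[iu] != 0.0
    weights = np.exp(rng.uniform(np.log(0.05), np.log(1.0), size=mask.sum()))
    vals = np.zeros(mask.shape[0])
    vals[mask] = weights
    W[iu] = vals
    W.T[iu] = vals
    tau = rng.normal(-2.5, 0.6, size=n)
    return make_network(tau, W, labels=base.labels)


def run_study2(cfg: ExperimentConfig | None = None, net=None) -> pd.DataFrame:
    """Targeted sweeps: strong- vs weak-node conditions, chain-sampled.

    Node strength picks the ``k`` strongest and weakest nodes; in each
    condition the grid constants multiply the targeted thresholds,
    the targeted nodes' incident edges, or both.  ESA/SAS come from the
    single-site sampler at the configured chain length.
    """
    cfg = cfg or ExperimentConfig(study="study2")
    if net is None:
        if cfg.network_json:
            from .io import read_network_json

            net = read_network_json(cfg.network_json)
        else:
            net = synthetic_study2_network(seed=cfg.seed)
    table = node_strength(net)
    conditions = {
        "strong_nodes": select_extreme_nodes(table, cfg.k, "strongest"),
        "weak_nodes": select_extreme_nodes(table, cfg.k, "weakest"),
    }
    frames = []
    for ci, (name, nodes) in enumerate(conditions.items()):
        edges = incident_edges(net, nodes)
        chain = ChainConfig(iterations=cfg.iterations, burn_in=cfg.burn_in,
                            seed=cfg.seed * 7919 + ci)
        sweep = perturbation_sweep(
            net, grid=cfg.multipliers(), node_subset=frozenset(nodes),
            edge_subset=edges, mode="sampled", chain_config=chain,
        )
        sweep.insert(0, "condition", name)
        sweep["targeted_nodes"] = ",".join(nodes)
        frames.append(sweep)
    out = _stamp(pd.concat(frames, ignore_index=True), cfg)
    _maybe_write(out, cfg, "study2.csv")
    return out


def run_study3(cfg: ExperimentConfig | None = None, model=None,
               scenarios: dict | None = None) -> pd.DataFrame:
    """Conditioning scenarios on a hybrid model: ESA and deltas.

    By default evaluates the two canonical scenarios — protective
    factors present with risk factors absent, and the reverse — where
    presence is a factor's scale maximum and absence is 0.  Custom
    scenarios can be supplied (or loaded from YAML via the config).
    """
    cfg = cfg or ExperimentConfig(study="study3")
    if model is None:
        if cfg.model_json:
            from .io import read_hybrid_model_json

            model = read_hybrid_model_json(cfg.model_json)
        else:
            from .synthetic import default_hybrid_spec, generate_hybrid_dataset

            _, model = generate_hybrid_dataset(default_hybrid_spec(seed=cfg.seed))
    roles = model.factor_roles
    protective = [f for f in model.factor_labels if roles.get(f) == "protective"]
    risk = [f for f in model.factor_labels if roles.get(f) == "risk"]
    if scenarios is None:
        if cfg.scenarios_yaml:
            from .io import read_scenario_yaml

            scenarios = read_scenario_yaml(cfg.scenarios_yaml)
        else:
            scenarios = {
                "protective_present_risk_absent": presence_scenario(
                    model, present=protective, absent=risk),
                "risk_present_protective_absent": presence_scenario(
                    model, present=risk, absent=protective),
            }
    baseline = condition_means(model, ConditioningScenario(fixed={}))
    rows = [{
        "scenario": "baseline",
        "esa": conditioned_esa(baseline),
        "delta": 0.0,
        "clip_count": baseline.clip_count,
    }]
    for name, sc in scenarios.items():
        cm = condition_means(model, sc)
        rows.append({
            "scenario": name,
            "esa": conditioned_esa(cm),
            "delta": conditioned_esa(cm) - conditioned_esa(baseline),
            "clip_count": cm.clip_count,
        })
    out = _stamp(pd.DataFrame(rows), cfg)
    _maybe_write(out, cfg, "study3.csv")
    return out


def plot_sweep(table: pd.DataFrame, path=None, facet: str = "density"):
    """Sweep figure: x = multiplier, y = ESA, point size = SAS, color = influence.

    One panel per value of ``facet`` (density or condition); lines per
    target type.  Plots are presentation artifacts — analyses assert on
    the tables, not the figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"risk": "tab:red", "protective": "tab:green",
              "both": "black", "baseline": "tab:gray"}
    facets = list(dict.fromkeys(table[facet]))
    fig, axes = plt.subplots(1, len(facets), figsize=(4 * len(facets), 3.5),
                             sharey=True, squeeze=False)
    for ax, val in zip(axes[0], facets):
        sub = table[table[facet] == val]
        for target, grp in sub.groupby("target"):
            grp = grp.sort_values("multiplier")
            ax.plot(grp["multiplier"], grp["esa"], lw=1, alpha=0.5,
                    label=target)
            sas = grp["sas"].fillna(0.0)
            ax.scatter(grp["multiplier"], grp["esa"], s=20 + 40 * sas,
                       c=[colors[i] for i in grp["influence"]], zorder=3)
        ax.set_title(f"{facet} = {val}")
        ax.set_xlabel("multiplier")
    axes[0][0].set_ylabel("ESA")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
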