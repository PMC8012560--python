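"""File formats: network JSON/CSV, sample matrices, hybrid models, scenarios.

Networks serialize to a single JSON document (labels, thresholds, dense
weight matrix, domain) or to a pair of CSVs: a node table
(``label,threshold``) and an undirected edge table
(``source,target,weight``, one row per unordered present pair).  Files
reference nodes by label; positional order is the node table's row
order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditioning import ConditioningScenario, HybridNodewiseModel
from .network import IsingNetwork, make_network
from .sampler import SampleMatrix

__all__ = [
    "write_network_json",
    "read_network_json",
    "write_network_csv",
    "read_network_csv",
    "write_samples_csv",
    "read_samples_csv",
    "write_hybrid_model_json",
    "read_hybrid_model_json",
    "write_scenario_yaml",
    "read_scenario_yaml",
]


def write_network_json(net: IsingNetwork, path):
    doc = {
        "labels": list(net.labels),
        "tau": net.tau.tolist(),
        "W": net.W.tolist(),
        "domain": net.domain,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network_json(path) -> IsingNetwork:
    doc = json.loads(Path(path).read_text())
    return make_network(doc["tau"], doc["W"], labels=doc["labels"],
                        domain=doc.get("domain", "{0,1}"))


def write_network_csv(net: IsingNetwork, node_path, edge_path):
    """Node table (label,threshold) + undirected edge table (source,target,weight)."""
    nodes = pd.DataFrame({"label": list(net.labels), "threshold": net.tau})
    nodes.to_csv(node_path, index=False)
    rows = []
    n = net.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if net.W[i, j] != 0.0:
                rows.append((net.labels[i], net.labels[j], net.W[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        edge_path, index=False
    )


def read_network_csv(node_path, edge_path) -> IsingNetwork:
    nodes = pd.read_csv(node_path)
    labels = [str(v) for v in nodes["label"]]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    edges = pd.read_csv(edge_path)
    for _, row in edges.iterrows():
        s, t = str(row["source"]), str(row["target"])
        if s not in index or t not in index:
            raise ValueError(f"edge ({s}, {t}) references an unknown node label")
        i, j = index[s], index[t]
        W[i, j] = W[j, i] = float(row["weight"])
    return make_network(nodes["threshold"].to_numpy(float), W, labels=labels)


def write_samples_csv(sm: SampleMatrix, path, sidecar_path=None):
    """One row per kept iteration, columns = node labels; JSON sidecar with settings."""
    pd.DataFrame(sm.states, columns=list(sm.labels)).to_csv(path, index=False)
    if sidecar_path is None:
        sidecar_path = str(path) + ".json"
    Path(sidecar_path).write_text(json.dumps(
        {"seed": sm.seed, "burn_in": sm.burn_in, "thin": sm.thin,
         "labels": list(sm.labels)}, indent=1
    ))


def read_samples_csv(path, sidecar_path=None) -> SampleMatrix:
    df = pd.read_csv(path)
    meta = {"seed": None, "burn_in": 0, "thin": 1}
    if sidecar_path is None:
        candidate = Path(str(path) + ".json")
        sidecar_path = candidate if candidate.exists() else None
    if sidecar_path is not None:
        meta.update(json.loads(Path(sidecar_path).read_text()))
    return SampleMatrix(
        states=df.to_numpy(), labels=tuple(df.columns),
        seed=meta["seed"], burn_in=meta["burn_in"], thin=meta["thin"],
    )


def write_hybrid_model_json(model: HybridNodewiseModel, path):
    doc = {
        "symptom_labels": list(model.symptom_labels),
        "factor_labels": list(model.factor_labels),
        "intercepts": model.intercepts.tolist(),
        "coef": model.coef.tolist(),
        "scale_min": model.scale_min.tolist(),
        "scale_max": model.scale_max.tolist(),
        "baseline_means": model.baseline_means.tolist(),
        "factor_roles": dict(model.factor_roles),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_hybrid_model_json(path) -> HybridNodewiseModel:
    doc = json.loads(Path(path).read_text())
    return HybridNodewiseModel(
        symptom_labels=tuple(doc["symptom_labels"]),
        factor_labels=tuple(doc["factor_labels"]),
        intercepts=np.array(doc["intercepts"]),
        coef=np.array(doc["coef"]),
        scale_min=np.array(doc["scale_min"]),
        scale_max=np.array(doc["scale_max"]),
        baseline_means=np.array(doc["baseline_means"]),
        factor_roles=doc.get("factor_roles", {}),
    )


def write_scenario_yaml(scenarios: dict, path):
    """Mapping of scenario name -> {factor label: fixed value}."""
    doc = {name: dict(sc.fixed if isinstance(sc, ConditioningScenario) else sc)
           for name, sc in scenarios.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_scenario_yaml(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return {name: ConditioningScenario(fixed=dict(fixed))
            for name, fixed in doc.items()}
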