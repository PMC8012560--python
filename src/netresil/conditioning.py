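"""Conditioning hybrid symptom + RP-factor models on factor values.

A hybrid network contains both symptoms (ordinal, treated as
continuous) and risk/protective factors.  Each node carries an
intercept and linear coefficients on every other node (a nodewise
regression parameter set).  Conditioning fixes chosen RP factors at
given values — their scale maximum for "presence", 0 for "absence" —
holds the remaining factors at their baseline means, and propagates the
nodewise predictions

.. math:: m_s \\leftarrow a_s + \\sum_{t \\ne s} B_{st}\\, m_t

to a fixed point, so effects travel through neighboring symptoms as
well as directly.  Expected Symptom Activity of the conditioned system
is the sum of the conditioned symptom means; its change from baseline
quantifies the factors' pull on symptom activity.  SAS is deliberately
not defined here: conditioning a nodewise-linear model does not change
symptom variance patterns, so an inverse-sd would not measure stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HybridNodewiseModel",
    "ConditioningScenario",
    "ConditionedMeans",
    "condition_means",
    "conditioned_esa",
    "esa_delta",
    "fit_nodewise_linear",
    "presence_scenario",
]


@dataclass(frozen=True)
class HybridNodewiseModel:
    """Nodewise-linear model over symptom and RP-factor nodes.

    ``coef[i, j]`` is node j's coefficient in node i's regression (zero
    diagonal).  ``factor_roles`` maps each RP-factor label to "risk" or
    "protective" (a-priori labels, not estimated).  ``scale_min``/
    ``scale_max`` bound each node's observed scale; conditioned means
    are clipped there, with clipping counted.
    """

    symptom_labels: tuple
    factor_labels: tuple
    intercepts: np.ndarray  # per node, symptoms first then factors
    coef: np.ndarray
    scale_min: np.ndarray
    scale_max: np.ndarray
    baseline_means: np.ndarray
    factor_roles: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = self.labels
        k = len(labels)
        for name in ("intercepts", "scale_min", "scale_max", "baseline_means"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per node ({k})")
            arr = arr.copy()
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        C = np.asarray(self.coef, dtype=float).copy()
        if C.shape != (k, k):
            raise ValueError(f"coef must be {k}x{k}")
        if np.abs(np.diag(C)).max(initial=0.0) > 0:
            raise ValueError("coef has nonzero self-coefficients on the diagonal")
        C.setflags(write=False)
        object.__setattr__(self, "coef", C)
        if len(set(labels)) != k:
            raise ValueError("node labels must be unique")
        if not (self.scale_min < self.scale_max).all():
            raise ValueError("each scale range must have min < max")
        below = self.baseline_means < self.scale_min
        above = self.baseline_means > self.scale_max
        if below.any() or above.any():
            bad = labels[int(np.argmax(below | above))]
            raise ValueError(f"baseline mean of {bad!r} outside its scale range")
        object.__setattr__(self, "symptom_labels", tuple(self.symptom_labels))
        object.__setattr__(self, "factor_labels", tuple(self.factor_labels))

    @property
    def labels(self) -> tuple:
        return tuple(self.symptom_labels) + tuple(self.factor_labels)

    @property
    def n_symptoms(self) -> int:
        return len(self.symptom_labels)

    def index(self, label) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class ConditioningScenario:
    """Fixed RP-factor values; unlisted factors stay at baseline means."""

    fixed: dict

    def validated(self, model: HybridNodewiseModel) -> dict:
        out = {}
        for label, value in self.fixed.items():
            if label not in model.factor_labels:
                raise ValueError(f"{label!r} is not an RP factor of this model")
            i = model.index(label)
            if not model.scale_min[i] <= value <= model.scale_max[i]:
                raise ValueError(
                    f"value {value} for {label!r} outside scale "
                    f"[{model.scale_min[i]}, {model.scale_max[i]}]"
                )
            out[label] = float(value)
        return out


@dataclass(frozen=True)
class ConditionedMeans:
    """Fixed-point symptom means plus convergence/clipping diagnostics."""

    means: pd.Series
    n_iter: int
    clipped: tuple

    @property
    def clip_count(self) -> int:
        return len(self.clipped)


def presence_scenario(model: HybridNodewiseModel, present=(), absent=()) -> ConditioningScenario:
    """Scenario with listed factors at their scale max / at zero.

    "Presence" of a factor is its observed scale maximum and "absence"
    is 0 (or the scale minimum if that is higher).
    """
    fixed = {}
    for label in present:
        fixed[label] = float(model.scale_max[model.index(label)])
    for label in absent:
        fixed[label] = float(max(0.0, model.scale_min[model.index(label)]))
    return ConditioningScenario(fixed=fixed)


def condition_means(
    model: HybridNodewiseModel,
    scenario: ConditioningScenario,
    tol: float = 1e-8,
    max_iter: int = 1000,
    one_step: bool = False,
) -> ConditionedMeans:
    """Propagate nodewise predictions to conditioned symptom means.

    RP factors in the scenario are clamped; the rest stay at their
    baseline means.  Symptom means are iterated from baseline through
    each symptom's regression until the largest change is below ``tol``
    (fixed point), or once if ``one_step`` (direct effects only).
    Results are clipped to each symptom's scale range; clipped nodes
    are reported.
    """
    fixed = scenario.validated(model)
    k = len(model.labels)
    ns = model.n_symptoms
    x = model.baseline_means.copy()
    for label, value in fixed.items():
        x[model.index(label)] = value
    A = model.coef[:ns]  # symptom rows
    a = model.intercepts[:ns]
    n_iter = 0
    if one_step:
        x[:ns] = a + A @ x
        n_iter = 1
    else:
        for n_iter in range(1, max_iter + 1):
            new = a + A @ x
            delta = np.abs(new - x[:ns]).max(initial=0.0)
            x[:ns] = new
            if delta < tol:
                break
        else:
            resid = np.abs((a + A @ x) - x[:ns])
            worst = [model.symptom_labels[i] for i in np.argsort(resid)[::-1][:5]]
            raise RuntimeError(
                f"conditioned means did not converge in {max_iter} iterations; "
                f"largest residuals at {worst}"
            )
    lo, hi = model.scale_min[:ns], model.scale_max[:ns]
    clipped = tuple(
        model.symptom_labels[i]
        for i in range(ns)
        if x[i] < lo[i] or x[i] > hi[i]
    )
    means = pd.Series(np.clip(x[:ns], lo, hi), index=list(model.symptom_labels))
    return ConditionedMeans(means=means, n_iter=n_iter, clipped=clipped)


def conditioned_esa(means) -> float:
    """ESA of a conditioned system: the sum of the symptom means."""
    if isinstance(means, ConditionedMeans):
        means = means.means
    return float(np.asarray(means, dtype=float).sum())


def esa_delta(model: HybridNodewiseModel, scenario: ConditioningScenario, **kwargs) -> float:
    """Signed ESA change of a scenario relative to the baseline system.

    The baseline is the empty scenario propagated through the same
    fixed-point map, so an empty scenario yields exactly 0.
    """
    base = condition_means(model, ConditioningScenario(fixed={}), **kwargs)
    cond = condition_means(model, scenario, **kwargs)
    return conditioned_esa(cond) - conditioned_esa(base)


def fit_nodewise_linear(
    data: pd.DataFrame,
    symptom_labels,
    factor_labels,
    factor_roles: dict | None = None,
    scale_ranges: dict | None = None,
) -> HybridNodewiseModel:
    """Unregularized nodewise OLS fit of a hybrid model from data.

    Each symptom is regressed on all other nodes; factor rows carry no
    regression (factors are always clamped or held at their means when
    conditioning).  Scale ranges default to the observed column min/max
    (or pass ``scale_ranges[label] = (lo, hi)``).
    """
    symptom_labels = tuple(symptom_labels)
    factor_labels = tuple(factor_labels)
    labels = symptom_labels + factor_labels
    df = data[list(labels)]
    X = df.to_numpy(dtype=float)
    k = len(labels)
    ns = len(symptom_labels)
    coef = np.zeros((k, k))
    intercepts = np.zeros(k)
    for i in range(ns):
        others = [j for j in range(k) if j != i]
        design = np.column_stack([np.ones(len(df)), X[:, others]])
        beta, *_ = np.linalg.lstsq(design, X[:, i], rcond=None)
        intercepts[i] = beta[0]
        coef[i, others] = beta[1:]
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    if scale_ranges:
        for label, (a, b) in scale_ranges.items():
            j = labels.index(label)
            lo[j], hi[j] = a, b
    return HybridNodewiseModel(
        symptom_labels=symptom_labels,
        factor_labels=factor_labels,
        intercepts=intercepts,
        coef=coef,
        scale_min=lo,
        scale_max=hi,
        baseline_means=X.mean(axis=0),
        factor_roles=dict(factor_roles or {}),
    )
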