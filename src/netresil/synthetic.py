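"""Synthetic data generators: Ising samples, ordinal items, hybrid data.

Three generators cover the data shapes the analyses consume:

* exact i.i.d. samples from an enumerable Ising network (inverse-CDF
  over the enumerated states) — the independent-sample counterpart of
  chain sampling;
* correlated five-level ordinal screening items via a thresholded
  latent one-factor Gaussian, calibrated so that binarization at the
  standard cut yields realistic symptom prevalences (5-40%);
* hybrid symptom + RP-factor datasets with *planted* effect structure
  (protective factors with negative symptom coefficients, risk factors
  with positive ones), returned together with the generating nodewise
  model so downstream estimates can be checked against known truth.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .conditioning import HybridNodewiseModel
from .network import IsingNetwork, enumerate_states, joint_distribution

__all__ = [
    "FactorSpec",
    "HybridGeneratorSpec",
    "sample_ising_exact",
    "generate_ordinal_scl",
    "generate_hybrid_dataset",
    "default_hybrid_spec",
]


def sample_ising_exact(net: IsingNetwork, n_samples: int, seed: int | None = None) -> pd.DataFrame:
    """I.i.d. draws from the exact joint distribution of a small network.

    Enumerates all states, then samples state indices by their exact
    probabilities.  Raises the enumeration-limit error (pointing to the
    chain sampler) for networks too large to enumerate.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    dist = joint_distribution(net)
    rng = np.random.default_rng(seed)
    idx = rng.choice(dist.probs.shape[0], size=n_samples, p=dist.probs)
    n = net.n_nodes
    states = ((idx[:, None] >> np.arange(n)) & 1).astype(np.int8)
    return pd.DataFrame(states, columns=list(net.labels))


def generate_ordinal_scl(
    n_persons: int,
    n_items: int,
    seed: int | None = None,
    latent_corr: float = 0.3,
    prevalence_band: tuple = (0.05, 0.40),
) -> pd.DataFrame:
    """Correlated five-level (0-4) ordinal items from a latent factor.

    Each person draws a shared latent factor and item-specific noise
    (pairwise latent correlation ``latent_corr``); items are cut into
    levels 0-4 with item-specific cutpoints chosen so that the standard
    binarization (level >= 3) has prevalence uniform in
    ``prevalence_band``.
    """
    if n_persons < 1 or n_items < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 <= latent_corr < 1.0:
        raise ValueError("latent_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_persons)[:, None]
    e = rng.standard_normal((n_persons, n_items))
    z = np.sqrt(latent_corr) * g + np.sqrt(1.0 - latent_corr) * e
    lo, hi = prevalence_band
    prev = rng.uniform(lo, hi, size=n_items)
    # c3 is the moderate-presence boundary (level >= 3), i.e. binarization cut
    c3 = norm.ppf(1.0 - prev)
    c4 = norm.ppf(1.0 - 0.4 * prev)  # 40% of actives reach the top level
    c1 = np.minimum(norm.ppf(0.30), c3 - 0.6)
    c2 = np.minimum(norm.ppf(0.55), c3 - 0.3)
    levels = (
        (z > c1).astype(int) + (z > c2) + (z > c3) + (z > c4)
    )
    return pd.DataFrame(levels, columns=[f"SCL-{i + 1}" for i in range(n_items)])


@dataclass(frozen=True)
class FactorSpec:
    """One RP factor: label, role, scale, and marginal distribution.

    ``kind="binary"`` draws Bernoulli(``prevalence``); ``kind="ordinal"``
    draws uniformly over 0..``levels``-1 unless ``probs`` is given.
    """

    label: str
    role: str  # "risk" | "protective"
    kind: str = "binary"
    levels: int = 2
    prevalence: float = 0.5
    probs: tuple | None = None

    def __post_init__(self):
        if self.role not in ("risk", "protective"):
            raise ValueError("role must be 'risk' or 'protective'")
        if self.kind not in ("binary", "ordinal"):
            raise ValueError("kind must be 'binary' or 'ordinal'")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")

    def sample(self, n: int, rng) -> np.ndarray:
        if self.kind == "binary":
            return (rng.random(n) < self.prevalence).astype(float)
        p = self.probs
        if p is None:
            p = np.full(self.levels, 1.0 / self.levels)
        return rng.choice(self.levels, size=n, p=np.asarray(p) / np.sum(p)).astype(float)

    @property
    def scale_max(self) -> float:
        return 1.0 if self.kind == "binary" else float(self.levels - 1)


@dataclass(frozen=True)
class HybridGeneratorSpec:
    """Recipe for a hybrid symptom + RP-factor dataset with known truth.

    Symptoms are continuous-coded ordinal scores on ``symptom_scale``
    generated from a linear structural system: sparse symptom-symptom
    coupling (``ss_density`` present pairs at weight ``ss_coef``),
    planted symptom-factor coefficients of magnitude ``sf_coef`` whose
    sign follows the factor's role (protective negative, risk
    positive), Gaussian residuals of sd ``noise_sd``, and intercepts
    solved so the population symptom means equal ``target_mean``.
    """

    n_symptoms: int = 10
    symptom_scale: tuple = (0.0, 4.0)
    factors: tuple = ()
    n_persons: int = 2000
    seed: int | None = None
    ss_density: float = 0.2
    ss_coef: float = 0.1
    sf_coef: float = 0.3
    sf_density: float = 0.5
    noise_sd: float = 0.6
    target_mean: float = 1.2

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("sample size must be >= 1")
        if self.n_symptoms < 1:
            raise ValueError("need at least one symptom")


def default_hybrid_spec(seed: int | None = None, **overrides) -> HybridGeneratorSpec:
    """A realistic default hybrid recipe: 27 symptoms, 5 RP factors.

    Mirrors a screening study's factor set: one collapsed substance-use
    risk factor (0-3) plus four protective factors (binary physical
    activity; five-level religious practice and volunteer work;
    six-level sexual life satisfaction).
    """
    factors = (
        FactorSpec("substance_use", "risk", kind="ordinal", levels=4,
                   probs=(0.45, 0.3, 0.15, 0.1)),
        FactorSpec("physical_activity", "protective", kind="binary", prevalence=0.5),
        FactorSpec("religious_practice", "protective", kind="ordinal", levels=5),
        FactorSpec("sexual_satisfaction", "protective", kind="ordinal", levels=6),
        FactorSpec("volunteer_work", "protective", kind="ordinal", levels=5),
    )
    # modest planted effects: a realistic screening sample shows small
    # RP-factor pulls on total symptom activity, not wholesale shifts
    kwargs = dict(n_symptoms=27, factors=factors, seed=seed,
                  ss_density=0.15, ss_coef=0.05, sf_coef=0.06, sf_density=0.25)
    kwargs.update(overrides)
    return HybridGeneratorSpec(**kwargs)


def generate_hybrid_dataset(spec: HybridGeneratorSpec):
    """Sample a hybrid dataset and return it with the generating model.

    Returns ``(data, model)``: a persons x (symptoms + factors)
    DataFrame and the true :class:`HybridNodewiseModel` (structural
    intercepts/coefficients; baseline means = population means), so
    conditioning and estimation can be validated against known truth.
    Symptom scores are continuous (linear-Gaussian simplification) and
    are not clipped, keeping the nodewise-linear truth exact.
    """
    rng = np.random.default_rng(spec.seed)
    ns = spec.n_symptoms
    factors = tuple(spec.factors)
    nf = len(factors)
    symptom_labels = tuple(f"S{i + 1}" for i in range(ns))
    factor_labels = tuple(f.label for f in factors)

    # planted symptom-symptom coupling (symmetric, sparse, no self-loops)
    B_ss = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(i + 1, ns):
            if rng.random() < spec.ss_density:
                B_ss[i, j] = B_ss[j, i] = spec.ss_coef
    # planted symptom-factor effects; sign fixed by factor role
    B_sf = np.zeros((ns, nf))
    for j, f in enumerate(factors):
        sign = 1.0 if f.role == "risk" else -1.0
        hit = rng.random(ns) < spec.sf_density
        if not hit.any():
            hit[rng.integers(0, ns)] = True
        B_sf[hit, j] = sign * spec.sf_coef

    F = np.column_stack([f.sample(spec.n_persons, rng) for f in factors]) \
        if nf else np.empty((spec.n_persons, 0))
    f_mean = F.mean(axis=0) if nf else np.empty(0)

    I_B = np.eye(ns) - B_ss
    if np.linalg.cond(I_B) > 1e8:
        raise ValueError("symptom-symptom coupling too strong (system near-singular)")
    m_star = np.full(ns, spec.target_mean)
    intercepts_s = I_B @ m_star - B_sf @ f_mean

    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_persons, ns))
    Y = np.linalg.solve(I_B, (intercepts_s + (B_sf @ F.T).T + eps).T).T

    data = pd.DataFrame(
        np.column_stack([Y, F]), columns=list(symptom_labels + factor_labels)
    )

    k = ns + nf
    coef = np.zeros((k, k))
    coef[:ns, :ns] = B_ss
    coef[:ns, ns:] = B_sf
    intercepts = np.concatenate([intercepts_s, np.zeros(nf)])
    lo = np.concatenate([np.full(ns, -np.inf), np.zeros(nf)])
    hi = np.concatenate(
        [np.full(ns, np.inf), np.array([f.scale_max for f in factors])]
    )
    # symptom scales: generous bounds around the generating scale so the
    # linear truth is never clipped on in-hull scenarios
    span = spec.symptom_scale[1] - spec.symptom_scale[0]
    lo[:ns] = spec.symptom_scale[0] - 2.0 * span
    hi[:ns] = spec.symptom_scale[1] + 2.0 * span
    baseline = np.concatenate([m_star, f_mean])
    model = HybridNodewiseModel(
        symptom_labels=symptom_labels,
        factor_labels=factor_labels,
        intercepts=intercepts,
        coef=coef,
        scale_min=lo,
        scale_max=hi,
        baseline_means=baseline,
        factor_roles={f.label: f.role for f in factors},
    )
    return data, model
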