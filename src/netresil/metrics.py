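"""Resilience metrics for symptom networks: ESA and SAS.

Expected Symptom Activity (ESA) is the expected sum score
:math:`\\mu = E(Y) = \\sum_i i\\,P(Y=i)` — how many symptoms the network
keeps active on average.  Symptom Activity Stability (SAS) is the inverse
standard deviation :math:`1/\\sigma` of the sum score — how tightly the
activity pattern concentrates around its mean.  A resilient network has
low ESA (healthy) and high SAS (the healthy state is stable).  A standard
deviation of 1 is the natural reference point: SAS above 1 means
activity varies by less than one symptom.

Both metrics are computed either from an exact sum-score distribution
(enumerable networks) or from a matrix of sampled/observed states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import StateDistribution, SumScoreDistribution

__all__ = [
    "DegenerateDistributionError",
    "ResilienceReport",
    "esa_exact",
    "sas_exact",
    "esa_from_samples",
    "sas_from_samples",
    "distribution_entropy",
    "resilience_exact",
]


class DegenerateDistributionError(ValueError):
    """The sum score is a point mass (sigma = 0), so SAS is undefined.

    Raised instead of returning infinity so callers can render the
    condition explicitly (e.g. "degenerate" in a results table).
    """


@dataclass(frozen=True)
class ResilienceReport:
    """One ESA/SAS measurement, exact or sampled.

    ``sas`` is ``None`` when the distribution is degenerate (all mass on
    one sum score), flagged by ``degenerate``.
    """

    esa: float
    sas: float | None
    source: str  # "exact" | "sampled"
    n_samples: int | None = None
    degenerate: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "esa": self.esa,
            "sas": self.sas,
            "source": self.source,
            "n_samples": self.n_samples,
            "degenerate": self.degenerate,
            "seed": self.seed,
        }


def _moments(ssd: SumScoreDistribution) -> tuple[float, float]:
    scores = np.arange(ssd.n + 1, dtype=float)
    mu = float(scores @ ssd.probs)
    var = float(((scores - mu) ** 2) @ ssd.probs)
    return mu, var


def esa_exact(ssd: SumScoreDistribution) -> float:
    """Expected number of active symptoms, mu = sum_i i P(Y=i)."""
    return _moments(ssd)[0]


def sas_exact(ssd: SumScoreDistribution) -> float:
    """Inverse standard deviation 1/sigma of the exact sum score."""
    _, var = _moments(ssd)
    sigma = math.sqrt(var)
    if sigma == 0.0:
        raise DegenerateDistributionError(
            "sum-score distribution is a point mass; SAS undefined"
        )
    return 1.0 / sigma


def resilience_exact(ssd: SumScoreDistribution) -> ResilienceReport:
    """ESA and SAS from an exact sum-score distribution, as one report."""
    mu, var = _moments(ssd)
    sigma = math.sqrt(var)
    if sigma == 0.0:
        return ResilienceReport(esa=mu, sas=None, source="exact", degenerate=True)
    return ResilienceReport(esa=mu, sas=1.0 / sigma, source="exact")


def _sum_scores(samples) -> np.ndarray:
    X = np.asarray(samples)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("samples must be a non-empty iterations x nodes matrix")
    return X.sum(axis=1, dtype=float)


def esa_from_samples(samples) -> float:
    """Mean sum score of a sampled (iterations x nodes) state matrix."""
    return float(_sum_scores(samples).mean())


def sas_from_samples(samples, *, ddof: int = 0) -> float:
    """Inverse standard deviation of sampled sum scores.

    The population denominator (``ddof=0``) mirrors the exact definition;
    pass ``ddof=1`` for the sample convention.
    """
    y = _sum_scores(samples)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 sampled states for SAS")
    sigma = float(y.std(ddof=ddof))
    if sigma == 0.0:
        raise DegenerateDistributionError(
            "all sampled sum scores identical; SAS undefined"
        )
    return 1.0 / sigma


def distribution_entropy(dist: StateDistribution) -> float:
    """Shannon entropy -sum p log p of the joint distribution, in nats.

    High entropy means many states are comparably likely (unstable
    dynamics); low entropy means a few dominant states (organized,
    stable dynamics).  SAS tracks the same notion on the sum score.
    """
    p = dist.probs[dist.probs > 0.0]
    return float(-(p * np.log(p)).sum())
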