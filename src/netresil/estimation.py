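"""Ising network estimation from binary data (eLasso) and binarization.

The eLasso procedure regresses each binary item on all others with an
L1-penalized logistic regression over a path of penalty weights, selects
each node's model by the extended BIC

.. math:: \\mathrm{EBIC}_\\gamma = -2\\,\\ell + d\\,\\log N
          + 2\\gamma\\, d \\log(p - 1),

(:math:`d` = number of retained neighbors, :math:`p` = item count), and
symmetrizes the directed neighborhoods into an undirected network.
Under the AND rule an edge is present only when both directions retain
it, its weight the mean of the two coefficients; intercepts become
thresholds.

Ordinal screening items (five levels, 0-4) are binarized before
estimation: no/modest presence (0-2) maps to 0, moderate/high presence
(3-4) maps to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .network import IsingNetwork, make_network

__all__ = ["BinaryDataset", "EstimationConfig", "binarize", "fit_elasso"]


@dataclass
class BinaryDataset:
    """Persons x items binary matrix with labels and constant-item flags."""

    data: pd.DataFrame
    constant_items: tuple = ()

    def __post_init__(self):
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryDataset entries must be 0/1")

    @property
    def labels(self) -> tuple:
        return tuple(self.data.columns)


@dataclass(frozen=True)
class EstimationConfig:
    """eLasso settings.

    ``ebic_gamma`` is the EBIC sparsity hyperparameter (0.25 default);
    ``rule`` symmetrizes directed neighborhoods ("AND": both directions
    required; "OR": either suffices); ``combine`` merges the two
    directed coefficients ("mean" or "max" magnitude).  The penalty path
    has ``n_lambda`` log-spaced values from each node's smallest
    all-zero penalty down to ``lambda_min_ratio`` times it.
    """

    ebic_gamma: float = 0.25
    rule: str = "AND"
    combine: str = "mean"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001

    def __post_init__(self):
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.combine not in ("mean", "max"):
            raise ValueError("combine must be 'mean' or 'max'")


def binarize(data, cut: int = 3, levels=(0, 4)) -> BinaryDataset:
    """Recode ordinal items to binary: level >= ``cut`` becomes 1.

    The default ``cut=3`` on five-level (0-4) items maps {0,1,2} to 0
    and {3,4} to 1.  Items constant after recoding are flagged (and
    later dropped by :func:`fit_elasso` with a warning).
    """
    df = pd.DataFrame(data)
    lo, hi = levels
    vals = df.to_numpy()
    bad = (vals < lo) | (vals > hi) | ~np.isfinite(vals.astype(float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"out-of-range level {vals[r, c]!r} for item {df.columns[c]!r}, "
            f"person {df.index[r]!r} (allowed {lo}..{hi})"
        )
    binary = (df >= cut).astype(int)
    constant = tuple(col for col in binary.columns if binary[col].nunique() == 1)
    return BinaryDataset(data=binary, constant_items=constant)


def _lambda_path(X: np.ndarray, y: np.ndarray, cfg: EstimationConfig) -> np.ndarray:
    N = X.shape[0]
    # smallest penalty that zeroes all coefficients (KKT at beta = 0)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / N
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def _node_fit(X: np.ndarray, y: np.ndarray, cfg: EstimationConfig):
    """EBIC-selected lasso logistic fit of one node on the rest."""
    N, p_minus_1 = X.shape
    best = (np.inf, np.zeros(p_minus_1), 0.0)
    log_n = np.log(N)
    log_p = np.log(max(p_minus_1, 1))
    for lam in _lambda_path(X, y, cfg):
        # liblinear penalizes the intercept; a large intercept_scaling
        # makes that penalty negligible, matching the usual convention
        # of an unpenalized threshold.
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (N * lam), solver="liblinear",
            tol=1e-5, max_iter=2000, intercept_scaling=100.0,
        )
        clf.fit(X, y)
        coef = clf.coef_[0]
        eta = clf.intercept_[0] + X @ coef
        # Bernoulli log-likelihood via log(1+e^eta) computed stably
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        d = int(np.count_nonzero(coef))
        ebic = -2.0 * ll + d * log_n + 2.0 * cfg.ebic_gamma * d * log_p
        if ebic < best[0]:
            best = (ebic, coef.copy(), float(clf.intercept_[0]))
    return best[1], best[2]


def fit_elasso(data, cfg: EstimationConfig | None = None) -> IsingNetwork:
    """Estimate an Ising network by nodewise penalized logistic regression.

    Parameters
    ----------
    data : BinaryDataset or DataFrame
        Persons x items 0/1 matrix.  Constant items are dropped with a
        warning (no regression is identified for them).
    cfg : EstimationConfig, optional

    Returns the symmetrized network (thresholds = selected intercepts,
    weights = combined neighborhood coefficients).
    """
    cfg = cfg or EstimationConfig()
    if not isinstance(data, BinaryDataset):
        data = BinaryDataset(pd.DataFrame(data))
    df = data.data
    constant = [c for c in df.columns if df[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"dropping constant items (no variation after binarization): {constant}",
            stacklevel=2,
        )
        df = df.drop(columns=constant)
    labels = tuple(df.columns)
    p = len(labels)
    if p < 2:
        raise ValueError("need at least 2 varying items to estimate a network")
    X_all = df.to_numpy(dtype=float)
    B = np.zeros((p, p))  # B[j, k]: coefficient of item k predicting item j
    tau = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        coef, intercept = _node_fit(X_all[:, others], X_all[:, j], cfg)
        if np.abs(coef).max(initial=0.0) > 30.0:
            warnings.warn(
                f"possible perfect separation for item {labels[j]!r}; "
                "coefficients from the largest finite-penalty model retained",
                stacklevel=2,
            )
        B[j, others] = coef
        tau[j] = intercept
    W = np.zeros((p, p))
    for j in range(p):
        for k in range(j + 1, p):
            a, b = B[j, k], B[k, j]
            keep = (a != 0.0 and b != 0.0) if cfg.rule == "AND" else (a != 0.0 or b != 0.0)
            if not keep:
                continue
            if cfg.combine == "mean":
                W[j, k] = W[k, j] = (a + b) / 2.0
            else:
                W[j, k] = W[k, j] = a if abs(a) >= abs(b) else b
    return make_network(tau, W, labels=labels)
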