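"""MSM parameter estimation: stabilized IPTW and sequential G-computation.

The marginal structural model here is linear in a single baseline covariate
and the cumulative number of treated time points,
``E(Y^a | L01) = mu0 + mu1*L01 + mu2*cum(a)`` (optionally with an
L01-by-cum interaction).  IPTW fits it by weighted least squares of the
observed outcome with cumulative stabilized weights — per-time numerator
probabilities conditioning only on L01 divided by the fitted propensity of
the observed treatment given the full history — with robust (sandwich)
standard errors.  G-computation regresses the stacked time-0 counterfactual
predictions over all patterns on the MSM design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._solvers import fit_logistic
from .dgp import LongitudinalData
from .working import QStack

__all__ = [
    "cum",
    "WeightSet",
    "MSMEstimate",
    "compute_weights",
    "fit_msm_iptw",
    "fit_msm_gcomp",
    "m_out_of_n_bootstrap",
]


def cum(pattern: Sequence[int]) -> int:
    """Number of treated time points in a pattern, e.g. (0,1,1,1,1) -> 4."""
    arr = np.asarray(pattern)
    if not np.all(np.isin(arr, [0, 1])):
        raise ValueError("treatment pattern entries must be 0/1")
    return int(arr.sum())


@dataclass
class WeightSet:
    """Cumulative stabilized weights with per-time components and diagnostics."""

    w: np.ndarray
    numerators: np.ndarray  # (n, T+1) probability of the observed treatment
    denominators: np.ndarray
    censoring_factor: np.ndarray | None = None

    @property
    def diagnostics(self) -> dict:
        w = self.w
        return {
            "min": float(w.min()),
            "max": float(w.max()),
            "mean": float(w.mean()),
            "ess": float(w.sum() ** 2 / np.sum(w**2)),
        }


@dataclass
class MSMEstimate:
    """MSM coefficients with standard errors and the weights used."""

    mu: pd.Series
    se: pd.Series | None
    estimator: str
    weight_diagnostics: dict = field(default_factory=dict)


def compute_weights(
    data: LongitudinalData,
    prob_treat: np.ndarray,
    l01: str,
    numerator: str | np.ndarray = "l01",
    prob_censor: np.ndarray | None = None,
    eps: float = 1e-12,
) -> WeightSet:
    """Cumulative stabilized weights ``prod_t num_t / den_t``.

    ``prob_treat`` is an (n, T+1) matrix of fitted P(A_t = 1 | history).
    The numerator is, per time, a logistic model of A_t on L01 alone
    (default), the marginal treatment frequency (``"marginal"``), or a
    user-supplied (n, T+1) matrix of P(A_t = 1 | numerator conditioning).
    ``prob_censor`` (n, n_censor_times) of P(C_t = 1 | history) adds inverse
    probability-of-remaining-uncensored factors with marginal numerators.
    """
    n, K = prob_treat.shape
    A = np.column_stack([a.astype(float) for a in data.A])
    den = np.where(A == 1, prob_treat, 1.0 - prob_treat)
    if np.any(den <= eps):
        bad = np.argwhere(den <= eps)
        raise ValueError(
            f"positivity violation: denominator <= {eps:g} at (subject, time) "
            f"{bad[:10].tolist()}{'...' if len(bad) > 10 else ''}"
        )
    if isinstance(numerator, np.ndarray):
        p_num = numerator
    elif numerator == "marginal":
        p_num = np.tile(A.mean(axis=0), (n, 1))
    elif numerator == "l01":
        x01 = data.covariate(l01)
        X = np.column_stack([np.ones(n), x01])
        p_num = np.empty_like(prob_treat)
        for t in range(K):
            coef = fit_logistic(X, A[:, t])
            p_num[:, t] = 1.0 / (1.0 + np.exp(-(X @ coef)))
    else:
        raise ValueError(f"unknown numerator spec {numerator!r}")
    num = np.where(A == 1, p_num, 1.0 - p_num)
    w = np.prod(num / den, axis=1)
    cens = None
    if prob_censor is not None:
        C = np.column_stack([c.astype(float) for c in data.C])
        pc = np.asarray(prob_censor)
        if np.any(1.0 - pc <= eps):
            raise ValueError("positivity violation in censoring probabilities")
        marg_unc = np.tile(1.0 - C.mean(axis=0), (n, 1))
        cens = np.prod(marg_unc / (1.0 - pc), axis=1)
        w = w * cens
    return WeightSet(w=w, numerators=num, denominators=den, censoring_factor=cens)


def _msm_design(
    x01: np.ndarray, cum_a: np.ndarray, interaction: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(x01), x01, cum_a]
    names = ["const", "L01", "cum"]
    if interaction:
        cols.append(x01 * cum_a)
        names.append("L01:cum")
    return np.column_stack(cols), names


def fit_msm_iptw(
    data: LongitudinalData,
    weights: WeightSet,
    l01: str,
    interaction: bool = False,
) -> MSMEstimate:
    """Weighted least squares of Y on the MSM design with sandwich SEs."""
    x01 = data.covariate(l01)
    cum_obs = np.sum([a for a in data.A], axis=0).astype(float)
    X, names = _msm_design(x01, cum_obs, interaction)
    res = sm.WLS(data.Y, X, weights=weights.w).fit(cov_type="HC0")
    return MSMEstimate(
        mu=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        estimator="iptw",
        weight_diagnostics=weights.diagnostics,
    )


def fit_msm_gcomp(
    qstack: QStack,
    data: LongitudinalData,
    l01: str,
    interaction: bool = False,
) -> MSMEstimate:
    """Regress stacked time-0 counterfactual predictions on the MSM design.

    No analytic standard errors are produced; use
    :func:`m_out_of_n_bootstrap` (with m = n for a standard subject-level
    bootstrap) on the full pipeline for uncertainty.
    """
    n = data.n
    x01 = data.covariate(l01)
    xs, cs, ys = [], [], []
    for j, pat in enumerate(qstack.patterns):
        xs.append(x01)
        cs.append(np.full(n, float(cum(pat))))
        ys.append(qstack.q[0][:, j])
    X, names = _msm_design(np.concatenate(xs), np.concatenate(cs), interaction)
    coef, *_ = np.linalg.lstsq(X, np.concatenate(ys), rcond=None)
    return MSMEstimate(
        mu=pd.Series(coef, index=names), se=None, estimator="gcomp"
    )


def m_out_of_n_bootstrap(
    pipeline: Callable[[LongitudinalData], np.ndarray],
    data: LongitudinalData,
    m: int,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """m-out-of-n bootstrap percentile intervals, rescaled by sqrt(m/n).

    Resamples of size m are drawn with replacement; the percentile interval
    of the resampled estimates around the full-sample estimate is shrunk by
    sqrt(m/n).  Designed for post-selection settings where the standard
    bootstrap is unreliable; coverage is not guaranteed.
    """
    n = data.n
    if m >= n:
        warnings.warn(
            "m >= n: this reduces to the standard bootstrap", stacklevel=2
        )
    est = np.atleast_1d(np.asarray(pipeline(data), dtype=float))
    rng = np.random.default_rng(seed)
    boots = np.empty((B, est.size))
    for b in range(B):
        idx = rng.integers(0, n, size=min(m, n))
        boots[b] = np.atleast_1d(np.asarray(pipeline(data.subset(idx)), dtype=float))
    a = (1.0 - level) / 2.0
    scale = np.sqrt(min(m, n) / n)
    qlo = np.quantile(boots, a, axis=0)
    qhi = np.quantile(boots, 1.0 - a, axis=0)
    return {
        "estimate": est,
        "lower": est - scale * (qhi - est),
        "upper": est - scale * (qlo - est),
        "boot": boots,
        "m": int(min(m, n)),
    }
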