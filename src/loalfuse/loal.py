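"""Longitudinal outcome-adaptive LASSO for pooled treatment/censoring models.

The pooled ("saturated") propensity model stacks the time-specific logistic
treatment models into a single regression with per-time intercept indicator
columns and indicator-masked covariate columns ``V_{tau,t,k} =
I(time == tau) * L_{t,k}`` for ``t <= tau`` (plus past-treatment slots).
Only the covariate columns are penalty candidates; their adaptive weights
``|beta|^(-gamma)`` come from the working structural models, so covariates
with no conditional outcome association (e.g., instruments) are pushed out
of the treatment model.  The regularization parameter is chosen by a
longitudinal covariate-balance criterion — a sum over times and candidate
covariates of absolute IPT-weighted mean differences, weighted by |beta| —
rather than by predictive fit.  The identical machinery applies to a binary
censoring process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._solvers import (
    WEIGHT_CAP,
    ConvergenceError,
    fit_logistic,
    fit_weighted_l1,
    kkt_residual_l1,
    lambda_max,
)
from .dgp import LongitudinalData
from .working import WorkingCoefficients

__all__ = [
    "Column",
    "PooledDesign",
    "PenalizedTreatmentFit",
    "PositivityError",
    "build_pooled_design",
    "adaptive_weights",
    "fit_loal_path",
    "pooled_probabilities",
    "balance_score",
    "select_lambda_and_refit",
    "fit_loal",
]


class PositivityError(RuntimeError):
    """A fitted probability is numerically 0 or 1 for an at-risk row."""


@dataclass(frozen=True)
class Column:
    """Pooled-design column: (model time tau, kind, name, measurement time t)."""

    tau: int
    kind: str  # 'intercept' | 'covariate' | 'treatment'
    name: str
    t: int | None = None

    @property
    def key(self) -> tuple:
        return (self.tau, self.t, self.name)

    def label(self) -> str:
        return f"tau{self.tau}:{self.name}"


@dataclass
class PooledDesign:
    """Block design of V-variables for the pooled binary-process model."""

    X: np.ndarray
    y: np.ndarray
    columns: list[Column]
    row_tau: np.ndarray
    row_subject: np.ndarray
    process: str
    n_times: int
    n_subjects: int

    @property
    def shrink_idx(self) -> np.ndarray:
        """Indices of the shrinkable set (covariate columns only)."""
        return np.array(
            [j for j, c in enumerate(self.columns) if c.kind == "covariate"], dtype=int
        )

    @property
    def unpenalized_idx(self) -> np.ndarray:
        return np.array(
            [j for j, c in enumerate(self.columns) if c.kind != "covariate"], dtype=int
        )

    def column_index(self, tau: int, name: str) -> int:
        for j, c in enumerate(self.columns):
            if c.tau == tau and c.name == name:
                return j
        raise KeyError(f"no column for model time {tau}, term {name!r}")


def build_pooled_design(
    data: LongitudinalData,
    process: str = "treatment",
    history_spec: Mapping[int, Sequence[str]] | None = None,
    absorbing: bool | None = None,
) -> PooledDesign:
    """Assemble the pooled design for the treatment or censoring process.

    ``history_spec`` maps model time tau to the covariate names included
    (default: every covariate measured at t <= tau).  Covariates measured
    after tau are rejected (no future leakage).  With ``absorbing`` (the
    default for censoring), subject-times after the process first equals 1
    are dropped from the rows.
    """
    if process not in ("treatment", "censoring"):
        raise ValueError("process must be 'treatment' or 'censoring'")
    if process == "censoring" and data.C is None:
        raise ValueError("data has no censoring indicators")
    if absorbing is None:
        absorbing = process == "censoring"
    resp = data.A if process == "treatment" else data.C
    n, n_times = data.n, len(resp)

    columns: list[Column] = []
    for tau in range(n_times):
        columns.append(Column(tau, "intercept", "const"))
        names = (
            list(history_spec[tau])
            if history_spec is not None and tau in history_spec
            else [nm for t in range(min(tau, data.T) + 1) for nm in data.names[t]]
        )
        for nm in names:
            t_meas = data.covariate_time(nm)
            if t_meas > tau:
                raise ValueError(
                    f"covariate {nm!r} is measured at time {t_meas}, after model "
                    f"time {tau}; future covariates cannot enter the history"
                )
            columns.append(Column(tau, "covariate", nm, t_meas))
        for k in range(tau):
            columns.append(Column(tau, "treatment", f"A{k}"))

    rows_X, rows_y, rows_tau, rows_subj = [], [], [], []
    at_risk = np.ones(n, dtype=bool)
    for tau in range(n_times):
        idx = np.flatnonzero(at_risk)
        block = np.zeros((idx.size, len(columns)))
        for j, c in enumerate(columns):
            if c.tau != tau:
                continue
            if c.kind == "intercept":
                block[:, j] = 1.0
            elif c.kind == "covariate":
                block[:, j] = data.covariate(c.name)[idx]
            else:
                block[:, j] = data.A[int(c.name[1:])][idx]
        rows_X.append(block)
        rows_y.append(np.asarray(resp[tau], dtype=float)[idx])
        rows_tau.append(np.full(idx.size, tau))
        rows_subj.append(idx)
        if absorbing:
            at_risk &= np.asarray(resp[tau]) == 0
    return PooledDesign(
        X=np.vstack(rows_X),
        y=np.concatenate(rows_y),
        columns=columns,
        row_tau=np.concatenate(rows_tau),
        row_subject=np.concatenate(rows_subj),
        process=process,
        n_times=n_times,
        n_subjects=n,
    )


def adaptive_weights(beta: WorkingCoefficients, design: PooledDesign) -> np.ndarray:
    """Penalty factors ``|beta_hat_j|^(-gamma)`` aligned with the design columns.

    Intercept and past-treatment columns get weight 0 (never penalized).  An
    exactly zero beta maps to a large finite cap so the objective stays
    finite while effectively excluding the covariate.
    """
    pen = np.zeros(len(design.columns))
    for j, c in enumerate(design.columns):
        if c.kind != "covariate":
            continue
        b = beta.value(c.tau, c.name)
        if b == 0.0:
            warnings.warn(
                f"working coefficient for {c.label()} is exactly zero; "
                f"penalty weight capped at {WEIGHT_CAP:g}",
                stacklevel=2,
            )
            pen[j] = WEIGHT_CAP
        else:
            pen[j] = min(abs(b) ** (-beta.gamma), WEIGHT_CAP)
    return pen


@dataclass
class PenalizedTreatmentFit:
    """Coefficient path of the LOAL with its tuning record."""

    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambda, n_columns)
    pen: np.ndarray
    design: PooledDesign
    balance: np.ndarray | None = None
    lambda_index: int | None = None
    alpha_refit: np.ndarray | None = None
    active: list[int] = field(default_factory=list)

    @property
    def lambda_selected(self) -> float:
        return float(self.lambdas[self.lambda_index])

    @property
    def alpha_selected(self) -> np.ndarray:
        return self.coefs[self.lambda_index]

    def kkt_residuals(self) -> np.ndarray:
        return np.array(
            [
                kkt_residual_l1(self.design.X, self.design.y, c, lam, self.pen)
                for lam, c in zip(self.lambdas, self.coefs)
            ]
        )

    def tidy(self) -> pd.DataFrame:
        rows = []
        for lam, coef in zip(self.lambdas, self.coefs):
            for c, v in zip(self.design.columns, coef):
                rows.append(
                    {
                        "model_time": c.tau,
                        "term": c.name,
                        "lambda": lam,
                        "estimate": v,
                    }
                )
        return pd.DataFrame(rows)


def fit_loal_path(
    design: PooledDesign,
    pen: np.ndarray,
    lambdas: Sequence[float] | None = None,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-4,
) -> PenalizedTreatmentFit:
    """Warm-started weighted-L1 path, largest lambda giving the all-zero model."""
    X, y = design.X, design.y
    if lambdas is None:
        lmax = lambda_max(X, y, pen) * (1.0 + 1e-6)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be descending")
    coefs = np.empty((len(lambdas), X.shape[1]))
    coef = None
    for i, lam in enumerate(lambdas):
        try:
            coef = fit_weighted_l1(X, y, pen, lam, coef_init=coef)
        except ConvergenceError as err:
            raise ConvergenceError(f"{err} (lambda index {i})") from err
        coefs[i] = coef
    return PenalizedTreatmentFit(lambdas=lambdas, coefs=coefs, pen=pen, design=design)


def pooled_probabilities(design: PooledDesign, alpha: np.ndarray) -> np.ndarray:
    """Per-subject-per-time fitted P(process = 1 | history), NaN off risk set."""
    p_rows = expit(design.X @ alpha)
    out = np.full((design.n_subjects, design.n_times), np.nan)
    out[design.row_subject, design.row_tau] = p_rows
    return out


def _cumulative_stabilized_weights(
    design: PooledDesign, probs: np.ndarray, eps: float = 1e-10
) -> np.ndarray:
    """Stabilized weight per (subject, time): prod_{k<=tau} num_k / den_k.

    Numerators are marginal per-time event frequencies on the risk set;
    denominators are the fitted probabilities of the observed event.
    """
    n, K = probs.shape
    resp = np.full((n, K), np.nan)
    resp[design.row_subject, design.row_tau] = design.y
    w = np.full((n, K), np.nan)
    cum = np.ones(n)
    for k in range(K):
        on = ~np.isnan(probs[:, k])
        pk, ak = probs[on, k], resp[on, k]
        if np.any(pk <= eps) or np.any(pk >= 1 - eps):
            bad = np.flatnonzero(on)[(pk <= eps) | (pk >= 1 - eps)]
            raise PositivityError(
                f"fitted probabilities numerically 0/1 at time {k} for subjects "
                f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
            )
        marg = float(np.mean(ak))
        num = np.where(ak == 1, marg, 1.0 - marg)
        den = np.where(ak == 1, pk, 1.0 - pk)
        cum_on = cum[on] * num / den
        w[on, k] = cum_on
        cum[on] = cum_on
    return w


def balance_score(
    data: LongitudinalData,
    alpha: np.ndarray,
    design: PooledDesign,
    beta: WorkingCoefficients,
    extra_weights: np.ndarray | None = None,
) -> float:
    """Longitudinal weighted absolute mean difference, smaller = better balance.

    For each model time tau and each shrinkable covariate column, the
    absolute difference between the stabilized-IPT-weighted covariate means
    of the event and non-event groups is multiplied by the covariate's
    |beta| working-model weight and summed over covariates and times.
    ``extra_weights`` (n_subjects x n_times) can carry multiplicative
    factors from a companion process (e.g., censoring weights when scoring
    the treatment model).
    """
    probs = pooled_probabilities(design, alpha)
    w = _cumulative_stabilized_weights(design, probs)
    if extra_weights is not None:
        w = w * extra_weights
    resp = np.full_like(probs, np.nan)
    resp[design.row_subject, design.row_tau] = design.y
    score = 0.0
    for j in design.shrink_idx:
        c = design.columns[j]
        on = ~np.isnan(w[:, c.tau])
        x = data.covariate(c.name)[on]
        a = resp[on, c.tau]
        ww = w[on, c.tau]
        m1 = np.average(x[a == 1], weights=ww[a == 1]) if np.any(a == 1) else 0.0
        m0 = np.average(x[a == 0], weights=ww[a == 0]) if np.any(a == 0) else 0.0
        score += abs(beta.value(c.tau, c.name)) * abs(m1 - m0)
    return float(score)


def select_lambda_and_refit(
    fit: PenalizedTreatmentFit,
    data: LongitudinalData,
    beta: WorkingCoefficients,
    extra_weights: np.ndarray | None = None,
) -> PenalizedTreatmentFit:
    """Balance-minimizing lambda, active set, and unpenalized refit.

    Ties in the balance score resolve to the largest lambda among the
    minimizers (most parsimonious model); lambdas at which the weights hit a
    positivity violation are infeasible.
    """
    design = fit.design
    scores = np.full(len(fit.lambdas), np.nan)
    for i, coef in enumerate(fit.coefs):
        try:
            scores[i] = balance_score(data, coef, design, beta, extra_weights)
        except PositivityError:
            continue
    if np.all(np.isnan(scores)):
        raise PositivityError(
            "every lambda on the grid produced a positivity violation; extend "
            "the grid toward larger lambda"
        )
    best = np.nanmin(scores)
    idx = int(np.flatnonzero(scores == best)[0])  # grid is descending: first = largest
    fit.balance = scores
    fit.lambda_index = idx
    fit.active = [int(j) for j in design.shrink_idx if fit.coefs[idx, j] != 0.0]
    cols = np.concatenate([design.unpenalized_idx, np.array(fit.active, dtype=int)])
    cols = np.sort(cols).astype(int)
    refit = np.zeros(len(design.columns))
    refit[cols] = fit_logistic(design.X[:, cols], design.y)
    fit.alpha_refit = refit
    return fit


def fit_loal(
    data: LongitudinalData,
    beta: WorkingCoefficients,
    process: str = "treatment",
    history_spec: Mapping[int, Sequence[str]] | None = None,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-4,
) -> PenalizedTreatmentFit:
    """Design construction, path, balance selection and refit in one call."""
    design = build_pooled_design(data, process=process, history_spec=history_spec)
    pen = adaptive_weights(beta, design)
    fit = fit_loal_path(design, pen, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    return select_lambda_and_refit(fit, data, beta)
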