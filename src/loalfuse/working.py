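"""Sequential counterfactual regressions q_t and working structural models.

The nested conditional expectations ``q_t`` of the outcome under a forced
treatment pattern are estimated by backward recursion: starting from
``q_{T+1} = Y``, at each time ``t`` the next-step quantity is regressed on
the observed covariate and treatment history, and predictions are generated
with the treatments up to ``t`` forced to each pattern of interest.

Stacking the time-``t`` predictions over all patterns and regressing them on
the covariate history plus the pattern's past treatments yields the working
structural-model coefficients ``beta``, whose magnitudes drive the adaptive
penalty of the longitudinal outcome-adaptive LASSO: covariates with no
conditional association with the (counterfactual) outcome get beta near
zero and are therefore penalized heavily in the treatment model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dgp import LongitudinalData, _eval_term, all_patterns

__all__ = [
    "QStack",
    "WorkingCoefficients",
    "default_q_terms",
    "fit_q_sequence",
    "fit_working_beta",
    "fit_working_coefficients",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when a regression design is singular; names the offending terms."""


def _env_of(data: LongitudinalData) -> dict[str, np.ndarray]:
    env: dict[str, np.ndarray] = {}
    for df in data.L:
        for name in df.columns:
            env[name] = df[name].to_numpy()
    for t, a in enumerate(data.A):
        env[f"A{t}"] = a.astype(float)
    return env


def _design(terms: Sequence[str], env: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    return np.column_stack([_eval_term(term, env, n) for term in terms])


def _lstsq_checked(X: np.ndarray, y: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [terms[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design is rank deficient; linearly dependent terms: {bad}"
        )
    return coef


def default_q_terms(data: LongitudinalData) -> dict[int, list[str]]:
    """Main terms of the covariate and treatment history at each time."""
    out = {}
    for t in range(data.T + 1):
        terms = ["const"]
        for k in range(t + 1):
            terms.extend(data.names[k])
        terms.extend(f"A{k}" for k in range(t + 1))
        out[t] = terms
    return out


@dataclass
class QStack:
    """Predicted q_t for every treatment pattern.

    ``q[t]`` is (n, n_patterns) for t = 0..T+1; the last entry equals the
    observed outcome replicated across patterns (recursion base).
    """

    patterns: list[tuple[int, ...]]
    q: list[np.ndarray]
    terms: dict[int, list[str]]

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (subject, pattern, time, q) table for audit/export."""
        rows = []
        for t, q_t in enumerate(self.q):
            for j, pat in enumerate(self.patterns):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": np.arange(q_t.shape[0]),
                            "pattern": "".join(map(str, pat)),
                            "time": t,
                            "q": q_t[:, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def fit_q_sequence(
    data: LongitudinalData,
    patterns: Sequence[Sequence[int]] | None = None,
    regressors: Mapping[int, Sequence[str]] | None = None,
) -> QStack:
    """Backward-recursive estimation of q_t under every pattern.

    ``regressors`` maps time t to the term list of the step regression
    (default: all main terms of the history, including treatments); terms
    may include interactions/powers, e.g. ``"C0*A0"`` or ``"I0^2"``.
    """
    T, n = data.T, data.n
    if patterns is None:
        if T > 5:
            raise ValueError(
                "exhaustive pattern set is too large for T > 5; pass a restricted "
                "regimen space explicitly"
            )
        patterns = all_patterns(T)
    patterns = [tuple(int(a) for a in p) for p in patterns]
    terms = dict(default_q_terms(data))
    if regressors is not None:
        terms.update({int(t): list(v) for t, v in regressors.items()})
    env = _env_of(data)

    q: list[np.ndarray | None] = [None] * (T + 2)
    q[T + 1] = np.tile(data.Y[:, None], (1, len(patterns)))
    for t in range(T, -1, -1):
        X_obs = _design(terms[t], env, n)
        coef = _lstsq_checked(X_obs, q[t + 1], terms[t])
        q_t = np.empty((n, len(patterns)))
        for j, pat in enumerate(patterns):
            env_pat = dict(env)
            for k in range(t + 1):
                env_pat[f"A{k}"] = np.full(n, float(pat[k]))
            q_t[:, j] = _design(terms[t], env_pat, n) @ coef[:, j]
        q[t] = q_t
    return QStack(patterns=patterns, q=q, terms=terms)


@dataclass
class WorkingCoefficients:
    """Stacked working structural-model coefficients per model time.

    ``beta[t]`` is indexed by 'const', covariate names measured at times
    <= t, and past-treatment slots 'A0'..'A{t-1}'.  ``gamma`` is the
    adaptive-weight exponent (> 2 for selection consistency).  Standard
    errors are diagnostic only (plain OLS on the stacked fit).
    """

    beta: dict[int, pd.Series]
    gamma: float = 2.5
    se: dict[int, pd.Series] = field(default_factory=dict)

    def __post_init__(self):
        if not self.gamma > 1:
            raise ValueError("adaptive exponent gamma must exceed 1")

    def value(self, t: int, term: str) -> float:
        return float(self.beta[t][term])

    def nonzero(self) -> dict[int, pd.Series]:
        """beta-dagger: nonzero indicators, intercept/treatment slots forced to 1."""
        out = {}
        for t, b in self.beta.items():
            ind = (b != 0).astype(int)
            ind["const"] = 1
            for term in b.index:
                if term.startswith("A"):
                    ind[term] = 1
            out[t] = ind
        return out

    def tidy(self) -> pd.DataFrame:
        rows = [
            {"model_time": t, "term": term, "estimate": float(v)}
            for t, b in sorted(self.beta.items())
            for term, v in b.items()
        ]
        return pd.DataFrame(rows)


def fit_working_beta(
    qstack: QStack, data: LongitudinalData, t: int, gamma: float = 2.5
) -> pd.Series:
    """Least-squares fit of the time-t working structural model.

    Stacks q_t over patterns (each subject replicated once per pattern with
    the pattern's past treatments as regressors) and regresses on the
    covariate history main terms; replicates are unweighted.
    """
    n = data.n
    pats = qstack.patterns
    cov_terms = [name for k in range(t + 1) for name in data.names[k]]
    treat_terms = [f"A{k}" for k in range(t)]
    y = qstack.q[t].ravel(order="F")  # pattern-major stacking
    blocks = []
    base = np.column_stack(
        [np.ones(n)] + [data.covariate(name) for name in cov_terms]
    )
    for pat in pats:
        tre = np.tile([float(pat[k]) for k in range(t)], (n, 1)) if t else np.empty((n, 0))
        blocks.append(np.hstack([base, tre]))
    X = np.vstack(blocks)
    terms = ["const"] + cov_terms + treat_terms

    # past-treatment columns can be constant under restricted regimen spaces
    keep = np.ones(X.shape[1], dtype=bool)
    for j, term in enumerate(terms):
        if term in treat_terms and np.ptp(X[:, j]) == 0:
            warnings.warn(
                f"past-treatment slot {term!r} is constant across the supplied "
                "patterns; dropping it from the time-"
                f"{t} working model",
                stacklevel=2,
            )
            keep[j] = False
    coef = _lstsq_checked(X[:, keep], y, [tm for tm, k in zip(terms, keep) if k])
    full = pd.Series(0.0, index=terms)
    full[[tm for tm, k in zip(terms, keep) if k]] = coef
    return full


def fit_working_coefficients(
    data: LongitudinalData,
    patterns: Sequence[Sequence[int]] | None = None,
    regressors: Mapping[int, Sequence[str]] | None = None,
    gamma: float = 2.5,
) -> WorkingCoefficients:
    """Convenience wrapper: q recursion plus working models at every time."""
    qs = fit_q_sequence(data, patterns=patterns, regressors=regressors)
    beta = {t: fit_working_beta(qs, data, t, gamma) for t in range(data.T + 1)}
    return WorkingCoefficients(beta=beta, gamma=gamma)
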