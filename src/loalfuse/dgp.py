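"""Synthetic longitudinal data-generating processes.

This module simulates observational data with time-varying binary treatments
``A_t``, multivariate covariates ``L_t`` (confounders, instruments, pure
outcome causes), and a continuous end-of-study outcome ``Y``.  The built-in
two-time-point process (:func:`scenario1_spec`) draws two baseline variables
``C0`` (confounder) and ``I0`` (instrument) from standard normals, assigns
``A0 ~ Bernoulli(expit(1.515*C0 + I0))``, generates ``C1`` and ``I1`` as
Gaussians with means ``A0 + C0`` and ``C0``, assigns
``A1 ~ Bernoulli(expit(-0.5 + 0.5*C0 + 0.25*C1 + 0.5*A0 + I1))``, and draws
``Y`` from a linear model in the confounders and treatments (optionally with
a covariate interaction or a treatment effect-modification term).  This
construction makes the marginal (instrument-free) logistic coefficient of
``C0`` equal in the two treatment models (approximately 1.28), which is what
allows a fused treatment model to be correct.

Counterfactual outcomes under forced treatment patterns are simulated with
common random numbers, so that forcing the factual treatments reproduces the
factual outcome exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CovariateDef",
    "DGPSpec",
    "LongitudinalData",
    "scenario1_spec",
    "generate",
    "counterfactual_outcomes",
    "true_msm_parameters",
    "all_patterns",
    "to_wide_frame",
    "write_csv",
    "read_wide_csv",
]

ROLES = ("confounder", "instrument", "outcome_cause")
OUTCOME_VARIANTS = ("main_terms", "covariate_interaction", "effect_modification")

_FACTOR_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)(?:\^([0-9]+))?$")


def _eval_term(term: str, env: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    """Evaluate a product term like ``C0``, ``A0*C1^2`` or ``const``."""
    if term == "const":
        return np.ones(n)
    out = np.ones(n)
    for factor in term.split("*"):
        m = _FACTOR_RE.match(factor.strip())
        if m is None:
            raise ValueError(f"cannot parse term factor {factor!r}")
        name, power = m.group(1), m.group(2)
        if name not in env:
            raise ValueError(f"term {term!r} references unknown variable {name!r}")
        x = env[name]
        out = out * (x ** int(power) if power else x)
    return out


def _linear_predictor(terms: Mapping[str, float], env: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    lp = np.zeros(n)
    for term, coef in terms.items():
        lp += coef * _eval_term(term, env, n)
    return lp


@dataclass(frozen=True)
class CovariateDef:
    """One covariate in the causal ordering.

    ``mean_terms`` is a linear map over previously generated variables
    (covariate names and treatment names ``A0``, ``A1``, ... ; key ``const``
    for an intercept); the covariate is Gaussian around that mean with
    standard deviation ``sd``.
    """

    name: str
    role: str
    mean_terms: Mapping[str, float] = field(default_factory=dict)
    sd: float = 1.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown covariate role {self.role!r}; expected one of {ROLES}")
        if not self.sd > 0:
            raise ValueError(f"noise sd for {self.name!r} must be strictly positive")


@dataclass(frozen=True)
class DGPSpec:
    """Full specification of a longitudinal data-generating process.

    Treatments are binary with logistic linear predictors over the history;
    ``T`` is the index of the last treatment time (times run 0..T).
    """

    T: int
    covariates: tuple  # tuple over time of tuples of CovariateDef
    treatment_terms: tuple  # tuple over time of Mapping[str, float]
    outcome_terms: Mapping[str, float]
    outcome_variant: str = "main_terms"
    outcome_sd: float = 1.0

    def __post_init__(self):
        if self.outcome_variant not in OUTCOME_VARIANTS:
            raise ValueError(
                f"unknown outcome variant {self.outcome_variant!r}; "
                f"expected one of {OUTCOME_VARIANTS}"
            )
        if len(self.covariates) != self.T + 1 or len(self.treatment_terms) != self.T + 1:
            raise ValueError("covariates and treatment_terms must have length T+1")
        if not self.outcome_sd > 0:
            raise ValueError("outcome noise sd must be strictly positive")
        # Validate the causal ordering: every referenced name must already exist.
        known: list[str] = ["const"]
        all_names: set[str] = set()
        for t in range(self.T + 1):
            for cov in self.covariates[t]:
                if cov.name in all_names:
                    raise ValueError(f"duplicate covariate name {cov.name!r}")
                for ref in cov.mean_terms:
                    self._check_term(ref, known)
                known.append(cov.name)
                all_names.add(cov.name)
            for ref in self.treatment_terms[t]:
                self._check_term(ref, known)
            known.append(f"A{t}")
        for ref in self.outcome_terms:
            self._check_term(ref, known)

    @staticmethod
    def _check_term(term: str, known: Sequence[str]) -> None:
        if term == "const":
            return
        for factor in term.split("*"):
            m = _FACTOR_RE.match(factor.strip())
            if m is None:
                raise ValueError(f"cannot parse term {term!r}")
            if m.group(1) not in known:
                raise ValueError(
                    f"term {term!r} references {m.group(1)!r} before it is generated"
                )

    @property
    def covariate_names(self) -> list[list[str]]:
        return [[c.name for c in covs] for covs in self.covariates]

    def roles(self) -> dict[str, str]:
        return {c.name: c.role for covs in self.covariates for c in covs}

    def confounders(self) -> list[str]:
        return [c.name for covs in self.covariates for c in covs if c.role == "confounder"]

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "covariates": [
                [
                    {"name": c.name, "role": c.role, "mean_terms": dict(c.mean_terms), "sd": c.sd}
                    for c in covs
                ]
                for covs in self.covariates
            ],
            "treatment_terms": [dict(tt) for tt in self.treatment_terms],
            "outcome_terms": dict(self.outcome_terms),
            "outcome_variant": self.outcome_variant,
            "outcome_sd": self.outcome_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DGPSpec":
        return cls(
            T=d["T"],
            covariates=tuple(
                tuple(CovariateDef(c["name"], c["role"], c["mean_terms"], c["sd"]) for c in covs)
                for covs in d["covariates"]
            ),
            treatment_terms=tuple(d["treatment_terms"]),
            outcome_terms=d["outcome_terms"],
            outcome_variant=d["outcome_variant"],
            outcome_sd=d["outcome_sd"],
        )


@dataclass
class LongitudinalData:
    """Wide longitudinal dataset: covariates per time, treatments, outcome.

    ``L[t]`` holds the (standardized, when produced by :func:`generate`)
    covariates measured at time ``t``; ``standardization`` maps covariate
    name -> (mean, sd) applied.  ``true_propensity``, populated by the
    simulator, records the generating P(A_t = 1 | history) for oracle-weight
    diagnostics; it is never used by the estimators unless explicitly passed.
    """

    L: list[pd.DataFrame]
    A: list[np.ndarray]
    Y: np.ndarray
    C: list[np.ndarray] | None = None
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    true_propensity: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.Y)
        for df in self.L:
            if len(df) != n:
                raise ValueError("all covariate frames must have the same number of rows")
        for a in self.A:
            if len(a) != n:
                raise ValueError("treatment arrays must match the outcome length")
            vals = np.unique(a)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("treatments must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def T(self) -> int:
        return len(self.A) - 1

    def covariate(self, name: str) -> np.ndarray:
        for df in self.L:
            if name in df.columns:
                return df[name].to_numpy()
        raise KeyError(f"no covariate named {name!r}")

    def covariate_time(self, name: str) -> int:
        for t, df in enumerate(self.L):
            if name in df.columns:
                return t
        raise KeyError(f"no covariate named {name!r}")

    @property
    def names(self) -> list[list[str]]:
        return [list(df.columns) for df in self.L]

    def subset(self, idx: np.ndarray) -> "LongitudinalData":
        return LongitudinalData(
            L=[df.iloc[idx].reset_index(drop=True) for df in self.L],
            A=[a[idx] for a in self.A],
            Y=self.Y[idx],
            C=None if self.C is None else [c[idx] for c in self.C],
            standardization=dict(self.standardization),
            true_propensity=None if self.true_propensity is None else self.true_propensity[idx],
        )


# ---------------------------------------------------------------------------
# Scenario 1

# Defaults chosen so each variant has a clean closed-form truth: the
# main-terms process gives
# (mu0, mu1, mu2) = (-1.5, 1.5, 1.25) with the treatment effect exactly
# linear in cum(a) (total a0 effect 0.25 + 1.0 through C1 equals the a1
# effect 1.25); the interaction variants shift them to (1, 2.75, 1.25) and
# (-1.5, 4, 5) respectively.  Noise sds default to 1 (a package convention).
_SCENARIO1_OUTCOME_MAIN = {"const": -1.5, "C0": 0.5, "A0": 0.25, "C1": 1.0, "A1": 1.25}
_SCENARIO1_INTERACTION = {
    "main_terms": {},
    "covariate_interaction": {"C0*C1": 2.5},
    "effect_modification": {"A0*C1^2": 2.5},
}


def scenario1_spec(
    outcome_variant: str = "main_terms",
    outcome_coefficients: Mapping[str, float] | None = None,
) -> DGPSpec:
    """Two-time-point process with one confounder and one instrument per time.

    The treatment linear predictors are ``1.515*C0 + I0`` at time 0 and
    ``-0.5 + 0.5*C0 + 0.25*C1 + 0.5*A0 + I1`` at time 1; ``C1`` has mean
    ``A0 + C0`` and ``I1`` mean ``C0``, all with unit Gaussian noise.  The
    default outcome coefficients are package constants chosen to reproduce
    exact reference true MSM parameter values per variant (see the module
    constants above); pass ``outcome_coefficients`` (used verbatim) to
    override.
    """
    if outcome_variant not in OUTCOME_VARIANTS:
        raise ValueError(
            f"unknown outcome variant {outcome_variant!r}; expected one of {OUTCOME_VARIANTS}"
        )
    if outcome_coefficients is None:
        terms = dict(_SCENARIO1_OUTCOME_MAIN)
        terms.update(_SCENARIO1_INTERACTION[outcome_variant])
    else:
        terms = dict(outcome_coefficients)
    return DGPSpec(
        T=1,
        covariates=(
            (
                CovariateDef("C0", "confounder"),
                CovariateDef("I0", "instrument"),
            ),
            (
                CovariateDef("C1", "confounder", {"A0": 1.0, "C0": 1.0}),
                CovariateDef("I1", "instrument", {"C0": 1.0}),
            ),
        ),
        treatment_terms=(
            {"C0": 1.515, "I0": 1.0},
            {"const": -0.5, "C0": 0.5, "C1": 0.25, "A0": 0.5, "I1": 1.0},
        ),
        outcome_terms=terms,
        outcome_variant=outcome_variant,
    )


# ---------------------------------------------------------------------------
# Simulation

def _draw_noise(spec: DGPSpec, n: int, rng: np.random.Generator) -> dict:
    """Exogenous draws shared across counterfactual treatment patterns."""
    noise = {"Y": rng.standard_normal(n)}
    for t in range(spec.T + 1):
        for cov in spec.covariates[t]:
            noise[cov.name] = rng.standard_normal(n)
        noise[f"A{t}"] = rng.uniform(size=n)
    return noise


def _simulate_raw(
    spec: DGPSpec,
    n: int,
    noise: Mapping[str, np.ndarray],
    forced: Sequence[int] | None = None,
) -> tuple[dict[str, np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
    """Run the causal ordering; with ``forced`` the treatments are set, not drawn.

    Returns (covariate env, treatments, Y, propensity matrix).
    """
    env: dict[str, np.ndarray] = {}
    A: list[np.ndarray] = []
    props = np.empty((n, spec.T + 1))
    for t in range(spec.T + 1):
        for cov in spec.covariates[t]:
            mean = _linear_predictor(cov.mean_terms, env, n)
            env[cov.name] = mean + cov.sd * noise[cov.name]
        p = expit(_linear_predictor(spec.treatment_terms[t], env, n))
        props[:, t] = p
        if forced is None:
            a = (noise[f"A{t}"] < p).astype(np.int8)
        else:
            a = np.full(n, forced[t], dtype=np.int8)
        env[f"A{t}"] = a.astype(float)
        A.append(a)
    y = _linear_predictor(spec.outcome_terms, env, n) + spec.outcome_sd * noise["Y"]
    return env, A, y, props


def generate(spec: DGPSpec, n: int, seed: int) -> LongitudinalData:
    """Simulate ``n`` subjects and standardize the covariates.

    Covariates are standardized to zero sample mean and unit sample standard
    deviation (ddof=0); treatments and the outcome are left on their natural
    scale.  Deterministic given ``(spec, n, seed)``.
    """
    if n < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    noise = _draw_noise(spec, n, rng)
    env, A, y, props = _simulate_raw(spec, n, noise)
    L: list[pd.DataFrame] = []
    standardization: dict[str, tuple[float, float]] = {}
    for t in range(spec.T + 1):
        cols = {}
        for cov in spec.covariates[t]:
            x = env[cov.name]
            m, s = float(np.mean(x)), float(np.std(x))
            standardization[cov.name] = (m, s)
            cols[cov.name] = (x - m) / s
        L.append(pd.DataFrame(cols))
    return LongitudinalData(
        L=L, A=A, Y=y, standardization=standardization, true_propensity=props
    )


def all_patterns(T: int) -> list[tuple[int, ...]]:
    """Exhaustive treatment patterns (a_0, ..., a_T)."""
    return [tuple(p) for p in product((0, 1), repeat=T + 1)]


def counterfactual_outcomes(
    spec: DGPSpec,
    n: int,
    seed: int,
    patterns: Sequence[Sequence[int]] | None = None,
) -> tuple[LongitudinalData, dict[tuple[int, ...], np.ndarray]]:
    """Factual data plus counterfactual outcomes under forced patterns.

    All patterns reuse the factual exogenous draws (common random numbers),
    so forcing the observed treatments reproduces the factual outcome.
    """
    if patterns is None:
        patterns = all_patterns(spec.T)
    rng = np.random.default_rng(seed)
    noise = _draw_noise(spec, n, rng)
    env, A, y, props = _simulate_raw(spec, n, noise)
    data = generate(spec, n, seed)  # same seed -> same noise stream
    out = {}
    for pat in patterns:
        _, _, y_pat, _ = _simulate_raw(spec, n, noise, forced=tuple(pat))
        out[tuple(pat)] = y_pat
    return data, out


def true_msm_parameters(
    spec: DGPSpec,
    n_mc: int = 1_000_000,
    seed: int = 0,
    l01: str | None = None,
) -> np.ndarray:
    """Monte-Carlo projection of E(Y^a | L01) onto the linear MSM.

    Simulates counterfactual outcomes under every treatment pattern (common
    random numbers across patterns), then least-squares-projects the stacked
    counterfactual outcomes onto ``mu0 + mu1*L01 + mu2*cum(a)``, where L01 is
    the (standardized) baseline covariate — by default the first confounder.
    """
    if l01 is None:
        l01 = spec.confounders()[0]
    data, cf = counterfactual_outcomes(spec, n_mc, seed)
    x01 = data.covariate(l01)
    rows_x, rows_c, rows_y = [], [], []
    for pat, y in cf.items():
        rows_x.append(x01)
        rows_c.append(np.full(n_mc, float(sum(pat))))
        rows_y.append(y)
    X = np.column_stack(
        [np.ones(n_mc * len(cf)), np.concatenate(rows_x), np.concatenate(rows_c)]
    )
    yy = np.concatenate(rows_y)
    mu, *_ = np.linalg.lstsq(X, yy, rcond=None)
    return mu


# ---------------------------------------------------------------------------
# I/O

def to_wide_frame(data: LongitudinalData) -> pd.DataFrame:
    """One row per subject with columns L{t}_<name>, A{t}, (C{t},) Y."""
    cols: dict[str, np.ndarray] = {}
    for t, df in enumerate(data.L):
        for name in df.columns:
            cols[f"L{t}_{name}"] = df[name].to_numpy()
        if t < len(data.A):
            cols[f"A{t}"] = data.A[t]
        if data.C is not None and t < len(data.C):
            cols[f"C{t}"] = data.C[t]
    for t in range(len(data.L), len(data.A)):
        cols[f"A{t}"] = data.A[t]
    cols["Y"] = data.Y
    return pd.DataFrame(cols)


def write_csv(data: LongitudinalData, path: str | Path, spec: DGPSpec | None = None) -> None:
    """Write wide CSV plus a JSON sidecar with the spec and standardization."""
    path = Path(path)
    to_wide_frame(data).to_csv(path, index=False)
    sidecar = {
        "standardization": {k: list(v) for k, v in data.standardization.items()},
        "spec": spec.to_dict() if spec is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_wide_csv(path: str | Path) -> LongitudinalData:
    """Read a wide-format CSV written by :func:`write_csv` (or hand-built)."""
    df = pd.read_csv(path)
    lt = {}
    for col in df.columns:
        m = re.match(r"^L(\d+)_(.+)$", col)
        if m:
            lt.setdefault(int(m.group(1)), {})[m.group(2)] = df[col].to_numpy()
    times = sorted(lt)
    L = [pd.DataFrame(lt[t]) for t in times]
    A = []
    t = 0
    while f"A{t}" in df.columns:
        A.append(df[f"A{t}"].to_numpy().astype(np.int8))
        t += 1
    # bare C{t} columns are censoring indicators (covariates carry an L{t}_ prefix)
    C = None
    ccols = [c for c in df.columns if re.match(r"^C\d+$", c)]
    if ccols:
        C = [df[c].to_numpy().astype(np.int8) for c in sorted(ccols, key=lambda s: int(s[1:]))]
    std = {}
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    if sidecar.exists():
        std = {
            k: tuple(v)
            for k, v in json.loads(sidecar.read_text())["standardization"].items()
        }
    return LongitudinalData(L=L, A=A, Y=df["Y"].to_numpy(), C=C, standardization=std)
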