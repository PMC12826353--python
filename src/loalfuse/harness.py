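"""Replicated simulation experiments: bias/MSE tables and selection rates.

Runs suites of MSM estimators over replicated draws from a data-generating
process, and aggregates n*|bias| and n*MSE against the Monte-Carlo truth,
along with covariate-selection and coefficient-fusion proportions for the
adaptive methods.  The registry covers sequential G-computation with main
terms, IPTW with fully stratified main-term treatment models ("full"),
IPTW with the variable-selection oracle (confounders only, optionally with
the baseline confounder coefficient correctly fused across times), and the
one- and two-step adaptive procedures (LOAL, fused LOAL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._solvers import fit_logistic
from .dgp import DGPSpec, LongitudinalData, generate, true_msm_parameters
from .estimators import MSMEstimate, compute_weights, fit_msm_gcomp, fit_msm_iptw
from .fusion import build_fusion_graph, select_by_bic
from .loal import (
    PooledDesign,
    build_pooled_design,
    fit_loal,
    pooled_probabilities,
)
from .working import fit_q_sequence, fit_working_coefficients

__all__ = [
    "ExperimentConfig",
    "ResultsTable",
    "ESTIMATORS",
    "scenario1_q_regressors",
    "oracle_estimators",
    "run_experiment",
    "marginal_confounder_coefficient",
    "oracle_fusion_rate",
]

ESTIMATORS = (
    "gcomp_main_terms",
    "iptw_full",
    "iptw_oracle_select",
    "iptw_oracle_select_fuse",
    "loal",
    "fused_loal",
)


def scenario1_q_regressors(data: LongitudinalData) -> dict[int, list[str]]:
    """Step-regression terms used in the two-time-point study design.

    The time-1 model has all main terms; the time-0 model additionally has
    the first-confounder-by-treatment interaction and a squared instrument
    term.  With a main-terms outcome process these extra terms are harmless
    (true coefficient zero); under interaction/effect-modification outcome
    processes the q models are deliberately misspecified.
    """
    from .working import default_q_terms

    terms = default_q_terms(data)
    c0 = data.names[0][0]
    extras = [f"{c0}*A0"]
    inst = [nm for nm in data.names[0] if nm != c0]
    if inst:
        extras.append(f"{inst[0]}^2")
    terms[0] = terms[0] + extras
    return terms


@dataclass
class ExperimentConfig:
    spec: DGPSpec
    sample_sizes: Sequence[int] = (200, 500, 1000)
    n_reps: int = 200
    estimators: Sequence[str] = ESTIMATORS
    q_regressors: str | Mapping[int, Sequence[str]] | None = "scenario1"
    l01: str | None = None
    base_seed: int = 0
    gamma: float = 2.5
    n_lambda: int = 30
    gamma1_grid: Sequence[float] = (2.5,)
    n_mc_truth: int = 1_000_000

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("replication count must be >= 1")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}; registry: {ESTIMATORS}")

    def resolve_l01(self) -> str:
        return self.l01 or self.spec.confounders()[0]

    def resolve_q(self, data: LongitudinalData):
        if self.q_regressors == "scenario1":
            return scenario1_q_regressors(data)
        if isinstance(self.q_regressors, str) and self.q_regressors == "main_terms":
            return None
        return self.q_regressors


@dataclass
class ResultsTable:
    """Aggregated experiment output.

    ``estimates``: per (estimator, n, component) — n*|mean bias|,
    n*mean(|bias|), n*MSE and Monte-Carlo SEs.  ``selection``: proportion of
    replications each covariate entered each treatment model.  ``fusion``:
    proportion of replications each covariate family's selected coefficients
    were all fused.  ``failures``: failed replication counts per cell.
    """

    truth: pd.Series
    estimates: pd.DataFrame
    selection: pd.DataFrame
    fusion: pd.DataFrame
    failures: pd.DataFrame


def _confounder_history(data: LongitudinalData, spec: DGPSpec) -> dict[int, list[str]]:
    conf = set(spec.confounders())
    return {
        tau: [nm for t in range(tau + 1) for nm in data.names[t] if nm in conf]
        for tau in range(data.T + 1)
    }


def _stratified_probabilities(data: LongitudinalData) -> np.ndarray:
    """Per-time logistic fits on the full main-term history (full IPTW)."""
    n = data.n
    probs = np.empty((n, data.T + 1))
    for tau in range(data.T + 1):
        cols = [np.ones(n)]
        for t in range(tau + 1):
            cols.extend(data.L[t][nm].to_numpy() for nm in data.names[t])
        cols.extend(data.A[k].astype(float) for k in range(tau))
        X = np.column_stack(cols)
        coef = fit_logistic(X, data.A[tau].astype(float))
        probs[:, tau] = 1.0 / (1.0 + np.exp(-(X @ coef)))
    return probs


def _oracle_probabilities(
    data: LongitudinalData, spec: DGPSpec, fuse: bool
) -> np.ndarray:
    design = build_pooled_design(
        data, history_spec=_confounder_history(data, spec), absorbing=False
    )
    if not fuse:
        coef = fit_logistic(design.X, design.y)
        return pooled_probabilities(design, coef)
    # shared coefficient for each baseline confounder across model times
    base_conf = [c.name for c in spec.covariates[0] if c.role == "confounder"]
    owners: list[list[int]] = []
    seen: dict[str, int] = {}
    for j, c in enumerate(design.columns):
        if c.kind == "covariate" and c.name in base_conf:
            if c.name in seen:
                owners[seen[c.name]].append(j)
                continue
            seen[c.name] = len(owners)
        owners.append([j])
    Xm = np.column_stack([design.X[:, own].sum(axis=1) for own in owners])
    cm = fit_logistic(Xm, design.y)
    coef = np.zeros(len(design.columns))
    for val, own in zip(cm, owners):
        coef[own] = val
    return pooled_probabilities(design, coef)


def oracle_estimators(
    data: LongitudinalData, truth: DGPSpec, l01: str | None = None
) -> dict[str, MSMEstimate]:
    """Variable-selection oracle IPTW, with and without correct fusion."""
    l01 = l01 or truth.confounders()[0]
    out = {}
    for name, fuse in (("iptw_oracle_select", False), ("iptw_oracle_select_fuse", True)):
        probs = _oracle_probabilities(data, truth, fuse)
        ws = compute_weights(data, probs, l01)
        out[name] = fit_msm_iptw(data, ws, l01)
    return out


def _run_one(
    data: LongitudinalData, config: ExperimentConfig, which: Sequence[str]
) -> tuple[dict[str, MSMEstimate], dict, dict]:
    """All requested estimators on one dataset; returns (mu, selection, fusion)."""
    l01 = config.resolve_l01()
    qreg = config.resolve_q(data)
    spec = config.spec
    out: dict[str, MSMEstimate] = {}
    selection: dict = {}
    fusion: dict = {}

    needs_q = {"gcomp_main_terms", "loal", "fused_loal"} & set(which)
    qs = fit_q_sequence(data, regressors=qreg) if needs_q else None

    if "gcomp_main_terms" in which:
        out["gcomp_main_terms"] = fit_msm_gcomp(qs, data, l01)
    if "iptw_full" in which:
        probs = _stratified_probabilities(data)
        out["iptw_full"] = fit_msm_iptw(data, compute_weights(data, probs, l01), l01)
    if {"iptw_oracle_select", "iptw_oracle_select_fuse"} & set(which):
        oracle = oracle_estimators(data, spec, l01)
        for k in ("iptw_oracle_select", "iptw_oracle_select_fuse"):
            if k in which:
                out[k] = oracle[k]
    if {"loal", "fused_loal"} & set(which):
        from .working import WorkingCoefficients, fit_working_beta

        beta = WorkingCoefficients(
            beta={t: fit_working_beta(qs, data, t) for t in range(data.T + 1)},
            gamma=config.gamma,
        )
        fit = fit_loal(data, beta, n_lambda=config.n_lambda)
        design = fit.design
        active_names = {(design.columns[j].tau, design.columns[j].name) for j in fit.active}
        for tau in range(design.n_times):
            for c in design.columns:
                if c.tau == tau and c.kind == "covariate":
                    selection[(tau, c.name)] = int((tau, c.name) in active_names)
        if "loal" in which:
            probs = pooled_probabilities(design, fit.alpha_refit)
            out["loal"] = fit_msm_iptw(data, compute_weights(data, probs, l01), l01)
        if "fused_loal" in which:
            graph = build_fusion_graph(design, fit.active)
            fused = select_by_bic(
                design, fit.active, graph, fit.alpha_refit,
                gamma1_grid=config.gamma1_grid,
            )
            probs = pooled_probabilities(design, fused.alpha_star)
            out["fused_loal"] = fit_msm_iptw(data, compute_weights(data, probs, l01), l01)
            # family -> all selected appearances fused into one group
            fams: dict[str, list[int]] = {}
            for j in graph.nodes:
                fams.setdefault(design.columns[j].name, []).append(j)
            gid = {}
            for i, g in enumerate(fused.groups):
                for j in g:
                    gid[j] = i
            for c in design.columns:
                if c.kind == "covariate" and c.name not in fams:
                    fusion.setdefault(c.name, 0)
            for fam, nodes in fams.items():
                fusion[fam] = int(
                    len(nodes) > 1 and len({gid[j] for j in nodes}) == 1
                )
    return out, selection, fusion


def run_experiment(config: ExperimentConfig) -> ResultsTable:
    """Replicated experiment; deterministic given the config's base seed."""
    truth = pd.Series(
        true_msm_parameters(
            config.spec, config.n_mc_truth, seed=config.base_seed,
            l01=config.resolve_l01(),
        ),
        index=["const", "L01", "cum"],
    )
    est_rows, sel_rows, fus_rows, fail_rows = [], [], [], []
    for n in config.sample_sizes:
        for r in range(config.n_reps):
            ss = np.random.SeedSequence(
                entropy=config.base_seed, spawn_key=(int(n), int(r))
            )
            seed = int(ss.generate_state(1)[0] % 2**31)
            data = generate(config.spec, n, seed)
            try:
                mus, sel, fus = _run_one(data, config, config.estimators)
            except Exception as err:  # failed replication: recorded, not fatal
                fail_rows.append({"n": n, "rep": r, "error": repr(err)})
                continue
            for name, est in mus.items():
                for comp in truth.index:
                    est_rows.append(
                        {
                            "estimator": name,
                            "n": n,
                            "component": comp,
                            "estimate": float(est.mu[comp]),
                        }
                    )
            for (tau, nm), v in sel.items():
                sel_rows.append({"n": n, "model_time": tau, "covariate": nm, "selected": v})
            for nm, v in fus.items():
                fus_rows.append({"n": n, "covariate": nm, "fused": v})

    est_df = pd.DataFrame(est_rows)
    summaries = []
    if len(est_df):
        for (name, n, comp), grp in est_df.groupby(["estimator", "n", "component"]):
            e = grp["estimate"].to_numpy()
            bias = e - truth[comp]
            sq = bias**2
            summaries.append(
                {
                    "estimator": name,
                    "n": n,
                    "component": comp,
                    "n_reps": len(e),
                    "n_abs_mean_bias": n * abs(bias.mean()),
                    "n_mean_abs_bias": n * np.abs(bias).mean(),
                    "n_mse": n * sq.mean(),
                    "mc_se_bias": n * bias.std(ddof=1) / np.sqrt(len(e))
                    if len(e) > 1
                    else np.nan,
                    "mc_se_mse": n * sq.std(ddof=1) / np.sqrt(len(e))
                    if len(e) > 1
                    else np.nan,
                }
            )
    sel_df = pd.DataFrame(sel_rows)
    sel_sum = (
        sel_df.groupby(["n", "model_time", "covariate"])["selected"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "proportion", "count": "n_reps"})
        if len(sel_rows)
        else pd.DataFrame(columns=["n", "model_time", "covariate", "proportion", "n_reps"])
    )
    fus_df = pd.DataFrame(fus_rows)
    fus_sum = (
        fus_df.groupby(["n", "covariate"])["fused"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "proportion", "count": "n_reps"})
        if len(fus_rows)
        else pd.DataFrame(columns=["n", "covariate", "proportion", "n_reps"])
    )
    for df in (sel_sum, fus_sum):
        if len(df):
            df["mc_se"] = np.sqrt(
                df["proportion"] * (1 - df["proportion"]) / df["n_reps"]
            )
    return ResultsTable(
        truth=truth,
        estimates=pd.DataFrame(summaries),
        selection=sel_sum,
        fusion=fus_sum,
        failures=pd.DataFrame(fail_rows, columns=["n", "rep", "error"]),
    )


def marginal_confounder_coefficient(
    spec: DGPSpec, n: int = 2_000_000, seed: int = 0, time: int = 0
) -> float:
    """Instrument-free marginal treatment-model coefficient of the first confounder.

    Fits an intercept-plus-confounder logistic regression of A_t on the
    (sample-standardized) first baseline confounder alone, marginalizing over
    the instrument.  Under the built-in two-time-point process this converges
    to about 1.28 for both treatment times, which is what makes the fused
    (time-shared) coefficient model correct.
    """
    data = generate(spec, n, seed)
    conf = spec.confounders()[0]
    X = np.column_stack([np.ones(n), data.covariate(conf)])
    coef = fit_logistic(X, data.A[time].astype(float))
    return float(coef[1])


def oracle_fusion_rate(
    spec: DGPSpec,
    n: int = 500,
    n_reps: int = 200,
    base_seed: int = 0,
    gamma1: float = 2.5,
) -> float:
    """Proportion of replications fusing the baseline-confounder coefficients.

    Replicates the fusion step in isolation: the pooled logistic model with
    the oracle (correctly selected) covariate set is fitted unpenalized, its
    estimates weight the adaptive fused LASSO over the baseline-confounder
    clique, lambda1 is selected by BIC, and the replication counts as fused
    when every fusion edge ends up in a single group.
    """
    fused_count = 0
    for r in range(n_reps):
        ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(int(n), int(r)))
        seed = int(ss.generate_state(1)[0] % 2**31)
        data = generate(spec, n, seed)
        design = build_pooled_design(
            data, history_spec=_confounder_history(data, spec), absorbing=False
        )
        alpha_refit = fit_logistic(design.X, design.y)
        active = [int(j) for j in design.shrink_idx]
        graph = build_fusion_graph(design, active, family="clique")
        fused = select_by_bic(
            design, active, graph, alpha_refit, gamma1_grid=(gamma1,)
        )
        fused_count += int(len(fused.fused_pairs()) == len(graph.edges))
    return fused_count / n_reps
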