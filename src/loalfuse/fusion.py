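"""Adaptive fused LASSO over the selected pooled treatment model.

After the outcome-adaptive selection step, coefficients of the same
underlying covariate appearing in several time-specific treatment models
often carry (nearly) equal values; fusing them yields a more parsimonious
pooled model.  A user-defined fusion graph says which coefficients may
fuse: baseline covariates across model times (clique or chain), and
time-updated covariates at equal lag relative to the model time.  The
penalty is ``lambda1 * sum_edges |alpha_u - alpha_v| / |diff_refit|^gamma1``
— adaptive weights from the refitted unpenalized estimates — with no
magnitude penalty, so the zero pattern of the selection step is preserved.
The pair (gamma1, lambda1) is chosen by BIC, counting one degree of freedom
per distinct coefficient value.

Numerically-fused coefficients (equal within a relative 1e-6 tolerance) are
snapped to exact equality by refitting the model with the fused columns
summed, which makes "fused" a discrete, testable property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._solvers import (
    WEIGHT_CAP,
    FusedSolution,
    fit_fused_logistic,
    fit_logistic,
    kkt_residual_fused,
    neg_loglik,
)
from .loal import PooledDesign

__all__ = [
    "FusionGraph",
    "FusedCandidate",
    "FusedFit",
    "build_fusion_graph",
    "fusion_weights",
    "fit_fused",
    "select_by_bic",
]

SNAP_RTOL = 1e-6


@dataclass
class FusionGraph:
    """Graph over selected coefficient indices that are allowed to fuse.

    Nodes are design-column indices of selected covariate columns; edges
    connect coefficients of the same covariate family: baseline covariates
    across model times, time-varying covariates at equal lag (model time
    minus measurement time).
    """

    nodes: list[int]
    edges: list[tuple[int, int]]
    family: str = "clique"

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError("self-edges are not allowed in a fusion graph")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError("edges may only connect selected coefficients")


def build_fusion_graph(
    design: PooledDesign,
    active: Sequence[int],
    family: str = "clique",
    variable_family: Mapping[str, str] | None = None,
) -> FusionGraph:
    """Construct the fusion graph over the active (selected) columns.

    ``variable_family`` maps covariate names to a shared family label for
    time-updated variables measured repeatedly under different names
    (default: each name is its own family).  A covariate selected at a
    single model time becomes an isolated node.
    """
    if family not in ("clique", "chain"):
        raise ValueError("graph family must be 'clique' or 'chain'")
    nodes = [int(j) for j in active]
    groups: dict[tuple, list[int]] = {}
    for j in nodes:
        c = design.columns[j]
        fam = variable_family.get(c.name, c.name) if variable_family else c.name
        key = ("base", fam) if c.t == 0 else ("lag", fam, c.tau - c.t)
        groups.setdefault(key, []).append(j)
    edges: list[tuple[int, int]] = []
    for key, members in groups.items():
        members = sorted(members, key=lambda j: design.columns[j].tau)
        if len(members) < 2:
            continue
        if family == "clique":
            edges.extend(combinations(members, 2))
        else:
            edges.extend(zip(members[:-1], members[1:]))
    return FusionGraph(nodes=nodes, edges=edges, family=family)


def fusion_weights(
    alpha_refit: np.ndarray, graph: FusionGraph, gamma1: float = 2.5
) -> np.ndarray:
    """Adaptive fusion weights ``|refit_u - refit_v|^(-gamma1)`` per edge."""
    if not gamma1 > 0:
        raise ValueError("gamma1 must be positive")
    w = np.empty(len(graph.edges))
    for e, (u, v) in enumerate(graph.edges):
        d = abs(alpha_refit[u] - alpha_refit[v])
        if d == 0.0:
            warnings.warn(
                f"refit coefficients for columns {u} and {v} are exactly equal; "
                f"fusion weight capped at {WEIGHT_CAP:g}",
                stacklevel=2,
            )
            w[e] = WEIGHT_CAP
        else:
            w[e] = min(d ** (-gamma1), WEIGHT_CAP)
    return w


def _snap_groups(
    coef_nodes: np.ndarray, nodes: list[int], edges: list[tuple[int, int]]
) -> list[list[int]]:
    """Union-find partition of nodes whose values agree within SNAP_RTOL."""
    parent = {j: j for j in nodes}

    def find(j):
        while parent[j] != j:
            parent[j] = parent[parent[j]]
            j = parent[j]
        return j

    val = dict(zip(nodes, coef_nodes))
    for u, v in edges:
        if abs(val[u] - val[v]) < SNAP_RTOL * (1.0 + abs(val[u])):
            parent[find(u)] = find(v)
    groups: dict[int, list[int]] = {}
    for j in nodes:
        groups.setdefault(find(j), []).append(j)
    return sorted(groups.values(), key=lambda g: min(g))


@dataclass
class FusedCandidate:
    """One point on the (gamma1, lambda1) grid, after snap-refit."""

    gamma1: float
    lam1: float
    alpha_star: np.ndarray  # full design-length coefficient vector
    groups: list[list[int]]  # partition of the penalized nodes
    loglik: float
    df: int
    bic: float
    kkt: float

    @property
    def n_distinct(self) -> int:
        return len(self.groups)


@dataclass
class FusedFit:
    """Fused-LASSO path with the BIC-selected candidate."""

    design: PooledDesign
    graph: FusionGraph
    edge_weights_by_gamma1: dict[float, np.ndarray]
    candidates: list[FusedCandidate]
    selected: int | None = None

    @property
    def best(self) -> FusedCandidate:
        if self.selected is None:
            raise ValueError("no candidate selected yet; run select_by_bic")
        return self.candidates[self.selected]

    @property
    def alpha_star(self) -> np.ndarray:
        return self.best.alpha_star

    @property
    def groups(self) -> list[list[int]]:
        return self.best.groups

    def fused_pairs(self) -> set[tuple[int, int]]:
        """Edges whose endpoints ended up in the same fusion group."""
        out = set()
        for g in self.best.groups:
            gs = set(g)
            for u, v in self.graph.edges:
                if u in gs and v in gs:
                    out.add((u, v))
        return out

    def tidy(self) -> pd.DataFrame:
        rows = []
        gid = {}
        for i, g in enumerate(self.best.groups):
            for j in g:
                gid[j] = i
        for j, c in enumerate(self.design.columns):
            if self.best.alpha_star[j] == 0.0 and j not in gid:
                continue
            rows.append(
                {
                    "model_time": c.tau,
                    "term": c.name,
                    "estimate": self.best.alpha_star[j],
                    "group": gid.get(j, -1),
                }
            )
        return pd.DataFrame(rows)

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gamma1": c.gamma1,
                    "lambda1": c.lam1,
                    "df": c.df,
                    "loglik": c.loglik,
                    "bic": c.bic,
                }
                for c in self.candidates
            ]
        )


def _restricted(design: PooledDesign, active: Sequence[int]):
    cols = np.sort(
        np.concatenate([design.unpenalized_idx, np.asarray(active, dtype=int)])
    ).astype(int)
    pos = {int(j): i for i, j in enumerate(cols)}
    return cols, pos


def _snap_refit(
    X: np.ndarray,
    y: np.ndarray,
    sol_coef: np.ndarray,
    cols: np.ndarray,
    pos: Mapping[int, int],
    nodes: list[int],
    edges: list[tuple[int, int]],
) -> tuple[np.ndarray, list[list[int]], float]:
    """Snap near-equal node values to exact equality by a summed-column refit."""
    coef_nodes = np.array([sol_coef[pos[j]] for j in nodes])
    groups = _snap_groups(coef_nodes, nodes, edges)
    # merged design: one column per fusion group, original columns elsewhere
    merged_cols: list[np.ndarray] = []
    owners: list[list[int]] = []
    node_set = set(nodes)
    for i, j in enumerate(cols):
        if int(j) not in node_set:
            merged_cols.append(X[:, i])
            owners.append([int(j)])
    for g in groups:
        merged_cols.append(np.sum([X[:, pos[j]] for j in g], axis=0))
        owners.append(list(g))
    Xm = np.column_stack(merged_cols)
    init = np.array(
        [
            np.mean([sol_coef[pos[j]] for j in own])
            for own in owners
        ]
    )
    cm = fit_logistic(Xm, y, coef_init=init)
    coef = np.zeros(X.shape[1])
    for val, own in zip(cm, owners):
        for j in own:
            coef[pos[j]] = val
    return coef, groups, -neg_loglik(Xm, y, cm)


def fit_fused(
    design: PooledDesign,
    active: Sequence[int],
    graph: FusionGraph,
    edge_weights: np.ndarray,
    lambda1_grid: Sequence[float] | None = None,
    n_lambda1: int = 20,
    gamma1: float = 2.5,
) -> list[FusedCandidate]:
    """Fused-LASSO path over lambda1 (ascending), snap-refit at each point.

    The default grid is {0} plus log-spaced values whose upper end is
    doubled until every edge fuses, so the path spans no-fusion to full
    fusion.
    """
    cols, pos = _restricted(design, active)
    X, y = design.X[:, cols], design.y
    nodes, edges = graph.nodes, graph.edges
    edges_r = [(pos[u], pos[v]) for u, v in edges]
    N = len(y)

    def one(lam1: float, init: np.ndarray | None) -> tuple[FusedCandidate, np.ndarray]:
        if lam1 == 0.0 or not edges:
            raw = fit_logistic(X, y, coef_init=init)
            sol = FusedSolution(coef=raw, dual=np.zeros(len(edges)))
        else:
            sol = fit_fused_logistic(X, y, edges_r, edge_weights, lam1, coef_init=init)
        kkt = kkt_residual_fused(X, y, sol, lam1, edges_r, edge_weights)
        coef_r, groups, ll = _snap_refit(X, y, sol.coef, cols, pos, nodes, edges)
        df = len(groups) + (len(cols) - len(nodes))
        bic = -2.0 * ll + df * np.log(N)
        full = np.zeros(len(design.columns))
        full[cols] = coef_r
        return (
            FusedCandidate(
                gamma1=gamma1,
                lam1=lam1,
                alpha_star=full,
                groups=groups,
                loglik=ll,
                df=df,
                bic=bic,
                kkt=kkt,
            ),
            sol.coef,
        )

    if lambda1_grid is None:
        if not edges:
            lambda1_grid = [0.0]
        else:
            hi = 1.0
            for _ in range(60):
                cand, _ = one(hi, None)
                if len(cand.groups) == _n_components(nodes, edges):
                    break
                hi *= 2.0
            lambda1_grid = np.concatenate([[0.0], np.geomspace(hi * 1e-5, hi, n_lambda1)])
    out: list[FusedCandidate] = []
    warm = None
    for lam1 in lambda1_grid:
        cand, warm = one(float(lam1), warm)
        out.append(cand)
    return out


def _n_components(nodes: list[int], edges: list[tuple[int, int]]) -> int:
    parent = {j: j for j in nodes}

    def find(j):
        while parent[j] != j:
            parent[j] = parent[parent[j]]
            j = parent[j]
        return j

    for u, v in edges:
        parent[find(u)] = find(v)
    return len({find(j) for j in nodes})


def select_by_bic(
    design: PooledDesign,
    active: Sequence[int],
    graph: FusionGraph,
    alpha_refit: np.ndarray,
    gamma1_grid: Sequence[float] = (2.5,),
    lambda1_grid: Sequence[float] | None = None,
    n_lambda1: int = 20,
) -> FusedFit:
    """Grid search over (gamma1, lambda1); BIC argmin, ties favor fewer df.

    Remaining ties resolve to the larger lambda1 (more smoothing).
    """
    all_cands: list[FusedCandidate] = []
    weights_by_g1: dict[float, np.ndarray] = {}
    for g1 in gamma1_grid:
        ew = fusion_weights(alpha_refit, graph, gamma1=g1)
        weights_by_g1[float(g1)] = ew
        all_cands.extend(
            fit_fused(
                design,
                active,
                graph,
                ew,
                lambda1_grid=lambda1_grid,
                n_lambda1=n_lambda1,
                gamma1=float(g1),
            )
        )
    order = sorted(
        range(len(all_cands)),
        key=lambda i: (all_cands[i].bic, all_cands[i].df, -all_cands[i].lam1),
    )
    return FusedFit(
        design=design,
        graph=graph,
        edge_weights_by_gamma1=weights_by_g1,
        candidates=all_cands,
        selected=order[0],
    )
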