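"""Piecewise structural equation models over spatial grids.

A candidate model is a DAG over the cell-table variables with the response
(species richness) as sink.  Each variable with parents gets its own SAR
error regression; the model score is the sum of the component AICc values,
so candidates sharing the same set of modelled responses are directly
comparable.  Missing edges imply conditional-independence claims that are
tested by d-separation and combined into Fisher's C; a model with no
missing edges is *saturated* and C is undefined (reported as a marker, not
zero).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sar import SarFit, fit_sar_error, nagelkerke_r2
from .spatial import SpatialWeights

logger = logging.getLogger(__name__)

__all__ = [
    "PsemSpec",
    "PsemFit",
    "DsepResult",
    "SATURATED",
    "enumerate_candidates",
    "fit_psem",
    "dsep_tests",
    "rank_and_select",
    "path_effects",
]

#: Marker reported instead of Fisher's C for saturated models.
SATURATED = "SATURATED"


@dataclass(frozen=True)
class PsemSpec:
    """A candidate structural model: a DAG with the response as sink."""

    edges: tuple[tuple[str, str], ...]
    response: str = "richness"
    name: str = ""

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"spec {self.name or self.edges} is cyclic")
        if any(u == self.response for u, _ in self.edges):
            raise ValueError(f"response {self.response!r} must have no outgoing edges")
        if self.response not in g.nodes:
            raise ValueError("spec contains no edge into the response")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def variables(self) -> list[str]:
        return sorted(self.graph().nodes)

    @property
    def endogenous(self) -> list[str]:
        """Variables with at least one parent (each gets an equation)."""
        g = self.graph()
        return sorted(v for v in g.nodes if g.in_degree(v) > 0)

    @property
    def exogenous(self) -> list[str]:
        g = self.graph()
        return sorted(v for v in g.nodes if g.in_degree(v) == 0)


@dataclass
class DsepResult:
    """One independence claim of the basis set, or the saturated marker."""

    claims: list[tuple[str, str, tuple[str, ...], float]]  # (u, v, cond set, p)
    fisher_c: float | None
    df: int
    p_value: float | None
    saturated: bool

    @property
    def marker(self) -> str | float | None:
        return SATURATED if self.saturated else self.fisher_c


@dataclass
class PsemFit:
    """A fitted candidate: one SAR fit per endogenous variable."""

    spec: PsemSpec
    equations: dict[str, SarFit]
    total_aicc: float
    total_k: int
    r2: dict[str, float]
    dsep: DsepResult | None = None
    _effects: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return next(iter(self.equations.values())).n


def enumerate_candidates(
    exogenous: list[str],
    endogenous_configs: list[list[str]],
    response: str = "richness",
    explicit: list[PsemSpec] | None = None,
) -> list[PsemSpec]:
    """Default candidate generator, or pass-through of an explicit list.

    For each endogenous configuration, every exogenous variable is assigned
    a non-empty set of targets among {response} U (endogenous set); each
    endogenous variable present receives an edge to the response, and
    endogenous variables left without parents are omitted from that spec
    (with their edge to the response).  Duplicate edge sets are removed,
    keeping first occurrence.
    """
    if explicit is not None:
        seen, out = set(), []
        for s in explicit:
            key = frozenset(s.edges)
            if key not in seen:
                seen.add(key)
                out.append(s)
        return out
    if not exogenous or not endogenous_configs:
        raise ValueError("empty candidate rules: no exogenous variables or configurations")
    seen, out = set(), []
    for endo in endogenous_configs:
        targets = [response] + list(endo)
        role_sets = [
            combo
            for r in range(1, len(targets) + 1)
            for combo in itertools.combinations(targets, r)
        ]
        for assignment in itertools.product(role_sets, repeat=len(exogenous)):
            edges = set()
            for var, roles in zip(exogenous, assignment):
                for tgt in roles:
                    edges.add((var, tgt))
            parented = {e for e in endo if any(v == e for _, v in edges)}
            for e in parented:
                edges.add((e, response))
            key = frozenset(edges)
            if key in seen:
                continue
            seen.add(key)
            out.append(PsemSpec(edges=tuple(sorted(edges)), response=response,
                                name=f"m{len(out) + 1}"))
    return out


def _design(table: pd.DataFrame, response: str, parents: list[str]):
    y = table[response].to_numpy(dtype=float)
    X = table[parents].to_numpy(dtype=float)
    return y, X


def fit_psem(
    spec: PsemSpec,
    cell_table: pd.DataFrame,
    weights: SpatialWeights,
    compute_r2: bool = True,
) -> PsemFit:
    """Fit one SAR error regression per endogenous variable of the spec.

    Rows with missing values in any spec variable are dropped (with the
    weight matrix subset and re-standardized accordingly).  Inputs are
    assumed pre-normalized so coefficients are standardized path effects.
    The model score is the sum of component AICc values.
    """
    missing = [v for v in spec.variables if v not in cell_table.columns]
    if missing:
        raise KeyError(f"spec variables absent from cell table: {missing}")
    sub = cell_table[spec.variables]
    complete = sub.notna().all(axis=1).to_numpy()
    if not complete.all():
        logger.info("dropping %d incomplete cells", int((~complete).sum()))
        sub = sub.loc[complete]
        weights = weights.subset(complete)
    g = spec.graph()
    equations: dict[str, SarFit] = {}
    r2: dict[str, float] = {}
    for endo in spec.endogenous:
        parents = sorted(g.predecessors(endo))
        y, X = _design(sub, endo, parents)
        fit = fit_sar_error(y, X, weights, response=endo, predictors=parents)
        equations[endo] = fit
        if compute_r2:
            null = fit_sar_error(
                y, np.empty((len(y), 0)), weights, response=endo, predictors=[]
            )
            r2[endo] = nagelkerke_r2(fit, null)
    total_aicc = float(sum(f.aicc for f in equations.values()))
    total_k = int(sum(f.k for f in equations.values()))
    return PsemFit(spec=spec, equations=equations, total_aicc=total_aicc,
                   total_k=total_k, r2=r2)


def fishers_c(p_values: list[float]) -> tuple[float, int, float]:
    """Combine independence-claim p-values: C = -2 sum ln p, df = 2k.

    Returns (C, df, upper-tail chi-square p).  Numerically zero p-values are
    floored at 1e-300 with a warning.
    """
    if not p_values:
        raise ValueError("no p-values to combine")
    ps = []
    for p in p_values:
        if p <= 0.0:
            logger.warning("numerically zero d-sep p-value; flooring at 1e-300")
            p = 1e-300
        ps.append(p)
    c = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df))


def _basis_set(spec: PsemSpec) -> list[tuple[str, str]]:
    """Shipley basis set: one claim per non-adjacent pair.

    Pairs of two exogenous variables are excluded — their covariance is free
    in a piecewise model, not a causal claim, and a model lacking only
    exogenous-exogenous edges is therefore saturated.  The pair is oriented
    so that the regression response is not an ancestor of the added
    variable; when neither is an ancestor of the other the topologically
    later variable is the response.
    """
    g = spec.graph()
    order = {v: i for i, v in enumerate(nx.lexicographical_topological_sort(g))}
    adj = {frozenset(e) for e in spec.edges}
    exog = set(spec.exogenous)
    claims = []
    nodes = sorted(g.nodes, key=order.get)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if frozenset((u, v)) in adj:
                continue
            if u in exog and v in exog:
                continue
            if nx.has_path(g, v, u):  # v ancestor of u: regress u on v
                claims.append((v, u))
            else:
                claims.append((u, v))
    return claims


def dsep_tests(
    spec: PsemSpec,
    cell_table: pd.DataFrame,
    weights: SpatialWeights,
) -> DsepResult:
    """Test the spec's independence claims; combine into Fisher's C.

    Each claim (u, v) is tested by adding u to the SAR regression of v on
    the union of both variables' parents and reading u's two-sided
    coefficient p-value.  C = -2 sum ln p_i with df = 2k, referred to the
    chi-square upper tail.  Saturated specs (empty basis set) return the
    SATURATED marker: C is undefined for them, never zero.
    """
    claims = _basis_set(spec)
    if not claims:
        return DsepResult(claims=[], fisher_c=None, df=0, p_value=None, saturated=True)
    sub = cell_table[spec.variables]
    complete = sub.notna().all(axis=1).to_numpy()
    if not complete.all():
        sub = sub.loc[complete]
        weights = weights.subset(complete)
    g = spec.graph()
    results = []
    for u, v in claims:
        cond = sorted((set(g.predecessors(v)) | set(g.predecessors(u))) - {u, v})
        predictors = cond + [u]
        y, X = _design(sub, v, predictors)
        fit = fit_sar_error(y, X, weights, response=v, predictors=predictors)
        results.append((u, v, tuple(cond), fit.p_value(u)))
    c, df, p = fishers_c([r[3] for r in results])
    return DsepResult(claims=results, fisher_c=c, df=df, p_value=p, saturated=False)


def rank_and_select(fits: list[PsemFit]) -> tuple[pd.DataFrame, PsemFit]:
    """Rank candidates by total AICc ascending; ties go to fewer parameters.

    Returns the ranked table (with delta AICc relative to the best and a
    tie flag) and the best fit.  Remaining ties are broken by stable input
    order and flagged.
    """
    if not fits:
        raise ValueError("no fitted candidates to rank")
    response_sets = {frozenset(f.equations) for f in fits}
    if len(response_sets) > 1:
        logger.warning(
            "candidates model different endogenous-variable sets; summed "
            "AICc values are not comparable across such candidates"
        )
    keyed = sorted(
        range(len(fits)),
        key=lambda i: (fits[i].total_aicc, fits[i].total_k, i),
    )
    best = fits[keyed[0]]
    rows = []
    for rank, i in enumerate(keyed, start=1):
        f = fits[i]
        tied = any(
            j != i and fits[j].total_aicc == f.total_aicc for j in keyed
        )
        rows.append({
            "rank": rank,
            "model": f.spec.name or f"model_{i}",
            "aicc": f.total_aicc,
            "delta_aicc": f.total_aicc - best.total_aicc,
            "k": f.total_k,
            "n_equations": len(f.equations),
            "r2": "; ".join(f"{k}={v:.3f}" for k, v in sorted(f.r2.items())),
            "tied": tied,
        })
    return pd.DataFrame(rows), best


def path_effects(fit: PsemFit) -> pd.DataFrame:
    """Direct, indirect, and total standardized effects on the response.

    direct = coefficient on the edge to the response (0 if absent);
    indirect = sum over all directed paths of length >= 2 of the product of
    coefficients along the path; total = direct + indirect.
    """
    g = fit.spec.graph()
    response = fit.spec.response
    coef = {}
    for endo, eq in fit.equations.items():
        for name in eq.predictors:
            if name != "intercept":
                coef[(name, endo)] = eq.coefficient(name)
    rows = []
    for var in fit.spec.variables:
        if var == response:
            continue
        direct = coef.get((var, response), 0.0)
        indirect = 0.0
        for path in nx.all_simple_paths(g, var, response):
            if len(path) <= 2:
                continue
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= coef[(a, b)]
            indirect += prod
        rows.append({
            "variable": var,
            "direct": direct,
            "indirect": indirect,
            "total": direct + indirect,
        })
    return pd.DataFrame(rows).set_index("variable").sort_index()
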