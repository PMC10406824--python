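"""Piecewise structural-equation modeling.

One ordinary regression per endogenous variable over a user-declared DAG;
the untested implications of the graph form the d-separation basis set
(Shipley's union convention: each non-adjacent pair, conditioned on the
parents of both members), pairs declared correlated errors are exempt, and
the claim p-values aggregate into Fisher's C = -2 sum ln p, tested against
a chi-square with 2k degrees of freedom.  A non-significant C means the
data are consistent with the hypothesized path structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from tmontanum.regression import FitResult, fit_ols

logger = logging.getLogger(__name__)

P_FLOOR = 1e-12


@dataclass
class PsemSpec:
    """A directed acyclic path model with correlated-error exemptions."""

    edges: list[tuple[str, str]]
    correlated_errors: list[tuple[str, str]] = field(default_factory=list)
    log_vars: tuple[str, ...] = ()
    extra_vars: tuple[str, ...] = ()  # isolated exogenous variables
    standardize: bool = True

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.extra_vars)
        g.add_edges_from(self.edges)
        return g

    @property
    def variables(self) -> list[str]:
        return list(self.graph().nodes)

    def endogenous(self) -> list[str]:
        g = self.graph()
        return [v for v in g.nodes if g.in_degree(v) > 0]

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        for a, b in self.correlated_errors:
            if g.has_edge(a, b) or g.has_edge(b, a):
                logger.warning(
                    "correlated-error pair (%s, %s) is an edge of the model; "
                    "it is redundant for the basis set", a, b)

    @classmethod
    def from_yaml(cls, path) -> "PsemSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            edges=[tuple(e) for e in raw.get("edges", [])],
            correlated_errors=[tuple(e) for e in raw.get("correlated_errors", [])],
            log_vars=tuple(raw.get("log_vars", ())),
            extra_vars=tuple(raw.get("extra_vars", ())),
        )


@dataclass
class IndependenceClaim:
    x: str
    y: str  # the downstream (topologically later / endogenous) member
    conditioning: frozenset[str]
    pvalue: float | None = None


@dataclass
class PsemFit:
    components: dict[str, FitResult]
    claims: list[IndependenceClaim]
    fishers_c: float
    df: int
    global_p: float

    def r2(self) -> pd.Series:
        return pd.Series({v: f.r2 for v, f in self.components.items()}, name="R2")


def basis_set(spec: PsemSpec) -> list[IndependenceClaim]:
    """Independence claims implied by the DAG.

    One claim per non-adjacent unordered pair with at least one endogenous
    member, excluding declared correlated errors; the conditioning set is
    the union of both members' parents, and the claim is oriented so that
    ``y`` is the downstream (endogenous, topologically later) variable.
    """
    spec.validate()
    g = spec.graph()
    topo = {v: i for i, v in enumerate(nx.topological_sort(g))}
    corr = {frozenset(p) for p in spec.correlated_errors}
    endo = set(spec.endogenous())
    claims = []
    nodes = sorted(g.nodes, key=topo.get)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if g.has_edge(a, b) or g.has_edge(b, a):
                continue
            if a not in endo and b not in endo:
                continue
            if frozenset((a, b)) in corr:
                continue
            # orient: y endogenous and topologically later
            x, y = a, b
            if y not in endo and x in endo:
                x, y = y, x
            cond = frozenset(set(g.predecessors(x)) | set(g.predecessors(y)))
            claims.append(IndependenceClaim(x=x, y=y, conditioning=cond - {x, y}))
    return claims


def test_claim(
    claim: IndependenceClaim,
    data: pd.DataFrame,
    standardize: bool = True,
) -> float:
    """Two-sided p for the partial effect of x on y given the conditioning set."""
    cols = [claim.x, *sorted(claim.conditioning)]
    fit = fit_ols(data[claim.y], data[cols], standardize=standardize,
                  response=claim.y)
    return float(fit.pvalues[claim.x])


def fishers_c(
    pvalues, floor: float | None = P_FLOOR
) -> tuple[float, int, float]:
    """Fisher's C = -2 sum ln p with df = 2k and its chi-square upper tail."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if (p <= 0).any():
        if floor is None:
            raise ValueError("claim p-value of zero; set a floor")
        logger.warning("flooring %d claim p-value(s) at %g", (p < floor).sum(), floor)
    if floor is not None:
        p = np.clip(p, floor, 1.0)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    c = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return c, df, float(stats.chi2.sf(c, df))


def fit_psem(spec: PsemSpec, data: pd.DataFrame) -> PsemFit:
    """Fit every component regression and evaluate the global d-separation test.

    Variables in ``spec.log_vars`` are natural-logged once, before both the
    component fits and the claim tests.  A saturated model has an empty
    basis set and returns C = 0, df = 0, p = 1 with a warning.
    """
    spec.validate()
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    work = data[spec.variables].astype(float).dropna()
    for v in spec.log_vars:
        if v in work.columns:
            work[v] = np.log(work[v])
    g = spec.graph()
    components = {}
    for v in spec.endogenous():
        parents = sorted(g.predecessors(v))
        components[v] = fit_ols(work[v], work[parents],
                                standardize=spec.standardize, response=v)
    claims = basis_set(spec)
    if not claims:
        logger.warning("saturated model: empty basis set, global test undefined")
    for claim in claims:
        claim.pvalue = test_claim(claim, work, standardize=spec.standardize)
    c, df, p = fishers_c([cl.pvalue for cl in claims])
    return PsemFit(components=components, claims=claims,
                   fishers_c=c, df=df, global_p=p)


def study_model_spec() -> PsemSpec:
    """The full path model of the field study.

    Population size is explained by eight habitat-factor CVs plus HD,
    HD by (log) habitat area, six genetic indices by (log) population
    size, expected heterozygosity additionally by HD, and trait variation
    iFD_CV by HD and expected heterozygosity.  The correlated-error list
    carries the significant non-causal residual associations the study
    exempted from the d-separation test (pairs that are themselves edges
    are redundant there and only logged).
    """
    cv_terms = ["CV_altitude", "CV_slope_exposure", "CV_LAI", "CV_soil_depth",
                "CV_pH", "CV_N", "CV_P", "CV_K"]
    edges = [(cv, "size") for cv in cv_terms]
    edges += [("HD", "size"), ("habitat_area", "HD")]
    edges += [("size", idx) for idx in ("N_A", "H_o", "H_e", "I", "F_IS", "G_ST")]
    edges += [("HD", "H_e"), ("HD", "iFD_CV"), ("H_e", "iFD_CV")]
    correlated = [
        ("N_A", "CV_altitude"),
        ("H_e", "I"),
        ("iFD_CV", "CV_slope_exposure"),
        ("H_o", "CV_slope"),
        ("F_IS", "CV_pH"),
        ("size", "HD"),
        ("I", "N_A"),
        ("F_IS", "H_o"),
        ("G_ST", "I"),
    ]
    return PsemSpec(
        edges=edges,
        correlated_errors=correlated,
        log_vars=("size", "habitat_area"),
        extra_vars=("CV_slope",),
    )


def reduced_model_spec() -> PsemSpec:
    """Summary-level variant of the study model for the packaged tables.

    The per-record habitat-factor CVs are not printed in the summary
    tables, so the CV -> size stage is omitted: size drives the genetic
    indices, habitat area drives HD, and HD plus expected heterozygosity
    drive iFD_CV.
    """
    edges = [("habitat_area", "HD")]
    edges += [("size", idx) for idx in ("N_A", "H_o", "H_e", "I", "F_IS", "G_ST")]
    edges += [("HD", "H_e"), ("HD", "iFD_CV"), ("H_e", "iFD_CV")]
    correlated = [("H_e", "I"), ("I", "N_A"), ("F_IS", "H_o"), ("G_ST", "I")]
    return PsemSpec(edges=edges, correlated_errors=correlated,
                    log_vars=("size", "habitat_area"))
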