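"""Pairwise term semantic similarity and distance.

The topology-universal measure scores a pair (x, y) by the topological
information of their most informative common ancestor:

    mu_s(x, y) = min { mu(t) : t in A(x, y) }
    S(x, y)    = -ln mu_s(x, y) / max(IC_T(x), IC_T(y))

where A(x, y) is the intersection of the self-inclusive ancestor sets of x
and y (so a parent-child pair's candidate set contains the parent itself).
The induced distance d = 1 - S is a metric up to topological synonyms:
d(x, y) = 0 exactly when x and y occupy the same topological position on a
shared path.

Comparator measures: Wang's S-value ratio and the Zhang D-value IC under
uniform-Resnik or Lin scaling.  All scores live in [0, 1]; pairs in
different namespaces (no shared ancestor) score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .ontology_graph import OntologyDAG, ancestors_self_inclusive, levels
from .topo_ic import ICTable, TopoPosition

__all__ = [
    "SharedPosition",
    "PairScore",
    "shared_position",
    "sim_universal",
    "dist_universal",
    "sim_wang",
    "sim_zhang",
    "sim_term_to_set",
    "term_measure",
]


@dataclass(frozen=True)
class SharedPosition:
    """Most informative common ancestor of a term pair.

    ``best_ancestor`` is None (and ``shared_ic`` 0) when the pair shares no
    ancestor, e.g. across ontology namespaces.
    """

    best_ancestor: object
    mu_s: TopoPosition | None
    shared_ic: float


@dataclass(frozen=True)
class PairScore:
    a: object
    b: object
    measure: str
    score: float | None


def _require_method(ic: ICTable, expected: str) -> None:
    if ic.method != expected:
        raise ValueError(f"expected a {expected!r} IC table, got {ic.method!r}")


def common_ancestors(dag: OntologyDAG, x, y) -> set:
    """Intersection of the self-inclusive ancestor sets of x and y."""
    return ancestors_self_inclusive(dag, x) & ancestors_self_inclusive(dag, y)


def shared_position(
    dag: OntologyDAG,
    mu: Mapping,
    x,
    y,
    level_map: Mapping | None = None,
) -> SharedPosition:
    """Common ancestor with the smallest topological position.

    Ties on mu are broken by the deeper (longest-path level) ancestor, then
    by lexicographic identifier; the tie-break affects only which ancestor
    is reported, never the score.
    """
    candidates = common_ancestors(dag, x, y)
    if not candidates:
        return SharedPosition(None, None, 0.0)
    if level_map is None:
        level_map = levels(dag)
    best = min(
        candidates,
        key=lambda t: (mu[t].log10(), -level_map.get(t, 0), str(t)),
    )
    return SharedPosition(best, mu[best], mu[best].ic())


def sim_universal(
    dag: OntologyDAG,
    ic: ICTable,
    x,
    y,
    level_map: Mapping | None = None,
) -> PairScore:
    """Topology-universal similarity: shared IC over the larger of the two
    term ICs.

    Root-only pairs (both ICs zero) and cross-namespace pairs score 0.
    Topological synonyms score exactly 1 because their shared position
    equals both terms' own position.
    """
    _require_method(ic, "universal")
    mu = ic.aux["mu"]
    denom = max(ic[x], ic[y])
    if denom == 0.0:
        return PairScore(x, y, "universal", 0.0)
    shared = shared_position(dag, mu, x, y, level_map=level_map)
    if shared.best_ancestor is None:
        warnings.warn(f"terms {x!r} and {y!r} share no ancestor; similarity 0")
        return PairScore(x, y, "universal", 0.0)
    score = shared.shared_ic / denom
    return PairScore(x, y, "universal", min(1.0, max(0.0, score)))


def dist_universal(dag: OntologyDAG, ic: ICTable, x, y, **kw) -> PairScore:
    """d(x, y) = 1 - S(x, y); zero exactly on topological synonyms."""
    s = sim_universal(dag, ic, x, y, **kw)
    return PairScore(x, y, "universal_distance", 1.0 - s.score)


def sim_wang(dag: OntologyDAG, ic: ICTable, x, y) -> PairScore:
    """Wang similarity: summed S-values of the common self-inclusive
    ancestors from both sides, normalized by IC_W(x) + IC_W(y)."""
    _require_method(ic, "wang")
    sx = ic.aux["svalues"][x]
    sy = ic.aux["svalues"][y]
    common = common_ancestors(dag, x, y)
    denom = ic[x] + ic[y]
    if denom == 0.0 or not common:
        return PairScore(x, y, "wang", 0.0)
    num = sum(sx[t] + sy[t] for t in common)
    return PairScore(x, y, "wang", min(1.0, num / denom))


def sim_zhang(dag: OntologyDAG, ic: ICTable, x, y, scaling: str = "lin") -> PairScore:
    """Zhang D-value similarity under ``lin`` or ``uniform_resnik`` scaling.

    lin:            max over common ancestors a of 2*IC_Z(a)/(IC_Z(x)+IC_Z(y))
    uniform_resnik: max over common ancestors a of IC_Z(a)/ln(N)
    """
    _require_method(ic, "zhang")
    common = common_ancestors(dag, x, y)
    measure = f"zhang_{scaling}"
    if not common:
        return PairScore(x, y, measure, 0.0)
    if scaling == "lin":
        denom = ic[x] + ic[y]
        if denom == 0.0:
            return PairScore(x, y, measure, 0.0)
        score = max(2.0 * ic[a] / denom for a in common)
    elif scaling == "uniform_resnik":
        uniform = ic.aux["ic_uniform"]
        score = max(uniform[a] for a in common)
    else:
        raise ValueError(f"unknown Zhang scaling {scaling!r}")
    return PairScore(x, y, measure, min(1.0, max(0.0, score)))


def term_measure(dag: OntologyDAG, ic: ICTable) -> Callable:
    """Bind an IC table to its matching pairwise measure.

    Returns ``f(x, y) -> float`` dispatching on the table's method:
    universal -> sim_universal, wang -> sim_wang, zhang -> sim_zhang(lin).
    """
    level_map = levels(dag)
    if ic.method == "universal":
        return lambda x, y: sim_universal(dag, ic, x, y, level_map=level_map).score
    if ic.method == "wang":
        return lambda x, y: sim_wang(dag, ic, x, y).score
    if ic.method == "zhang":
        return lambda x, y: sim_zhang(dag, ic, x, y).score
    raise ValueError(f"no pairwise measure for IC method {ic.method!r}")


def sim_term_to_set(
    dag: OntologyDAG,
    ic: ICTable,
    t,
    terms: Iterable,
    measure: Callable | None = None,
) -> float:
    """Best-match similarity of one term against a set: the maximum pairwise
    similarity (equivalently 1 minus the minimum distance)."""
    terms = list(terms)
    if not terms:
        raise ValueError("term set must be non-empty")
    if measure is None:
        measure = term_measure(dag, ic)
    return max(measure(t, s) for s in terms)
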