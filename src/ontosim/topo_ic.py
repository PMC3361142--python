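"""Per-term information content under four schemes.

* ``universal`` — topology-only IC.  Each term carries a topological
  position (reachability measure) mu, with mu(root) = 1 and
  mu(z) = prod over parents x of mu(x) / C(x), where C(x) is the number of
  children of x.  IC_T(z) = -ln mu(z).  Because mu decays roughly
  geometrically with depth, mu is never held as a dense float: it is kept
  as a normalized base-10 mantissa/exponent pair (alpha, beta) with
  0.1 <= alpha < 1 (alpha = 1 only for mu = 1), renormalized after every
  multiplication, and IC_T = -ln(alpha) - beta * ln(10).

* ``zhang`` / ``zhang_uniform`` — the child-path-count D value:
  D(t) = (paths from t to leaves) / (paths from the root to leaves),
  IC_Z = -ln D, and IC_Zu = IC_Z / ln N with N the number of terms under
  the term's root.

* ``wang`` — S-values propagated from each query term toward the root by
  maximization with per-relation semantic factors; IC_W is their sum.

* ``annotation`` — the classical corpus-frequency IC: annotation counts
  propagated to ancestors under the true-path rule,
  IC = -ln(freq(t) / freq(root)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .ontology_graph import (
    OntologyDAG,
    ancestors_self_inclusive,
    topological_order,
)

__all__ = [
    "TopoPosition",
    "ICTable",
    "compute_mu",
    "ic_universal",
    "zhang_ic",
    "wang_ic",
    "annotation_ic",
    "synonym_classes",
]

_LN10 = math.log(10.0)

#: Default Wang semantic contribution factors per relation.
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass(frozen=True, order=False)
class TopoPosition:
    """Normalized mantissa/exponent pair: mu = alpha * 10**beta.

    Invariants: 0.1 <= alpha < 1 (or alpha == 1 when mu == 1), beta <= 0.
    The exponent is an exact integer so arbitrarily small mu never
    underflows; only the mantissa is a double.
    """

    alpha: float
    beta: int

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"mantissa out of range: {self.alpha}")

    @staticmethod
    def _normalize(alpha: float, beta: int) -> "TopoPosition":
        if alpha <= 0.0:
            raise ValueError("topological position must be positive")
        if alpha == 1.0 and beta == 0:  # mu = 1 keeps its canonical form
            return TopoPosition(1.0, 0)
        while alpha < 0.1:
            alpha *= 10.0
            beta -= 1
        while alpha >= 1.0:
            alpha /= 10.0
            beta += 1
        return TopoPosition(alpha, beta)

    @classmethod
    def from_float(cls, x: float) -> "TopoPosition":
        if x == 1.0:
            return cls(1.0, 0)
        return cls._normalize(x, 0)

    @classmethod
    def from_string(cls, text: str) -> "TopoPosition":
        """Parse a printed ``<mantissa>e<exponent>`` string, e.g.
        ``0.1278292e-116`` or ``0.0456910e-27``.

        The printed mantissa is kept verbatim (some published tables print
        denormalized mantissas); the value alpha * 10**beta is what matters.
        """
        mant, _, expo = text.partition("e")
        if not expo:
            return cls.from_float(float(mant))
        return cls(float(mant), int(expo))

    def times(self, other: "TopoPosition") -> "TopoPosition":
        return self._normalize(self.alpha * other.alpha, self.beta + other.beta)

    def div(self, k: int) -> "TopoPosition":
        if k < 1:
            raise ValueError("divisor must be a positive integer")
        return self._normalize(self.alpha / k, self.beta)

    def log(self) -> float:
        """ln(mu), computed without materializing mu."""
        return math.log(self.alpha) + self.beta * _LN10

    def log10(self) -> float:
        return math.log10(self.alpha) + self.beta

    def ic(self) -> float:
        """-ln(mu) in nats: -ln(alpha) - beta*ln(10)."""
        # +0.0 flushes the negative zero that -ln(1.0) produces for roots
        return -math.log(self.alpha) - self.beta * _LN10 + 0.0

    def to_float(self) -> float:
        """Dense float value; underflows to 0.0 for very deep terms."""
        return self.alpha * 10.0 ** self.beta

    def __lt__(self, other: "TopoPosition") -> bool:
        # Compare on log10 so denormalized printed mantissas order correctly.
        return self.log10() < other.log10()

    def __str__(self) -> str:
        return f"{self.alpha:.7f}e{self.beta:+d}"


TopoPosition.ONE = TopoPosition(1.0, 0)


@dataclass
class ICTable:
    """Term -> information content (nats), tagged with the producing method.

    ``aux`` carries method-specific payload: the mu map for ``universal``;
    uniform IC, path counts and per-root term counts for ``zhang``; S-value
    maps and relation weights for ``wang``; propagated frequencies for
    ``annotation``.
    """

    method: str
    values: dict
    aux: dict = field(default_factory=dict)

    def __getitem__(self, term) -> float:
        try:
            return self.values[term]
        except KeyError:
            raise KeyError(f"term {term!r} missing from {self.method} IC table")

    def __contains__(self, term) -> bool:
        return term in self.values

    def get(self, term, default=None):
        return self.values.get(term, default)


# ---------------------------------------------------------------------------
# universal (topological) IC
# ---------------------------------------------------------------------------

def compute_mu(dag: OntologyDAG) -> dict:
    """Topological position of every term as a :class:`TopoPosition`.

    Parents are evaluated before children (topological order); each
    multiplication immediately renormalizes the (alpha, beta) pair, so the
    product never underflows regardless of depth.
    """
    mu: dict = {}
    for z in topological_order(dag):
        parents = dag.parents(z)
        if not parents:
            mu[z] = TopoPosition.ONE
            continue
        acc = TopoPosition.ONE
        for x in sorted(parents, key=str):  # deterministic product order
            acc = acc.times(mu[x].div(dag.n_children(x)))
        mu[z] = acc
    return mu


def ic_universal(mu: Mapping) -> ICTable:
    """IC_T(z) = -ln mu(z), evaluated in log space from (alpha, beta)."""
    values = {t: pos.ic() for t, pos in mu.items()}
    return ICTable(method="universal", values=values, aux={"mu": dict(mu)})


# ---------------------------------------------------------------------------
# Zhang D-value IC
# ---------------------------------------------------------------------------

def zhang_ic(dag: OntologyDAG) -> ICTable:
    """Child-path-count IC.

    The count of a leaf is 1 and the count of any other term is the sum of
    its direct children's counts (the number of paths from the term to the
    leaves below it).  All leaves share D = 1/count(root); D then sums up
    the hierarchy exactly like the counts, so D(t) = count(t)/count(root)
    per root and D(root) = 1.  Counts are exact integers; logs are taken at
    the end, so huge path counts cannot overflow.
    """
    order = topological_order(dag)
    counts: dict = {}
    for t in reversed(order):
        ch = dag.children(t)
        counts[t] = 1 if not ch else sum(counts[c] for c in ch)

    # Assign each term to the root(s) that reach it; in GO namespaces are
    # disjoint so exactly one root reaches any term.
    root_of: dict = {}
    for t in order:
        parents = dag.parents(t)
        root_of[t] = t if not parents else root_of[next(iter(sorted(parents, key=str)))]

    n_terms_per_root: dict = {}
    for t, r in root_of.items():
        n_terms_per_root[r] = n_terms_per_root.get(r, 0) + 1

    values: dict = {}
    uniform: dict = {}
    for t in order:
        r = root_of[t]
        ic = math.log(counts[r]) - math.log(counts[t])
        values[t] = max(ic, 0.0)
        n = n_terms_per_root[r]
        uniform[t] = values[t] / math.log(n) if n > 1 else 0.0
    return ICTable(
        method="zhang",
        values=values,
        aux={
            "ic_uniform": uniform,
            "path_counts": counts,
            "n_terms": n_terms_per_root,
            "root_of": root_of,
        },
    )


# ---------------------------------------------------------------------------
# Wang S-value IC
# ---------------------------------------------------------------------------

def _svalues(dag: OntologyDAG, z, weights: Mapping) -> dict:
    """S_z(t) over the self-inclusive ancestors of z.

    S_z(z) = 1; otherwise S_z(t) = max over children t' of t inside the
    ancestor sub-DAG of weight(t -> t') * S_z(t').  Only the sub-DAG above
    z is ever materialized.
    """
    anc = ancestors_self_inclusive(dag, z)
    order = [t for t in topological_order(dag) if t in anc]
    s: dict = {z: 1.0}
    for t in reversed(order):
        if t == z:
            continue
        best = 0.0
        for c in dag.children(t):
            if c in anc and c in s:
                w = weights.get(dag.relation(t, c), 0.0)
                best = max(best, w * s[c])
        s[t] = best
    return s


def wang_ic(dag: OntologyDAG, weights: Mapping | None = None) -> ICTable:
    """Wang semantic value: IC_W(z) = sum of S_z(t) over z's self-inclusive
    ancestors, with semantic contribution factors 0.8 (is_a) and 0.6
    (part_of) by default."""
    weights = dict(WANG_WEIGHTS if weights is None else weights)
    svalues = {z: _svalues(dag, z, weights) for z in dag.terms}
    values = {z: sum(s.values()) for z, s in svalues.items()}
    return ICTable(
        method="wang", values=values, aux={"svalues": svalues, "weights": weights}
    )


# ---------------------------------------------------------------------------
# annotation-frequency IC
# ---------------------------------------------------------------------------

def annotation_ic(dag: OntologyDAG, annotations, namespace: str | None = None) -> ICTable:
    """Corpus-frequency IC with true-path propagation.

    ``annotations`` is any object with a ``direct_terms(namespace=None)``
    method returning protein -> set of directly annotated terms (see
    :class:`ontosim.protein_similarity.AnnotationSet`).  A protein
    annotated to a term also counts for every ancestor of that term; the
    frequency is the number of distinct annotated proteins.  IC(t) =
    -ln(freq(t)/freq(root of t)); terms never reached by any annotation are
    absent from the table.
    """
    direct = annotations.direct_terms(namespace)
    if not any(direct.values()):
        raise ValueError("annotation corpus is empty")

    freq: dict = {}
    for terms in direct.values():
        closure: set = set()
        for t in terms:
            if t in dag:
                closure |= ancestors_self_inclusive(dag, t)
        for t in closure:
            freq[t] = freq.get(t, 0) + 1

    values = {}
    for t, f in freq.items():
        roots = ancestors_self_inclusive(dag, t) & dag.roots
        denom = max((freq.get(r, 0) for r in roots), default=f)
        if denom <= 0:
            continue
        values[t] = max(0.0, -math.log(f / denom))
    return ICTable(method="annotation", values=values, aux={"frequency": freq})


# ---------------------------------------------------------------------------
# synonym (topologically identical) classes
# ---------------------------------------------------------------------------

def synonym_classes(dag: OntologyDAG, mu: Mapping) -> list:
    """Partition of the terms into topological-synonym classes.

    Two terms are synonyms when their (alpha, beta) positions are exactly
    equal and one lies on a directed path to the other (the only way equal
    positions arise along a path is an unbranched single-parent/single-child
    run).  Classes are the transitive closure of this pairwise relation;
    unrelated terms form singleton classes.
    """
    by_pos: dict = {}
    for t, pos in mu.items():
        by_pos.setdefault((pos.alpha, pos.beta), []).append(t)

    parent_ptr = {t: t for t in mu}

    def find(t):
        while parent_ptr[t] != t:
            parent_ptr[t] = parent_ptr[parent_ptr[t]]
            t = parent_ptr[t]
        return t

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_ptr[ra] = rb

    for group in by_pos.values():
        if len(group) < 2:
            continue
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if nx.has_path(dag.graph, a, b) or nx.has_path(dag.graph, b, a):
                    union(a, b)

    classes: dict = {}
    for t in mu:
        classes.setdefault(find(t), set()).add(t)
    return [frozenset(c) for c in classes.values()]
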