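"""Fixtures, random generators, and brute-force oracles.

Two fixtures encode published worked examples of the topological measure:

* :func:`fixture_toy_dag` — a small integer-labelled DAG whose topological
  positions are derivable by hand (mu(1) = mu(2) = 1/2, mu(4) = 1/24, ...).
* :func:`fixture_go_subgraph` — a 12-term subgraph of the GO biological
  process ontology around DNA-damage response (14 parent-child links).
  Its absolute topological positions depend on the full GO above the
  subgraph, which the source table prints but whose upstream context is
  not recoverable; the fixture therefore injects the printed mu values,
  Zhang IC values and levels, and carries the printed similarity scores as
  expected values for the similarity layer.

The random generators produce seeded single-root DAGs and GAF-style
annotation corpora so every operation is testable without downloads.  The
oracles recompute quantities by the most literal route available (exact
rationals, explicit transitive closure, path enumeration) and exist only
to check the production code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .ontology_graph import (
    OntologyDAG,
    build_dag,
    read_edge_list,
    topological_order,
)
from .protein_similarity import AnnotationSet
from .topo_ic import ICTable, TopoPosition

__all__ = [
    "FixtureBundle",
    "SimConfig",
    "fixture_toy_dag",
    "fixture_go_subgraph",
    "generate_random_dag",
    "generate_annotations",
    "oracle_mu_exact",
    "mu_log_discrepancy",
    "oracle_ancestors",
    "oracle_levels",
    "oracle_leaf_path_counts",
]


@dataclass
class FixtureBundle:
    """A fixture DAG plus any injected values and the expected results.

    ``expected`` rows are dicts with keys ``quantity`` (e.g. ``mu``,
    ``ic_universal``, ``sim_universal``, ``sim_zhang_lin``), ``key`` (a term
    or ordered term pair), ``value`` and ``source`` (which published table
    or walkthrough the number was printed in).
    """

    dag: OntologyDAG
    injected_mu: dict | None = None
    injected_ic: dict = field(default_factory=dict)
    injected_levels: dict | None = None
    expected: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

# Core of the hand-worked integer DAG: the walkthrough fixes 0 as the root
# with children 1 and 2, 1 with children {3, 4}, and 2 with three children
# {4, 5, +one more}; node 6 stands in for the third, otherwise unspecified,
# child of 2.
_TOY_EDGES_TSV = """\
# parent	child	relation
0	1	is_a
0	2	is_a
1	3	is_a
1	4	is_a
2	4	is_a
2	5	is_a
2	6	is_a
"""

_TOY_EXPECTED = [
    ("mu", "1", 0.5), ("mu", "2", 0.5), ("mu", "3", 0.25),
    ("mu", "4", 1.0 / 24.0), ("mu", "5", 1.0 / 6.0),
    ("ic_universal", "0", 0.0),
    ("ic_universal", "1", 0.69315), ("ic_universal", "2", 0.69315),
    # The walkthrough prints 1.38639 for node 3; -ln(1/4) = 1.38629 and the
    # printed value is a fifth-decimal slip, so the exact value is expected.
    ("ic_universal", "3", math.log(4.0)),
    ("ic_universal", "4", 3.17806), ("ic_universal", "5", 1.79176),
]


def fixture_toy_dag() -> FixtureBundle:
    """Hand-derivable integer DAG with its walkthrough mu/IC values."""
    dag = read_edge_list(_TOY_EDGES_TSV)
    expected = [
        {"quantity": q, "key": k, "value": v, "source": "worked-example walkthrough"}
        for q, k, v in _TOY_EXPECTED
    ]
    return FixtureBundle(dag=dag, expected=expected)


# Per-term characteristics of the GO BP subgraph: printed level, topological
# position (verbatim mantissa/exponent string), topological IC, Zhang IC and
# uniform Zhang IC.
_SUBGRAPH_TERMS = [
    # term,          level, mu string,        IC_T,         IC_Z,     IC_Zu
    ("GO:0042770", 6, "0.0456910e-27", 6.525565e01, 10.11006, 0.71747),
    ("GO:0042772", 7, "0.1142274e-28", 6.664195e01, 12.30729, 0.87340),
    ("GO:0030330", 7, "0.1142274e-28", 6.664195e01, 11.20867, 0.79544),
    ("GO:0000077", 7, "0.0171747e-34", 8.235221e01, 10.92099, 0.77502),
    ("GO:0008630", 10, "0.0335723e-86", 2.014164e02, 12.30729, 0.87340),
    ("GO:0006978", 8, "0.0434930e-57", 1.343825e02, 12.30729, 0.87340),
    ("GO:0006977", 9, "0.0419985e-79", 1.850743e02, 12.30729, 0.87340),
    ("GO:0042771", 11, "0.1278292e-116", 2.691569e02, 12.30729, 0.87340),
    ("GO:0031571", 8, "0.1103023e-50", 1.173338e02, 12.30729, 0.87340),
    ("GO:0031572", 8, "0.0735349e-50", 1.177393e02, 12.30729, 0.87340),
    ("GO:0031573", 8, "0.4293676e-36", 8.373851e01, 12.30729, 0.87340),
    ("GO:0031574", 8, "0.2206046e-50", 1.166406e02, 12.30729, 0.87340),
]

# The 14 parent-child links of the subgraph with the printed similarity
# scores: topological (S), Wang (S_W), uniform-Resnik Zhang (S_ZuR) and
# Lin-scaled Zhang (S_ZL).
_SUBGRAPH_PAIRS = [
    # parent,        child,        S_GO,    S_W,   S_ZuR,   S_ZL
    ("GO:0042770", "GO:0042772", 0.97920, 0.940, 0.71747, 0.90199),
    ("GO:0042770", "GO:0030330", 0.97920, 0.940, 0.71747, 0.94847),
    ("GO:0042770", "GO:0008630", 0.32398, 0.704, 0.71747, 0.90199),
    ("GO:0042770", "GO:0000077", 0.79240, 0.802, 0.71747, 0.96144),
    ("GO:0042772", "GO:0006978", 0.49591, 0.882, 0.87340, 1.00000),
    ("GO:0030330", "GO:0006978", 0.49591, 0.889, 0.79544, 0.95328),
    ("GO:0030330", "GO:0006977", 0.36008, 0.615, 0.79544, 0.95328),
    ("GO:0030330", "GO:0042771", 0.24760, 0.696, 0.79544, 0.95328),
    ("GO:0008630", "GO:0042771", 0.74832, 0.931, 0.87340, 1.00000),
    ("GO:0000077", "GO:0031571", 0.70186, 0.830, 0.77502, 0.94032),
    ("GO:0000077", "GO:0031572", 0.69945, 0.850, 0.77502, 0.94032),
    ("GO:0000077", "GO:0031573", 0.98344, 0.948, 0.77502, 0.94032),
    ("GO:0000077", "GO:0031574", 0.70603, 0.870, 0.77502, 0.94032),
    ("GO:0031571", "GO:0006977", 0.63398, 0.774, 0.87340, 1.00000),
]


def fixture_go_subgraph() -> FixtureBundle:
    """DNA-damage-response BP subgraph with injected printed values.

    The DAG's edges are exactly the 14 published parent-child pairs; the
    bundle injects the printed mu strings (as exact mantissa/exponent
    pairs), a ``universal`` IC table derived from them, and a ``zhang`` IC
    table from the printed IC_Z / IC_Zu columns.  Expected rows carry the
    published per-term IC values and per-pair similarity scores.
    """
    edges = [(p, c, "is_a") for p, c, *_ in _SUBGRAPH_PAIRS]
    namespaces = {t: "BP" for t, *_ in _SUBGRAPH_TERMS}
    dag = build_dag(edges, namespaces=namespaces)

    mu = {t: TopoPosition.from_string(s) for t, _lvl, s, *_ in _SUBGRAPH_TERMS}
    ic_universal_tbl = ICTable(
        method="universal",
        values={t: pos.ic() for t, pos in mu.items()},
        aux={"mu": mu},
    )
    ic_zhang_tbl = ICTable(
        method="zhang",
        values={t: icz for t, _l, _s, _ict, icz, _iczu in _SUBGRAPH_TERMS},
        aux={"ic_uniform": {t: iczu for t, _l, _s, _ict, _icz, iczu in _SUBGRAPH_TERMS}},
    )
    levels = {t: lvl for t, lvl, *_ in _SUBGRAPH_TERMS}

    expected = []
    for t, _lvl, _s, ict, _icz, _iczu in _SUBGRAPH_TERMS:
        expected.append(
            {"quantity": "ic_universal", "key": t, "value": ict,
             "source": "per-term characteristics table"}
        )
    for parent, child, s_go, s_w, s_zur, s_zl in _SUBGRAPH_PAIRS:
        pair = (parent, child)
        src = "pairwise similarity table"
        expected.append({"quantity": "sim_universal", "key": pair, "value": s_go, "source": src})
        expected.append({"quantity": "sim_wang", "key": pair, "value": s_w, "source": src})
        expected.append({"quantity": "sim_zhang_uniform_resnik", "key": pair, "value": s_zur, "source": src})
        expected.append({"quantity": "sim_zhang_lin", "key": pair, "value": s_zl, "source": src})

    return FixtureBundle(
        dag=dag,
        injected_mu=mu,
        injected_ic={"universal": ic_universal_tbl, "zhang": ic_zhang_tbl},
        injected_levels=levels,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Knobs for the random DAG / annotation generators.

    The same config (including seed) always yields identical output.
    """

    n_terms: int = 50
    max_parents: int = 3
    extra_parent_prob: float = 0.25
    part_of_prob: float = 0.15
    n_proteins: int = 20
    mean_annotations: float = 3.0
    depth_bias: float = 1.0
    evidence_weights: tuple = (("EXP", 0.4), ("IDA", 0.3), ("IEA", 0.2), ("ISS", 0.1))
    seed: int = 0

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def generate_random_dag(config: SimConfig) -> OntologyDAG:
    """Seeded single-root random DAG.

    Node ``T000`` is the root; the first three non-root nodes form a chain
    so any DAG with >= 4 terms spans at least three levels, and every later
    node attaches to 1..max_parents earlier nodes with attachment weight
    growing with node index (which deepens the graph rather than flattening
    it under the root).
    """
    if config.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if config.max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(config.seed)
    names = [f"T{i:03d}" for i in range(config.n_terms)]
    if config.n_terms == 1:
        return build_dag([], extra_terms=names)
    edges = []
    for i in range(1, config.n_terms):
        if i <= 3:
            parent_idx = [i - 1]
        else:
            k = 1 + rng.binomial(config.max_parents - 1, config.extra_parent_prob)
            k = min(k, i)
            weights = np.arange(1, i + 1, dtype=float) ** 2
            weights /= weights.sum()
            parent_idx = rng.choice(i, size=k, replace=False, p=weights)
        for j in parent_idx:
            rel = "part_of" if rng.random() < config.part_of_prob else "is_a"
            edges.append((names[int(j)], names[i], rel))
    return build_dag(edges)


def generate_annotations(dag: OntologyDAG, config: SimConfig) -> AnnotationSet:
    """Seeded GOA-style corpus of direct annotations.

    Each protein draws 1 + Poisson(mean_annotations - 1) direct terms with
    probability biased toward deeper terms ((level+1)^depth_bias), matching
    the tendency of curated annotations to sit below the top of the
    ontology; evidence codes are sampled from ``evidence_weights``.
    """
    rng = np.random.default_rng(config.seed + 1)
    order = topological_order(dag)
    level: dict = {}
    for t in order:
        preds = dag.parents(t)
        level[t] = 0 if not preds else 1 + max(level[p] for p in preds)
    terms = sorted(dag.terms, key=str)
    weights = np.array([(level[t] + 1.0) ** config.depth_bias for t in terms])
    weights /= weights.sum()
    codes = [c for c, _w in config.evidence_weights]
    code_w = np.array([w for _c, w in config.evidence_weights], dtype=float)
    code_w /= code_w.sum()

    annot = AnnotationSet(dag=dag)
    for p in range(config.n_proteins):
        protein = f"P{p:04d}"
        n = 1 + rng.poisson(max(config.mean_annotations - 1.0, 0.0))
        n = min(n, len(terms))
        chosen = rng.choice(len(terms), size=n, replace=False, p=weights)
        for idx in chosen:
            code = codes[int(rng.choice(len(codes), p=code_w))]
            annot.add(protein, terms[int(idx)], evidence=code, source="synthetic")
    return annot


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_mu_exact(dag: OntologyDAG) -> dict:
    """Exact rational topological positions (arbitrary precision).

    Evaluates the defining recursion with :class:`fractions.Fraction`
    arithmetic; intended for DAGs up to about a thousand terms.
    """
    mu: dict = {}
    for z in topological_order(dag):
        parents = dag.parents(z)
        if not parents:
            mu[z] = Fraction(1)
            continue
        acc = Fraction(1)
        for x in parents:
            acc *= mu[x] / dag.n_children(x)
        mu[z] = acc
    return mu


def _log_fraction(f: Fraction) -> float:
    return math.log(f.numerator) - math.log(f.denominator)


def mu_log_discrepancy(dag: OntologyDAG, mu_fast: dict) -> float:
    """max over terms of |ln mu_fast - ln mu_exact| / max(1, |ln mu_exact|)."""
    exact = oracle_mu_exact(dag)
    worst = 0.0
    for t, frac in exact.items():
        log_exact = _log_fraction(frac)
        err = abs(mu_fast[t].log() - log_exact) / max(1.0, abs(log_exact))
        worst = max(worst, err)
    return worst


def oracle_ancestors(dag: OntologyDAG, term) -> set:
    """Self-inclusive ancestors by fixed-point parent expansion."""
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown |= dag.parents(t)
        if grown == out:
            return out
        out = grown


def oracle_levels(dag: OntologyDAG) -> dict:
    """Longest-path levels by exhaustive upward path enumeration
    (exponential; only for tiny DAGs)."""

    def longest(t) -> int:
        parents = dag.parents(t)
        if not parents:
            return 0
        return 1 + max(longest(p) for p in parents)

    return {t: longest(t) for t in dag.terms}


def oracle_leaf_path_counts(dag: OntologyDAG, term) -> int:
    """Number of distinct directed paths from ``term`` down to any leaf,
    by explicit recursion."""
    children = dag.children(term)
    if not children:
        return 1
    return sum(oracle_leaf_path_counts(dag, c) for c in children)
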