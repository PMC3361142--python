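"""Protein-level functional similarity from GO annotations.

Two families of measures are provided:

* pairwise combination of term-level similarity scores over the DIRECT
  annotation sets — best-match average (BMA), plain average, and maximum;
* set-wise IC-weighted overlap of the ancestor-closed annotation sets —
  SimGIC (IC-weighted Jaccard), SimUIC (the same Jaccard form driven by
  the topological IC table), SimDIC (Dice denominator), SimUIX (max
  denominator) and SimUI (unweighted Jaccard).

Direct sets feed the pairwise family because closing them under the
true-path rule degenerates set overlap: two proteins annotated with
consecutive terms on one path then share all but one term and any
set-overlap score is forced toward 1 regardless of how informative the
terms are.  The Czekanowski-Dice measure on direct sets is included to
expose exactly that pathology.

Empty annotation sets yield ``None`` (an undefined-score sentinel) rather
than 0, so unannotated proteins can be excluded from downstream statistics
instead of diluting them.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .ontology_graph import OntologyDAG, ancestors_self_inclusive
from .term_similarity import ICTable, PairScore, term_measure

__all__ = [
    "EvidenceFilter",
    "AnnotationSet",
    "parse_gaf",
    "write_gaf",
    "czekanowski_dice",
    "funsim_pairwise",
    "funsim_setwise",
    "funsim_matrix",
]

_ASPECT_TO_NAMESPACE = {"P": "BP", "F": "MF", "C": "CC"}
_NAMESPACE_TO_ASPECT = {v: k for k, v in _ASPECT_TO_NAMESPACE.items()}

#: Set-wise variants: ``name -> denominator kind``.
SETWISE_VARIANTS = {
    "simgic": "union",
    "simuic": "union",
    "simdic": "mean",
    "simuix": "max",
    "simui": "count",
}


@dataclass(frozen=True)
class EvidenceFilter:
    """Keep or drop annotations by GO evidence code.

    ``exclude`` mode drops the listed codes (the usual "no IEA" or
    "no IEA/ISS" configurations); ``include_only`` keeps nothing else.
    """

    codes: frozenset = frozenset()
    mode: str = "exclude"

    def __post_init__(self):
        if self.mode not in ("exclude", "include_only"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def admits(self, evidence: str) -> bool:
        if self.mode == "exclude":
            return evidence not in self.codes
        return evidence in self.codes

    @classmethod
    def excluding(cls, *codes: str) -> "EvidenceFilter":
        return cls(codes=frozenset(codes), mode="exclude")


@dataclass
class AnnotationSet:
    """protein -> namespace -> set of (term, evidence, source) triples,
    bound to the ontology the terms live in."""

    dag: OntologyDAG
    entries: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)

    def add(self, protein: str, term, evidence: str = "EXP",
            source: str = "ontosim") -> None:
        if term not in self.dag:
            raise KeyError(f"term {term!r} not in the bound ontology")
        ns = self.dag.namespace(term)
        self.entries.setdefault(protein, {}).setdefault(ns, set()).add(
            (term, evidence, source)
        )

    def proteins(self, namespace: str | None = None) -> list:
        if namespace is None:
            return sorted(self.entries)
        return sorted(p for p, by_ns in self.entries.items() if by_ns.get(namespace))

    def terms(self, protein: str, namespace: str | None = None,
              evidence_filter: EvidenceFilter | None = None) -> set:
        """Direct term identifiers of one protein, optionally restricted to
        one namespace and filtered by evidence code."""
        by_ns = self.entries.get(protein, {})
        spaces = [namespace] if namespace is not None else list(by_ns)
        out: set = set()
        for ns in spaces:
            for term, evidence, _src in by_ns.get(ns, ()):
                if evidence_filter is None or evidence_filter.admits(evidence):
                    out.add(term)
        return out

    def direct_terms(self, namespace: str | None = None) -> dict:
        """protein -> set of direct terms (all evidence codes)."""
        return {p: self.terms(p, namespace) for p in self.entries}

    def closure(self, protein: str, namespace: str | None = None) -> set:
        """Self-inclusive ancestor closure of the protein's direct terms
        (the true-path rule)."""
        out: set = set()
        for t in self.terms(protein, namespace):
            out |= ancestors_self_inclusive(self.dag, t)
        return out


def parse_gaf(
    stream,
    dag: OntologyDAG,
    evidence_filter: EvidenceFilter | None = None,
) -> AnnotationSet:
    """Parse GAF 2.x association lines into an :class:`AnnotationSet`.

    Rows with a NOT qualifier are dropped (they assert the absence of a
    function); rows whose term is unknown to the bound ontology, whose
    evidence code is filtered out, or which are malformed are skipped and
    counted in ``counters``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    annot = AnnotationSet(dag=dag)
    counters = {"kept": 0, "not_qualifier": 0, "filtered_evidence": 0,
                "unknown_term": 0, "malformed": 0}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            counters["malformed"] += 1
            warnings.warn(f"malformed GAF row skipped: {line[:60]!r}")
            continue
        _db, obj_id, _symbol, qualifier, go_id, _ref, evidence, _with, aspect = cols[:9]
        if "NOT" in qualifier.split("|"):
            counters["not_qualifier"] += 1
            continue
        if evidence_filter is not None and not evidence_filter.admits(evidence):
            counters["filtered_evidence"] += 1
            continue
        if go_id not in dag:
            counters["unknown_term"] += 1
            continue
        ns = dag.namespace(go_id)
        expected = _ASPECT_TO_NAMESPACE.get(aspect)
        if expected is not None and expected != ns and ns != "other":
            warnings.warn(
                f"aspect {aspect!r} disagrees with ontology namespace of {go_id}"
            )
        annot.entries.setdefault(obj_id, {}).setdefault(ns, set()).add(
            (go_id, evidence, _db or "GAF")
        )
        counters["kept"] += 1
    annot.counters = counters
    return annot


def write_gaf(annot: AnnotationSet, stream) -> None:
    """Serialize to GAF 2.2 (enough columns to round-trip through
    :func:`parse_gaf`)."""
    stream.write("!gaf-version: 2.2\n")
    for protein in sorted(annot.entries):
        for ns in sorted(annot.entries[protein]):
            aspect = _NAMESPACE_TO_ASPECT.get(ns, "P")
            for term, evidence, source in sorted(annot.entries[protein][ns]):
                cols = [
                    source, protein, protein, "involved_in", str(term),
                    "ONTOSIM:0000001", evidence, "", aspect, "", "",
                    "protein", "taxon:0000", "20120101", source, "", "",
                ]
                stream.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# similarity measures
# ---------------------------------------------------------------------------

def czekanowski_dice(
    annot: AnnotationSet, p1: str, p2: str, namespace: str | None = None
) -> float | None:
    """2|A n B| / (|A u B| + |A n B|) on DIRECT term sets (no propagation).

    Returns None when either protein has no direct terms in scope.
    """
    a = annot.terms(p1, namespace)
    b = annot.terms(p2, namespace)
    if not a or not b:
        return None
    inter = len(a & b)
    return 2.0 * inter / (len(a | b) + inter)


def funsim_pairwise(
    dag: OntologyDAG,
    ic: ICTable,
    annot: AnnotationSet,
    p1: str,
    p2: str,
    namespace: str | None = None,
    combine: str = "bma",
    measure: Callable | None = None,
) -> PairScore:
    """Combine term-level similarities over direct annotation sets.

    bma: mean of each term's best match into the other set, averaged over
    the two directions; avg: mean over all cross pairs; max: best cross
    pair.  Empty sets give a None-score sentinel.
    """
    name = f"{ic.method}_{combine}"
    a = sorted(annot.terms(p1, namespace), key=str)
    b = sorted(annot.terms(p2, namespace), key=str)
    if not a or not b:
        return PairScore(p1, p2, name, None)
    if measure is None:
        measure = term_measure(dag, ic)
    grid = [[measure(s, t) for t in b] for s in a]
    if combine == "bma":
        row = sum(max(r) for r in grid) / len(a)
        col = sum(max(grid[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
        score = 0.5 * (row + col)
    elif combine == "avg":
        score = sum(sum(r) for r in grid) / (len(a) * len(b))
    elif combine == "max":
        score = max(max(r) for r in grid)
    else:
        raise ValueError(f"unknown combination strategy {combine!r}")
    return PairScore(p1, p2, name, min(1.0, max(0.0, score)))


def _ic_sum(ic: ICTable, terms: Iterable) -> float:
    # Roots (and any term missing from an annotation table) carry zero IC.
    return sum(ic.get(t, 0.0) for t in terms)


def funsim_setwise(
    dag: OntologyDAG,
    ic: ICTable,
    annot: AnnotationSet,
    p1: str,
    p2: str,
    namespace: str | None = None,
    variant: str = "simgic",
) -> PairScore:
    """IC-weighted overlap of ancestor-closed annotation sets.

    simgic / simuic: sum IC(A n B) / sum IC(A u B)   (weighted Jaccard)
    simdic:          2 sum IC(A n B) / (sum IC(A) + sum IC(B))
    simuix:          sum IC(A n B) / max(sum IC(A), sum IC(B))
    simui:           |A n B| / |A u B|               (unweighted)

    Root terms stay in the closures with IC 0, so they never affect the
    weighted sums but do enter SimUI's cardinalities.
    """
    if variant not in SETWISE_VARIANTS:
        raise ValueError(f"unknown set-wise variant {variant!r}")
    a = annot.closure(p1, namespace)
    b = annot.closure(p2, namespace)
    if not a or not b:
        return PairScore(p1, p2, variant, None)
    inter, union = a & b, a | b
    if variant == "simui":
        score = len(inter) / len(union)
    else:
        num = _ic_sum(ic, inter)
        kind = SETWISE_VARIANTS[variant]
        if kind == "union":
            denom = _ic_sum(ic, union)
        elif kind == "mean":
            num, denom = 2.0 * num, _ic_sum(ic, a) + _ic_sum(ic, b)
        else:  # max
            denom = max(_ic_sum(ic, a), _ic_sum(ic, b))
        score = 1.0 if denom == 0.0 and a == b else (num / denom if denom else 0.0)
    return PairScore(p1, p2, variant, min(1.0, max(0.0, score)))


def funsim_matrix(
    dag: OntologyDAG,
    ic: ICTable,
    annot: AnnotationSet,
    pairs: Sequence[tuple],
    namespace: str | None = None,
    variant: str = "bma",
) -> list:
    """Score a list of protein pairs under one configuration.

    ``variant`` is a pairwise combination strategy (bma/avg/max, using the
    IC table's matching term measure) or a set-wise variant name.  Unknown
    proteins yield a sentinel row; the run continues.
    """
    pairwise = variant in ("bma", "avg", "max")
    measure = term_measure(dag, ic) if pairwise else None
    out = []
    for p1, p2 in pairs:
        if p1 not in annot.entries or p2 not in annot.entries:
            out.append(PairScore(p1, p2, variant, None))
            continue
        if pairwise:
            out.append(
                funsim_pairwise(dag, ic, annot, p1, p2, namespace,
                                combine=variant, measure=measure)
            )
        else:
            out.append(funsim_setwise(dag, ic, annot, p1, p2, namespace, variant))
    return out
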