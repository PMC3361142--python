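import io
import itertools

import pytest

from ontosim.ontology_graph import build_dag
from ontosim.protein_similarity import (
    AnnotationSet,
    EvidenceFilter,
    czekanowski_dice,
    funsim_matrix,
    funsim_pairwise,
    funsim_setwise,
    parse_gaf,
    write_gaf,
)
from ontosim.synthetic_data import SimConfig, generate_annotations, generate_random_dag
from ontosim.term_similarity import sim_universal, term_measure
from ontosim.topo_ic import compute_mu, ic_universal

GAF_TWO_ROWS = """\
!gaf-version: 2.2
UniProtKB\tP1\tP1\tinvolved_in\tGO:A\tREF\tIDA\t\tP\t\t\tprotein\ttaxon:9606\t20120101\tSRC
UniProtKB\tP1\tP1\tinvolved_in\tGO:B\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20120101\tSRC
UniProtKB\tP2\tP2\tNOT|involved_in\tGO:A\tREF\tIDA\t\tP\t\t\tprotein\ttaxon:9606\t20120101\tSRC
UniProtKB\tP3\tP3\tinvolved_in\tGO:MISSING\tREF\tIDA\t\tP\t\t\tprotein\ttaxon:9606\t20120101\tSRC
"""


@pytest.fixture()
def tiny_dag():
    return build_dag(
        [("GO:R", "GO:A"), ("GO:R", "GO:B"), ("GO:A", "GO:C"), ("GO:A", "GO:D")],
        namespaces={t: "BP" for t in ("GO:R", "GO:A", "GO:B", "GO:C", "GO:D")},
    )


class TestParseGaf:
    def test_evidence_filter_drops_iea(self, tiny_dag):
        annot = parse_gaf(GAF_TWO_ROWS, tiny_dag,
                          evidence_filter=EvidenceFilter.excluding("IEA"))
        assert annot.terms("P1", "BP") == {"GO:A"}
        assert annot.counters["filtered_evidence"] == 1

    def test_not_qualifier_dropped(self, tiny_dag):
        annot = parse_gaf(GAF_TWO_ROWS, tiny_dag)
        assert "P2" not in annot.entries
        assert annot.counters["not_qualifier"] == 1

    def test_unknown_term_counted(self, tiny_dag):
        annot = parse_gaf(GAF_TWO_ROWS, tiny_dag)
        assert annot.counters["unknown_term"] == 1
        assert "P3" not in annot.entries

    def test_synthetic_corpus_roundtrips(self):
        cfg = SimConfig(n_terms=30, n_proteins=10, seed=21)
        dag = generate_random_dag(cfg)
        annot = generate_annotations(dag, cfg)
        buf = io.StringIO()
        write_gaf(annot, buf)
        again = parse_gaf(buf.getvalue(), dag)
        for p in annot.proteins():
            assert again.terms(p) == annot.terms(p)


class TestCzekanowskiDice:
    def _annot(self, dag, sets):
        annot = AnnotationSet(dag=dag)
        for p, terms in sets.items():
            for t in terms:
                annot.add(p, t)
        return annot

    def test_identical_sets_score_one(self, tiny_dag):
        annot = self._annot(tiny_dag, {"p": ["GO:C", "GO:D"], "q": ["GO:C", "GO:D"]})
        assert czekanowski_dice(annot, "p", "q", "BP") == 1.0

    def test_disjoint_sets_score_zero(self, tiny_dag):
        annot = self._annot(tiny_dag, {"p": ["GO:C"], "q": ["GO:B"]})
        assert czekanowski_dice(annot, "p", "q", "BP") == 0.0

    def test_partial_overlap_hand_value(self, tiny_dag):
        annot = self._annot(tiny_dag, {"p": ["GO:A", "GO:B"], "q": ["GO:B", "GO:C"]})
        # 2*1 / (3 + 1)
        assert czekanowski_dice(annot, "p", "q", "BP") == pytest.approx(0.5)

    def test_empty_side_is_undefined(self, tiny_dag):
        annot = self._annot(tiny_dag, {"p": ["GO:A"]})
        assert czekanowski_dice(annot, "p", "missing", "BP") is None

    def test_closure_pathology_on_a_chain(self):
        # Proteins annotated with consecutive terms on one branching chain:
        # ancestor-closed set overlap is forced toward 1 even though the
        # term-level similarity is well below it.
        edges = []
        chain = ["r", "a", "b", "c", "d"]
        for i, (p, c) in enumerate(zip(chain, chain[1:])):
            edges.append((p, c))
            edges.append((p, f"side{i}"))
        dag = build_dag(edges)
        annot = self._annot(dag, {"p1": ["c"], "p2": ["d"]})
        clo1, clo2 = annot.closure("p1"), annot.closure("p2")
        inter, union = len(clo1 & clo2), len(clo1 | clo2)
        closed_cd = 2 * inter / (union + inter)
        ic = ic_universal(compute_mu(dag))
        bma = funsim_pairwise(dag, ic, annot, "p1", "p2").score
        # mu halves per step: sim(c, d) = ln 8 / ln 16 = 0.75
        assert bma == pytest.approx(0.75)
        assert closed_cd > 0.85 > bma


class TestFunsimPairwise:
    def _setup(self, seed=5):
        cfg = SimConfig(n_terms=40, n_proteins=12, mean_annotations=3.0, seed=seed)
        dag = generate_random_dag(cfg)
        annot = generate_annotations(dag, cfg)
        ic = ic_universal(compute_mu(dag))
        return dag, annot, ic

    def test_identical_annotation_sets_score_one(self, tiny_dag):
        annot = AnnotationSet(dag=tiny_dag)
        for p in ("p", "q"):
            annot.add(p, "GO:C")
            annot.add(p, "GO:B")
        for combine in ("bma", "avg", "max"):
            ic = ic_universal(compute_mu(tiny_dag))
            score = funsim_pairwise(tiny_dag, ic, annot, "p", "q",
                                    combine=combine).score
            if combine == "avg":
                assert 0.0 < score <= 1.0  # avg mixes cross terms
            else:
                assert score == pytest.approx(1.0)

    def test_unrelated_annotations_score_zero(self):
        dag = build_dag([("r1", "a"), ("r1", "a2"), ("r2", "b"), ("r2", "b2")])
        annot = AnnotationSet(dag=dag)
        annot.add("p", "a")
        annot.add("q", "b")
        ic = ic_universal(compute_mu(dag))
        with pytest.warns(UserWarning):
            assert funsim_pairwise(dag, ic, annot, "p", "q").score == 0.0

    def test_empty_set_gives_sentinel(self, tiny_dag):
        annot = AnnotationSet(dag=tiny_dag)
        annot.add("p", "GO:C")
        ic = ic_universal(compute_mu(tiny_dag))
        assert funsim_pairwise(tiny_dag, ic, annot, "p", "ghost").score is None

    def test_bma_equals_bruteforce_double_loop(self):
        dag, annot, ic = self._setup()
        measure = term_measure(dag, ic)
        proteins = annot.proteins()
        for p1, p2 in itertools.islice(itertools.combinations(proteins, 2), 15):
            a = sorted(annot.terms(p1))
            b = sorted(annot.terms(p2))
            row = sum(max(measure(s, t) for t in b) for s in a) / len(a)
            col = sum(max(measure(s, t) for s in a) for t in b) / len(b)
            expected = 0.5 * (row + col)
            got = funsim_pairwise(dag, ic, annot, p1, p2).score
            assert got == pytest.approx(expected)

    def test_bma_bounded_by_max(self):
        dag, annot, ic = self._setup(seed=6)
        proteins = annot.proteins()
        for p1, p2 in itertools.islice(itertools.combinations(proteins, 2), 25):
            bma = funsim_pairwise(dag, ic, annot, p1, p2, combine="bma").score
            mx = funsim_pairwise(dag, ic, annot, p1, p2, combine="max").score
            assert bma <= mx + 1e-12


class TestFunsimSetwise:
    VARIANTS = ("simgic", "simuic", "simdic", "simuix", "simui")

    def test_identical_sets_score_one_for_every_variant(self, tiny_dag):
        annot = AnnotationSet(dag=tiny_dag)
        for p in ("p", "q"):
            annot.add(p, "GO:C")
        ic = ic_universal(compute_mu(tiny_dag))
        for variant in self.VARIANTS:
            got = funsim_setwise(tiny_dag, ic, annot, "p", "q", variant=variant)
            assert got.score == pytest.approx(1.0), variant

    def test_nested_closures_give_ic_ratio_under_max_denominator(self, tiny_dag):
        annot = AnnotationSet(dag=tiny_dag)
        annot.add("p", "GO:A")   # closure {R, A}
        annot.add("q", "GO:C")   # closure {R, A, C}
        ic = ic_universal(compute_mu(tiny_dag))
        expect = ic["GO:A"] / (ic["GO:A"] + ic["GO:C"])
        got = funsim_setwise(tiny_dag, ic, annot, "p", "q", variant="simuix")
        assert got.score == pytest.approx(expect)

    def test_denominator_ordering(self):
        cfg = SimConfig(n_terms=35, n_proteins=10, seed=8)
        dag = generate_random_dag(cfg)
        annot = generate_annotations(dag, cfg)
        ic = ic_universal(compute_mu(dag))
        for p1, p2 in itertools.combinations(annot.proteins(), 2):
            gic = funsim_setwise(dag, ic, annot, p1, p2, variant="simgic").score
            dic = funsim_setwise(dag, ic, annot, p1, p2, variant="simdic").score
            uix = funsim_setwise(dag, ic, annot, p1, p2, variant="simuix").score
            # shared numerator; denominators obey union >= max >= mean
            assert gic <= uix + 1e-12
            assert uix <= dic + 1e-12

    def test_symmetry(self, tiny_dag):
        annot = AnnotationSet(dag=tiny_dag)
        annot.add("p", "GO:C")
        annot.add("q", "GO:D")
        annot.add("q", "GO:B")
        ic = ic_universal(compute_mu(tiny_dag))
        for variant in self.VARIANTS:
            ab = funsim_setwise(tiny_dag, ic, annot, "p", "q", variant=variant).score
            ba = funsim_setwise(tiny_dag, ic, annot, "q", "p", variant=variant).score
            assert ab == pytest.approx(ba)


class TestFunsimMatrix:
    def test_batch_equals_per_pair_calls(self):
        cfg = SimConfig(n_terms=30, n_proteins=8, seed=13)
        dag = generate_random_dag(cfg)
        annot = generate_annotations(dag, cfg)
        ic = ic_universal(compute_mu(dag))
        pairs = list(itertools.combinations(annot.proteins(), 2))
        rows = funsim_matrix(dag, ic, annot, pairs, variant="bma")
        assert len(rows) == len(pairs)
        for row, (p1, p2) in zip(rows, pairs):
            single = funsim_pairwise(dag, ic, annot, p1, p2)
            assert row.score == pytest.approx(single.score)

    def test_self_pairs_score_one(self):
        cfg = SimConfig(n_terms=30, n_proteins=6, seed=14)
        dag = generate_random_dag(cfg)
        annot = generate_annotations(dag, cfg)
        ic = ic_universal(compute_mu(dag))
        pairs = [(p, p) for p in annot.proteins()]
        for row in funsim_matrix(dag, ic, annot, pairs, variant="bma"):
            assert row.score == pytest.approx(1.0)

    def test_unknown_protein_yields_sentinel_and_run_continues(self, tiny_dag):
        annot = AnnotationSet(dag=tiny_dag)
        annot.add("p", "GO:C")
        ic = ic_universal(compute_mu(tiny_dag))
        rows = funsim_matrix(tiny_dag, ic, annot, [("p", "ghost"), ("p", "p")])
        assert rows[0].score is None
        assert rows[1].score == pytest.approx(1.0)
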