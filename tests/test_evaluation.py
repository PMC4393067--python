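"""Boundary assessments, report arithmetic, and the restricted comparison."""

import pytest

import chemner as cn
from chemner.evaluation import EvaluationReport, format_reports, round2
from chemner.text import AnnotatedDocument, EntityMention


def _m(doc, start, end, lid=None):
    return EntityMention(doc, start, end, "x" * (end - start), lid)


class TestMatch:
    def test_identical_spans_match_all_modes(self):
        for mode in cn.MODES:
            assert len(cn.match([_m("d", 10, 20)], [_m("d", 10, 20)], mode)) == 1

    def test_right_aligned_span(self):
        g, p = [_m("d", 10, 20)], [_m("d", 14, 20)]
        for mode, hit in [("exact", 0), ("left", 0), ("right", 1),
                          ("left_right", 1), ("partial", 1)]:
            assert len(cn.match(g, p, mode)) == hit

    def test_disjoint_spans_match_nothing(self):
        for mode in cn.MODES:
            assert cn.match([_m("d", 10, 20)], [_m("d", 25, 30)], mode) == []

    def test_one_to_one_pairing(self):
        # two predictions overlap one gold: only one pair may form
        g = [_m("d", 10, 20)]
        p = [_m("d", 8, 12), _m("d", 15, 25)]
        assert len(cn.match(g, p, "partial")) == 1

    def test_cross_document_mentions_rejected(self):
        with pytest.raises(ValueError, match="multiple documents"):
            cn.match([_m("a", 0, 5)], [_m("b", 0, 5)], "exact")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            cn.match([], [], "middle")


class TestReportArithmetic:
    def test_zero_tp_gives_zero_scores(self):
        rep = EvaluationReport("exact", 0, 10, 10)
        assert (rep.precision, rep.recall, rep.f_measure) == (0.0, 0.0, 0.0)

    def test_empty_predictions_precision_zero(self):
        rep = EvaluationReport("exact", 0, 0, 10)
        assert rep.precision == 0.0

    def test_half_up_rounding(self):
        assert round2(31.405) == 31.41
        assert round2(31.404999) == 31.40

    def test_f_bounded_and_symmetric(self):
        a = EvaluationReport("exact", 30, 40, 100)
        b = EvaluationReport("exact", 30, 100, 40)
        assert a.f_measure == b.f_measure
        assert a.f_measure <= max(a.precision, a.recall)


def brute_force_report(gold_docs, preds, mode, require_id=False):
    """Recount from scratch: per-document greedy pairing re-derived with an
    explicit quadratic loop over (gold, pred) pairs."""
    pred_ok = {
        "exact": lambda g, p: g.span == p.span,
        "left": lambda g, p: g.start == p.start,
        "right": lambda g, p: g.end == p.end,
        "left_right": lambda g, p: g.start == p.start or g.end == p.end,
        "partial": lambda g, p: max(g.start, p.start) < min(g.end, p.end),
    }[mode]
    tp = 0
    for doc in gold_docs:
        ps = sorted(preds.get(doc.doc_id, []), key=lambda m: m.span)
        used = set()
        for g in sorted(doc.entities, key=lambda m: m.span):
            for i, p in enumerate(ps):
                if i in used or not pred_ok(g, p):
                    continue
                used.add(i)
                if not require_id or (g.lexicon_id is not None
                                      and g.lexicon_id == p.lexicon_id):
                    tp += 1
                break
    return tp


@pytest.fixture(scope="module")
def gold_and_preds():
    cfg = cn.FixtureConfig(seed=23, n_docs=4, n_terms=25)
    lexicon = cn.make_lexicon(cfg)
    corpus = cn.make_corpus(lexicon, cfg)
    preds = {d.doc_id: cn.recognize(lexicon, d.text, d.doc_id) for d in corpus}
    return corpus, preds


class TestPooledReports:
    @pytest.mark.parametrize("mode", cn.MODES)
    def test_recognition_matches_brute_force(self, gold_and_preds, mode):
        corpus, preds = gold_and_preds
        rep = cn.recognition_report(corpus, preds, mode)
        assert rep.tp == brute_force_report(corpus, preds, mode)
        assert rep.n_pred == sum(len(v) for v in preds.values())
        assert rep.n_gold == sum(len(d.entities) for d in corpus)

    @pytest.mark.parametrize("mode", cn.MODES)
    def test_identification_never_exceeds_recognition(self, gold_and_preds, mode):
        corpus, preds = gold_and_preds
        mapped = cn.mapped_subset(corpus)
        rec = cn.recognition_report(mapped, preds, mode)
        ident = cn.identification_report(mapped, preds, mode)
        assert ident.tp <= rec.tp
        assert ident.tp == brute_force_report(mapped, preds, mode, require_id=True)

    def test_doc_id_mismatch_rejected(self, gold_and_preds):
        corpus, preds = gold_and_preds
        bad = dict(preds)
        bad["ghost"] = []
        with pytest.raises(ValueError, match="ghost"):
            cn.recognition_report(corpus, bad, "exact")


class TestRestrictedResolution:
    def test_identical_correct_systems(self):
        text = "methanol and ethanol"
        gold = [
            AnnotatedDocument("d", text, [
                EntityMention("d", 0, 8, "methanol", "CHEBI:17790"),
                EntityMention("d", 13, 20, "ethanol", "CHEBI:16236"),
            ])
        ]
        preds = {"d": gold[0].entities}
        rep_a, rep_b = cn.restricted_resolution_report(gold, preds, preds, "exact")
        assert rep_a == rep_b
        assert rep_a.precision == 100.0
        assert rep_a.recall == 100.0

    def test_evaluation_set_is_intersection(self):
        text = "methanol and ethanol and water"
        gold_ents = [
            EntityMention("d", 0, 8, "methanol", "CHEBI:17790"),
            EntityMention("d", 13, 20, "ethanol", "CHEBI:16236"),
            EntityMention("d", 25, 30, "water", "CHEBI:15377"),
        ]
        gold = [AnnotatedDocument("d", text, gold_ents)]
        # A recognizes all three but misresolves water; B misses water
        pred_a = {"d": [
            EntityMention("d", 0, 8, "methanol", "CHEBI:17790"),
            EntityMention("d", 13, 20, "ethanol", "CHEBI:16236"),
            EntityMention("d", 25, 30, "water", "CHEBI:99999"),
        ]}
        pred_b = {"d": gold_ents[:2]}
        rep_a, rep_b = cn.restricted_resolution_report(gold, pred_a, pred_b, "exact")
        assert rep_a.n_pred == rep_b.n_pred == 2  # |both-recognized|
        assert rep_a.tp == 2 and rep_b.tp == 2
        assert rep_a.n_gold == 3

    def test_fixture_systems_agree_with_recount(self):
        cfg = cn.FixtureConfig(seed=31, n_docs=3, n_terms=25, unmapped_rate=0.2)
        lexicon = cn.make_lexicon(cfg)
        corpus = cn.mapped_subset(cn.make_corpus(lexicon, cfg))
        pred_a = {d.doc_id: cn.recognize(lexicon, d.text, d.doc_id) for d in corpus}
        # system B: A with every second prediction dropped and ids of the rest kept
        pred_b = {k: v[::2] for k, v in pred_a.items()}
        rep_a, rep_b = cn.restricted_resolution_report(corpus, pred_a, pred_b, "exact")
        # recount: gold matched by both systems, then id agreement per system
        both = 0
        tp_a = tp_b = 0
        for d in corpus:
            pa = {g.span: p for g, p in cn.match(d.entities, pred_a[d.doc_id], "exact")}
            pb = {g.span: p for g, p in cn.match(d.entities, pred_b[d.doc_id], "exact")}
            for g in d.entities:
                if g.span in pa and g.span in pb:
                    both += 1
                    tp_a += pa[g.span].lexicon_id == g.lexicon_id
                    tp_b += pb[g.span].lexicon_id == g.lexicon_id
        assert (rep_a.n_pred, rep_a.tp, rep_b.tp) == (both, tp_a, tp_b)


def test_report_formatting_columns():
    rep = EvaluationReport("exact", 9094, 13832, 18061)
    text = format_reports([("Exact matching", "Machine learning", rep)])
    header, row = text.strip().splitlines()
    assert header.split("\t") == [
        "Assessment", "Method", "TP", "Precision", "Recall", "F-measure",
    ]
    assert row.split("\t")[2:] == ["9094", "65.75", "50.35", "57.03"]
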