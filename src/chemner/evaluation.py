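"""Boundary-matching evaluation of predicted mentions against a gold standard.

Five assessments decide when a predicted span counts as matching a gold
span (g and p half-open intervals):

    exact       g.start == p.start and g.end == p.end
    left        g.start == p.start
    right       g.end == p.end
    left_right  g.start == p.start or g.end == p.end
    partial     the spans overlap at all

Within each document a one-to-one pairing over admissible (gold, pred)
pairs is built greedily in document order, so no mention is counted twice.
Three report flavours share this machinery:

* recognition: TP = matched pairs;
* identification: TP = matched pairs whose lexicon ids also agree;
* restricted resolution: the evaluation set is the gold mentions recognized
  by BOTH systems under the assessment; each system's precision is measured
  against that set, recall against the full mapped gold.

Precision, recall and F-measure are percentages rounded half-up to two
decimals; F is computed from the unrounded precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .text import AnnotatedDocument, EntityMention

__all__ = [
    "MODES",
    "EvaluationReport",
    "match",
    "recognition_report",
    "identification_report",
    "restricted_resolution_report",
    "mapped_subset",
    "format_reports",
]

MODES: tuple[str, ...] = ("exact", "left", "right", "left_right", "partial")

_PREDICATES: dict[str, Callable[[EntityMention, EntityMention], bool]] = {
    "exact": lambda g, p: g.start == p.start and g.end == p.end,
    "left": lambda g, p: g.start == p.start,
    "right": lambda g, p: g.end == p.end,
    "left_right": lambda g, p: g.start == p.start or g.end == p.end,
    "partial": lambda g, p: g.start < p.end and p.start < g.end,
}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the convention of the printed tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvaluationReport:
    mode: str
    tp: int
    n_pred: int
    n_gold: int

    @property
    def precision(self) -> float:
        return round2(self._precision_raw)

    @property
    def recall(self) -> float:
        return round2(self._recall_raw)

    @property
    def f_measure(self) -> float:
        p, r = self._precision_raw, self._recall_raw
        return round2(0.0 if p + r == 0 else 2 * p * r / (p + r))

    @property
    def _precision_raw(self) -> float:
        return 100.0 * self.tp / self.n_pred if self.n_pred else 0.0

    @property
    def _recall_raw(self) -> float:
        return 100.0 * self.tp / self.n_gold if self.n_gold else 0.0


def match(
    gold: Sequence[EntityMention], pred: Sequence[EntityMention], mode: str
) -> list[tuple[EntityMention, EntityMention]]:
    """Greedy one-to-one pairing of admissible (gold, pred) pairs.

    Both lists must come from one document.  Gold mentions are visited in
    document order; each takes the first admissible unused prediction.
    """
    if mode not in _PREDICATES:
        raise ValueError(f"unknown assessment mode {mode!r}")
    doc_ids = {m.doc_id for m in gold} | {m.doc_id for m in pred}
    if len(doc_ids) > 1:
        raise ValueError(f"mentions from multiple documents: {sorted(doc_ids)}")
    admissible = _PREDICATES[mode]
    preds = sorted(pred, key=lambda m: (m.start, m.end))
    used = [False] * len(preds)
    pairs = []
    for g in sorted(gold, key=lambda m: (m.start, m.end)):
        for i, p in enumerate(preds):
            if not used[i] and admissible(g, p):
                used[i] = True
                pairs.append((g, p))
                break
    return pairs


def _by_doc(docs: Iterable[AnnotatedDocument]) -> dict[str, AnnotatedDocument]:
    return {d.doc_id: d for d in docs}


def _check_same_docs(gold_docs, pred: Mapping[str, Sequence[EntityMention]]) -> None:
    gold_ids = {d.doc_id for d in gold_docs}
    extra = set(pred) - gold_ids
    if extra:
        raise ValueError(f"predictions for unknown documents: {sorted(extra)}")


def _pool_pairs(
    gold_docs: Sequence[AnnotatedDocument],
    pred: Mapping[str, Sequence[EntityMention]],
    mode: str,
) -> list[tuple[EntityMention, EntityMention]]:
    pairs = []
    for doc in gold_docs:
        pairs.extend(match(doc.entities, pred.get(doc.doc_id, []), mode))
    return pairs


def recognition_report(
    gold_docs: Sequence[AnnotatedDocument],
    pred: Mapping[str, Sequence[EntityMention]],
    mode: str,
) -> EvaluationReport:
    """Pooled recognition scores: a TP is any matched (gold, pred) pair."""
    _check_same_docs(gold_docs, pred)
    pairs = _pool_pairs(gold_docs, pred, mode)
    n_pred = sum(len(v) for v in pred.values())
    n_gold = sum(len(d.entities) for d in gold_docs)
    return EvaluationReport(mode, len(pairs), n_pred, n_gold)


def identification_report(
    gold_docs: Sequence[AnnotatedDocument],
    pred: Mapping[str, Sequence[EntityMention]],
    mode: str,
) -> EvaluationReport:
    """Recognition + resolution: a matched pair is a TP only when the
    predicted lexicon id equals the gold id.

    Gold documents are expected to be restricted upstream to mentions that
    carry lexicon ids (see :func:`mapped_subset`).
    """
    _check_same_docs(gold_docs, pred)
    pairs = _pool_pairs(gold_docs, pred, mode)
    tp = sum(
        1
        for g, p in pairs
        if g.lexicon_id is not None and g.lexicon_id == p.lexicon_id
    )
    n_pred = sum(len(v) for v in pred.values())
    n_gold = sum(len(d.entities) for d in gold_docs)
    return EvaluationReport(mode, tp, n_pred, n_gold)


def restricted_resolution_report(
    gold_docs: Sequence[AnnotatedDocument],
    pred_a: Mapping[str, Sequence[EntityMention]],
    pred_b: Mapping[str, Sequence[EntityMention]],
    mode: str,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Resolution-only comparison on the gold mentions both systems recognized.

    The evaluation set is the set of gold mentions matched under ``mode`` by
    both systems.  For each system TP counts members whose paired prediction
    carries the gold lexicon id; precision is TP over the evaluation set
    size, recall is TP over the full (mapped) gold count.
    """
    _check_same_docs(gold_docs, pred_a)
    _check_same_docs(gold_docs, pred_b)
    paired_a = {
        (g.doc_id, g.span): p for g, p in _pool_pairs(gold_docs, pred_a, mode)
    }
    paired_b = {
        (g.doc_id, g.span): p for g, p in _pool_pairs(gold_docs, pred_b, mode)
    }
    both = set(paired_a) & set(paired_b)
    gold_by_key = {
        (g.doc_id, g.span): g for d in gold_docs for g in d.entities
    }
    n_gold = sum(len(d.entities) for d in gold_docs)

    def report(paired: dict) -> EvaluationReport:
        tp = sum(
            1
            for key in both
            if gold_by_key[key].lexicon_id is not None
            and paired[key].lexicon_id == gold_by_key[key].lexicon_id
        )
        return EvaluationReport(mode, tp, len(both), n_gold)

    return report(paired_a), report(paired_b)


def mapped_subset(docs: Sequence[AnnotatedDocument]) -> list[AnnotatedDocument]:
    """Restrict gold documents to mentions that carry a lexicon id."""
    return [
        AnnotatedDocument(
            d.doc_id, d.text, [e for e in d.entities if e.lexicon_id is not None]
        )
        for d in docs
    ]


def format_reports(
    rows: Sequence[tuple[str, str, EvaluationReport]], sep: str = "\t"
) -> str:
    """Render (assessment, method, report) rows in the tables' column layout."""
    lines = [sep.join(("Assessment", "Method", "TP", "Precision", "Recall", "F-measure"))]
    for assessment, method, rep in rows:
        lines.append(
            sep.join(
                (
                    assessment,
                    method,
                    str(rep.tp),
                    f"{rep.precision:.2f}",
                    f"{rep.recall:.2f}",
                    f"{rep.f_measure:.2f}",
                )
            )
        )
    return "\n".join(lines) + "\n"


def write_reports(
    rows: Sequence[tuple[str, str, EvaluationReport]], path: str | Path
) -> None:
    Path(path).write_text(format_reports(rows), encoding="utf-8")
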