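"""Two-stage lexical resolution of a surface string to a lexicon term.

Stage 1 (exact): the case-folded surface is compared against case-folded
descriptors.  A match to a term's name scores 1.0, to a synonym 0.8.

Stage 2 (partial, only when stage 1 fails): descriptors sharing at least one
vocabulary word with the surface are scored by an evidence-content-weighted
Jaccard similarity,

    Sim_PM(input, t_d) = desc * sum_{w in input ∩ t_d} EC(w)
                              / sum_{w in t_d} EC(w)

where t_d is the descriptor's (stopword-filtered) word set, EC the evidence
content from the vocabulary index, and desc = 1.0 for names, 0.8 for
synonyms.  The score weighs the relevance of the shared words against the
total relevance of the descriptor's words, so sharing a rare word counts
for more than sharing a common one.  Per term only the best descriptor is
kept; results are ranked by score.

Because Sim_PM is a ratio of EC sums, it is invariant to the logarithm base
used when building the index.  Input words outside the ontology vocabulary
contribute to neither sum; descriptors whose words all have EC = 0 (words
present in every term) are unrankable and skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .lexicon import VocabularyIndex

__all__ = ["ResolutionResult", "resolve_exact", "resolve_partial", "resolve"]

_MATCH_KINDS = ("name-exact", "synonym-exact", "partial-name", "partial-synonym")
SYNONYM_WEIGHT = 0.8


@dataclass(frozen=True)
class ResolutionResult:
    term_id: str
    score: float
    match_kind: str
    matched_descriptor: str

    def __post_init__(self) -> None:
        if self.match_kind not in _MATCH_KINDS:
            raise ValueError(f"unknown match kind {self.match_kind!r}")


def resolve_exact(surface: str, index: VocabularyIndex) -> ResolutionResult | None:
    """Whole-string exact match of the surface against descriptors.

    Matching is case-folded whole-string equality (a surface *containing*
    a descriptor is the partial matcher's business).  Name matches beat
    synonym matches; remaining ties go to the smallest term id.
    """
    hits = index.by_descriptor.get(surface.strip().lower())
    if not hits:
        return None
    best = min(hits, key=lambda h: (not h[1], h[0]))  # names first, then id
    term_id, is_name, descriptor = best
    if is_name:
        return ResolutionResult(term_id, 1.0, "name-exact", descriptor)
    return ResolutionResult(term_id, SYNONYM_WEIGHT, "synonym-exact", descriptor)


def _descriptor_is_name(index: VocabularyIndex, term_id: str, descriptor: str) -> bool:
    return index.names.get(term_id) == descriptor


def resolve_partial(surface: str, index: VocabularyIndex) -> list[ResolutionResult]:
    """Rank every descriptor sharing a vocabulary word with the surface.

    Returns at most one result per term (its best-scoring descriptor),
    sorted by score; ties prefer name matches, then fewer descriptor words,
    then the smaller term id.
    """
    query = index.query_words(surface)
    if not query:
        warnings.warn(f"surface {surface!r} reduced to an empty word set", stacklevel=2)
        return []
    candidate_terms: set[str] = set()
    for w in query:
        candidate_terms |= index.terms_of.get(w, set())

    best_per_term: dict[str, tuple] = {}
    for (term_id, descriptor), words in index.words_of.items():
        if term_id not in candidate_terms:
            continue
        shared = query & words
        if not shared:
            continue
        denom = sum(index.ec[w] for w in words)
        if denom == 0.0:
            warnings.warn(
                f"descriptor {descriptor!r} of {term_id} has zero total evidence "
                "content; skipped",
                stacklevel=2,
            )
            continue
        numer = sum(index.ec[w] for w in shared)
        if numer == 0.0:
            continue
        is_name = _descriptor_is_name(index, term_id, descriptor)
        desc_weight = 1.0 if is_name else SYNONYM_WEIGHT
        score = desc_weight * numer / denom
        # ties: prefer names, then the descriptor explaining more of the
        # input (larger shared evidence content), then fewer words
        key = (-score, not is_name, -numer, len(words), descriptor)
        if term_id not in best_per_term or key < best_per_term[term_id][0]:
            kind = "partial-name" if is_name else "partial-synonym"
            best_per_term[term_id] = (
                key,
                ResolutionResult(term_id, score, kind, descriptor),
            )

    # across terms: same ordering, then smallest term id
    ranked = sorted(
        best_per_term.items(), key=lambda item: (*item[1][0][:4], item[0])
    )
    return [res for _, (_, res) in ranked]


def resolve(surface: str, index: VocabularyIndex) -> ResolutionResult | None:
    """Exact match first; on failure, the best partial match; else None."""
    if not surface.strip():
        return None
    exact = resolve_exact(surface, index)
    if exact is not None:
        return exact
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        partial = resolve_partial(surface, index)
    return partial[0] if partial else None


def resolve_batch(
    surfaces: Iterable[str], index: VocabularyIndex, out_path: str | Path
) -> None:
    """Resolve one surface per input line to TSV: surface, id, score, kind."""
    with open(out_path, "w", encoding="utf-8") as fh:
        for surface in surfaces:
            result = resolve(surface, index)
            if result is None:
                fh.write(f"{surface}\t-\t-\t-\n")
            else:
                fh.write(
                    f"{surface}\t{result.term_id}\t{result.score:.4f}\t{result.match_kind}\n"
                )
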