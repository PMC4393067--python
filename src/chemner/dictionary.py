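"""Dictionary-matching baseline recognizer.

Exact matching of lexicon descriptors (names and synonyms) against document
text, in the style of dictionary pipelines such as Whatizit's ChEBI
pipeline: recognition and resolution happen in one step, since every match
is inherently linked to the term whose descriptor matched.

Matching is case-insensitive and token-boundary-aligned; no stemming or
fuzzy matching is applied.  Overlapping candidates are resolved longest
match first, ties broken leftmost then by smallest term id.  The method
inherits the known weakness of its kind: descriptors that are common
English words ("can", "group", "all" are genuine ChEBI synonyms) match in
non-chemical contexts and surface as false positives.
"""

from __future__ import annotations

from typing import Sequence

from .lexicon import LexiconTerm
from .text import EntityMention, tokenize

__all__ = ["recognize"]


def _descriptor_token_keys(descriptor: str) -> tuple[str, ...]:
    """Case-folded token texts of a descriptor; () if it has no word tokens."""
    return tuple(tok.text.lower() for tok in tokenize(descriptor))


def recognize(
    terms: Sequence[LexiconTerm], text: str, doc_id: str = "doc"
) -> list[EntityMention]:
    """Find every maximal token-aligned descriptor occurrence in ``text``.

    Returns non-overlapping mentions in document order, each carrying the
    matched term's id and a score of 1.0 (dictionary matches are certain by
    construction of the method, not calibrated).
    """
    # descriptor word-sequence -> smallest owning term id
    patterns: dict[tuple[str, ...], str] = {}
    for term in terms:
        for desc in term.descriptors:
            key = _descriptor_token_keys(desc)
            if not key:
                continue
            best = patterns.get(key)
            if best is None or term.term_id < best:
                patterns[key] = term.term_id
    if not patterns:
        return []
    max_len = max(len(k) for k in patterns)

    tokens = tokenize(text)
    words = [t.text.lower() for t in tokens]
    n = len(tokens)

    # candidate matches: (token index, token span length)
    candidates: list[tuple[int, int]] = []
    for i in range(n):
        for span in range(min(max_len, n - i), 0, -1):
            if tuple(words[i : i + span]) in patterns:
                candidates.append((i, span))

    # longest match wins; ties leftmost (term-id tie-break already folded
    # into the pattern table)
    candidates.sort(key=lambda c: (-c[1], c[0]))
    taken = [False] * n
    chosen: list[tuple[int, int]] = []
    for i, span in candidates:
        if any(taken[i : i + span]):
            continue
        for k in range(i, i + span):
            taken[k] = True
        chosen.append((i, span))

    mentions = []
    for i, span in sorted(chosen):
        start = tokens[i].start
        end = tokens[i + span - 1].end
        term_id = patterns[tuple(words[i : i + span])]
        mentions.append(
            EntityMention(doc_id, start, end, text[start:end], term_id, score=1.0)
        )
    return mentions
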