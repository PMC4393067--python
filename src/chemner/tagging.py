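"""Entity-span <-> tag-sequence conversion and per-token feature extraction.

The tag set marks entity boundaries with five tags:

    NO    non-chemical token
    NE    single-token chemical entity
    S-NE  start of a multi-token entity
    M-NE  middle of a multi-token entity
    E-NE  end of a multi-token entity

so "an oligomeric amdioamine salt and an amidoquat", with entities
"oligomeric amdioamine salt" and "amidoquat", is tagged
NO, S-NE, M-NE, E-NE, NO, NO, NE.

Each token is described by four features: its Porter stem, its first three
and last three characters (the whole token when shorter), and whether it is
a number.  These are deliberately dictionary-independent: no lexicon lookup
feeds the sequence model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .stem import porter_stem
from .text import EntityMention, Token

__all__ = [
    "TAGS",
    "FeatureSet",
    "AlignmentError",
    "spans_to_tags",
    "tags_to_spans",
    "extract_features",
    "write_tagged",
    "read_tagged",
]

NO, NE, S_NE, M_NE, E_NE = "NO", "NE", "S-NE", "M-NE", "E-NE"
TAGS: tuple[str, ...] = (NO, NE, S_NE, M_NE, E_NE)

# optional sign, digits, optional single decimal point or comma
_NUMBER_RE = re.compile(r"^[+-]?\d+([.,]\d+)?$")


class AlignmentError(ValueError):
    """An entity boundary falls strictly inside a token."""


@dataclass(frozen=True)
class FeatureSet:
    stem: str
    prefix: str
    suffix: str
    is_number: bool


def extract_features(tokens: Sequence[Token | str]) -> list[FeatureSet]:
    """Per-token features: stem, 3-char prefix/suffix, numeric flag.

    Context-free and deterministic; accepts Token objects or raw strings.
    """
    out = []
    for tok in tokens:
        text = tok.text if isinstance(tok, Token) else tok
        out.append(
            FeatureSet(
                stem=porter_stem(text),
                prefix=text[:3],
                suffix=text[-3:],
                is_number=bool(_NUMBER_RE.match(text)),
            )
        )
    return out


def spans_to_tags(
    tokens: Sequence[Token], entities: Sequence[EntityMention]
) -> list[str]:
    """Encode token-aligned entity spans as a tag sequence.

    Single-token entities become NE; k-token entities (k >= 2) become
    S-NE, (k-2) x M-NE, E-NE.  An entity whose boundary does not coincide
    with token boundaries raises :class:`AlignmentError`.
    """
    tags = [NO] * len(tokens)
    start_of = {t.start: i for i, t in enumerate(tokens)}
    end_of = {t.end: i for i, t in enumerate(tokens)}
    for ent in entities:
        if ent.start not in start_of or ent.end not in end_of:
            raise AlignmentError(
                f"entity {ent.surface!r} [{ent.start}, {ent.end}) does not align "
                "with token boundaries"
            )
        i, j = start_of[ent.start], end_of[ent.end]
        if any(tags[k] != NO for k in range(i, j + 1)):
            raise AlignmentError(
                f"entity {ent.surface!r} overlaps a previously tagged entity"
            )
        if i == j:
            tags[i] = NE
        else:
            tags[i] = S_NE
            for k in range(i + 1, j):
                tags[k] = M_NE
            tags[j] = E_NE
    return tags


def tags_to_spans(
    tokens: Sequence[Token],
    tags: Sequence[str],
    doc_id: str = "doc",
    text: str | None = None,
    repairs: list[str] | None = None,
) -> list[EntityMention]:
    """Decode a tag sequence into entity mentions; total on invalid input.

    Valid sequences invert :func:`spans_to_tags`.  Invalid sequences (which a
    sequence model can emit) are repaired deterministically:

    * dangling S-NE (not followed by M-NE/E-NE) closes as a single-token
      entity;
    * an orphan M-NE or E-NE extends the immediately preceding entity when
      adjacent (previous token ended an entity), otherwise it starts/forms
      its own entity.

    Repairs are appended to ``repairs`` when a list is supplied.  ``text``
    provides surfaces for multi-token spans (inter-token gaps); when absent,
    surfaces are reconstructed with single spaces.
    """
    if len(tags) != len(tokens):
        raise ValueError(f"{len(tags)} tags for {len(tokens)} tokens")
    for t in tags:
        if t not in TAGS:
            raise ValueError(f"unknown tag {t!r}")

    def log(msg: str) -> None:
        if repairs is not None:
            repairs.append(msg)

    spans: list[tuple[int, int]] = []  # token index ranges, inclusive
    open_start: int | None = None

    def close(upto: int) -> None:
        nonlocal open_start
        if open_start is not None:
            spans.append((open_start, upto))
            open_start = None

    for i, tag in enumerate(tags):
        if tag == NO:
            if open_start is not None:
                log(f"token {i}: entity left open before NO; closed at {i - 1}")
                close(i - 1)
        elif tag == NE:
            if open_start is not None:
                log(f"token {i}: entity left open before NE; closed at {i - 1}")
                close(i - 1)
            spans.append((i, i))
        elif tag == S_NE:
            if open_start is not None:
                log(f"token {i}: S-NE while open; previous closed at {i - 1}")
                close(i - 1)
            open_start = i
        elif tag in (M_NE, E_NE):
            if open_start is None:
                if spans and spans[-1][1] == i - 1:
                    # orphan continuation adjacent to the previous entity
                    log(f"token {i}: orphan {tag}; extended previous entity")
                    open_start = spans.pop()[0]
                else:
                    log(f"token {i}: orphan {tag}; treated as entity start")
                    open_start = i
            if tag == E_NE:
                close(i)
    if open_start is not None:
        log(f"end of sequence: entity left open; closed at {len(tags) - 1}")
        close(len(tags) - 1)

    mentions = []
    for i, j in spans:
        start, end = tokens[i].start, tokens[j].end
        if text is not None:
            surface = text[start:end]
        elif i == j:
            surface = tokens[i].text
        else:
            # reconstruct with single spaces; offsets follow suit only when
            # tokens really are space-separated, so prefer passing text
            surface = " ".join(tok.text for tok in tokens[i : j + 1])
            end = start + len(surface)
        mentions.append(EntityMention(doc_id, start, end, surface))
    return mentions


# ---------------------------------------------------------------------------
# CoNLL-style tagged-sequence interchange

def write_tagged(
    sequences: Sequence[tuple[Sequence[Token], Sequence[str]]], path
) -> None:
    """One token per line (token TAB tag), blank line between sequences."""
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, tags in sequences:
            for tok, tag in zip(tokens, tags, strict=True):
                fh.write(f"{tok.text}\t{tag}\n")
            fh.write("\n")


def read_tagged(path) -> list[tuple[list[str], list[str]]]:
    """Inverse of :func:`write_tagged` on token texts (offsets are not stored)."""
    sequences: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if toks:
                    sequences.append((toks, tags))
                    toks, tags = [], []
                continue
            tok, tag = line.split("\t")
            toks.append(tok)
            tags.append(tag)
    if toks:
        sequences.append((toks, tags))
    return sequences
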