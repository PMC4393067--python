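"""Core text types, chemistry-aware tokenization, and standoff corpus I/O.

Systematic chemical names ("1,2-dimethylbenzene", "propan-2-ol") embed
digits, commas, hyphens, primes, and brackets that a general-purpose word
tokenizer would shatter.  The tokenizer here keeps such characters inside a
token whenever they are flanked by alphanumerics on both sides, and treats
them as separators otherwise, so ordinary sentence punctuation still splits
words.  Separator characters are skipped rather than emitted as tokens; every
token carries its character span, so the original text is always recoverable.

Corpora are stored in a standoff layout: one UTF-8 plain-text file per
document plus a single tab-separated annotation file with columns
``doc_id, start, end, surface, lexicon_id`` (``-`` when unmapped).  Offsets
are 0-based and half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "EntityMention",
    "AnnotatedDocument",
    "CorpusFormatError",
    "tokenize",
    "read_corpus",
    "write_corpus",
]

_LEXICON_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")

# Characters allowed to stay inside a token when both neighbours are
# alphanumeric: hyphens, commas, periods, colons, primes, slashes, brackets.
_JOINERS = set("-,.:'′/()[]")


@dataclass(frozen=True)
class Token:
    """A contiguous slice of document text with its half-open span."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty token span [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValueError(
                f"token text {self.text!r} does not fill span [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class EntityMention:
    """A document-anchored entity span, optionally mapped to a lexicon term.

    ``lexicon_id`` uses the ``PREFIX:digits`` convention (e.g. ``CHEBI:16236``);
    ``score`` is a confidence in [0, 1] attached by recognizers/resolvers.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    lexicon_id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty mention span [{self.start}, {self.end}) in {self.doc_id}"
            )
        if len(self.surface) != self.end - self.start:
            raise ValueError(
                f"surface {self.surface!r} does not fill span "
                f"[{self.start}, {self.end}) in {self.doc_id}"
            )
        if self.lexicon_id is not None and not _LEXICON_ID_RE.match(self.lexicon_id):
            raise ValueError(f"malformed lexicon id {self.lexicon_id!r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)

    def validate(self) -> None:
        """Check span/text agreement and pairwise non-overlap of entities."""
        prev_end = -1
        for ent in sorted(self.entities, key=lambda e: (e.start, e.end)):
            if ent.doc_id != self.doc_id:
                raise ValueError(
                    f"mention doc_id {ent.doc_id!r} inside document {self.doc_id!r}"
                )
            if ent.end > len(self.text):
                raise ValueError(
                    f"{self.doc_id}: span [{ent.start}, {ent.end}) outside text "
                    f"of length {len(self.text)}"
                )
            if self.text[ent.start : ent.end] != ent.surface:
                raise ValueError(
                    f"{self.doc_id}: surface {ent.surface!r} != text slice "
                    f"{self.text[ent.start:ent.end]!r} at [{ent.start}, {ent.end})"
                )
            if ent.start < prev_end:
                raise ValueError(
                    f"{self.doc_id}: overlapping entities at offset {ent.start}"
                )
            prev_end = ent.end


class CorpusFormatError(ValueError):
    """A standoff record that cannot be reconciled with its document text."""


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into tokens, preserving systematic chemical names.

    Rules: runs of alphanumeric characters form tokens; a joiner character
    (hyphen, comma, period, colon, prime, slash, bracket) is kept inside a
    token only when the characters immediately before and after it are both
    alphanumeric.  Everything else (whitespace, detached punctuation) is a
    separator and produces no token.  Total function: any string, including
    the empty string, is accepted.
    """
    tokens: list[Token] = []
    n = len(text)
    i = 0
    while i < n:
        if not _is_word_char(text[i]):
            i += 1
            continue
        start = i
        i += 1
        while i < n:
            ch = text[i]
            if _is_word_char(ch):
                i += 1
            elif ch in _JOINERS and i + 1 < n and _is_word_char(text[i + 1]):
                # joiner flanked by alphanumerics stays inside the token
                i += 2
            else:
                break
        tokens.append(Token(text[start:i], start, i))
    return tokens


# ---------------------------------------------------------------------------
# Standoff corpus I/O

_ANNOTATION_FILE = "annotations.tsv"


def write_corpus(documents: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write documents to ``path`` (a directory) in the standoff layout.

    Each document becomes ``<doc_id>.txt``; all annotations go to a single
    ``annotations.tsv`` with records in (doc_id, start) order.  Documents are
    validated before anything is written.
    """
    docs = list(documents)
    for doc in docs:
        doc.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = []
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        for ent in sorted(doc.entities, key=lambda e: e.start):
            lex = ent.lexicon_id if ent.lexicon_id is not None else "-"
            lines.append(f"{doc.doc_id}\t{ent.start}\t{ent.end}\t{ent.surface}\t{lex}\n")
    (path / _ANNOTATION_FILE).write_text("".join(lines), encoding="utf-8")
    (path / "docs.list").write_text(
        "".join(f"{doc.doc_id}\n" for doc in docs), encoding="utf-8"
    )


def read_corpus(path: str | Path) -> list[AnnotatedDocument]:
    """Read a standoff corpus directory written by :func:`write_corpus`.

    Raises :class:`CorpusFormatError` naming the offending record when offsets
    are malformed or a surface string disagrees with its document slice.
    """
    path = Path(path)
    doc_ids = [
        line.strip()
        for line in (path / "docs.list").read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    docs = {
        doc_id: AnnotatedDocument(
            doc_id, (path / f"{doc_id}.txt").read_text(encoding="utf-8")
        )
        for doc_id in doc_ids
    }
    ann = path / _ANNOTATION_FILE
    if ann.exists():
        for lineno, line in enumerate(ann.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise CorpusFormatError(
                    f"{ann}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            doc_id, start_s, end_s, surface, lex = fields
            if doc_id not in docs:
                raise CorpusFormatError(f"{ann}:{lineno}: unknown document {doc_id!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{ann}:{lineno}: non-integer offsets in {doc_id}"
                ) from exc
            text = docs[doc_id].text
            if not (0 <= start < end <= len(text)):
                raise CorpusFormatError(
                    f"{ann}:{lineno}: bad span [{start}, {end}) for {doc_id} "
                    f"(text length {len(text)})"
                )
            if text[start:end] != surface:
                raise CorpusFormatError(
                    f"{ann}:{lineno}: surface {surface!r} != {doc_id} text slice "
                    f"{text[start:end]!r} at [{start}, {end})"
                )
            docs[doc_id].entities.append(
                EntityMention(doc_id, start, end, surface, None if lex == "-" else lex)
            )
    for doc in docs.values():
        doc.validate()
    return [docs[d] for d in doc_ids]


def write_mentions(mentions: Sequence[EntityMention], path: str | Path) -> None:
    """Write mentions as standoff TSV (doc_id, start, end, surface, lexicon_id)."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            lex = m.lexicon_id if m.lexicon_id is not None else "-"
            fh.write(f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{lex}\n")
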