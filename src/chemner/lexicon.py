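"""ChEBI-style lexicon loading and the evidence-content vocabulary index.

A lexicon term has a unique identifier, a primary name, and synonyms; name
and synonyms together are the term's *descriptors*.  For the partial-match
resolver every descriptor is tokenized, case-folded and stopword-filtered,
and each surviving word w receives an *evidence content*

    EC(w) = -ln f(w),        f(w) = (#terms containing w) / (#terms)

where a word occurring several times within one term's descriptors counts
once, so synonym-rich terms do not inflate word frequencies.  Ubiquitous
words get EC = 0 and carry no weight; words unique to a single term get the
maximum EC = ln(#terms).
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import obonet

from .stopwords import STOPWORDS
from .text import tokenize

__all__ = [
    "LexiconTerm",
    "VocabularyIndex",
    "LexiconFormatError",
    "load_lexicon",
    "build_index",
    "descriptor_words",
]


class LexiconFormatError(ValueError):
    pass


@dataclass(frozen=True)
class LexiconTerm:
    term_id: str
    name: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise LexiconFormatError(f"term {self.term_id} has an empty name")

    @property
    def descriptors(self) -> tuple[str, ...]:
        """The term's name followed by its synonyms."""
        return (self.name,) + self.synonyms


def descriptor_words(descriptor: str, stopwords: frozenset[str] = STOPWORDS) -> frozenset[str]:
    """Tokenize a descriptor, case-fold, and drop stopwords."""
    return frozenset(
        tok.text.lower() for tok in tokenize(descriptor)
    ) - stopwords


# ---------------------------------------------------------------------------
# Loading

_OBO_SYNONYM_RE = re.compile(r'^"(.*)"')


def _load_obo(path: Path) -> list[LexiconTerm]:
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = []
    for term_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            raise LexiconFormatError(f"OBO term {term_id} has no name")
        synonyms = []
        for raw in data.get("synonym", []):
            m = _OBO_SYNONYM_RE.match(raw)
            if m and m.group(1):
                synonyms.append(m.group(1))
        terms.append(LexiconTerm(term_id, name, tuple(synonyms)))
    terms.sort(key=lambda t: t.term_id)
    return terms


def _load_tsv(path: Path) -> list[LexiconTerm]:
    terms = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise LexiconFormatError(f"{path}:{lineno}: expected id<TAB>name[<TAB>synonyms]")
        term_id, name = fields[0], fields[1]
        syns = tuple(s for s in fields[2].split("|") if s) if len(fields) > 2 else ()
        terms.append(LexiconTerm(term_id, name, syns))
    return terms


def load_lexicon(path: str | Path, format: str | None = None) -> list[LexiconTerm]:
    """Load a lexicon from an OBO 1.2 flat file or a TSV.

    TSV columns: id, name, pipe-separated synonyms.  Format is inferred from
    the extension when not given.  Duplicate term ids are rejected; obsolete
    OBO terms are skipped.
    """
    path = Path(path)
    if format is None:
        format = "obo" if path.suffix.lower() == ".obo" else "tsv"
    if format == "obo":
        terms = _load_obo(path)
    elif format == "tsv":
        terms = _load_tsv(path)
    else:
        raise ValueError(f"unknown lexicon format {format!r}")
    seen: set[str] = set()
    for term in terms:
        if term.term_id in seen:
            raise LexiconFormatError(f"duplicate term id {term.term_id}")
        seen.add(term.term_id)
    return terms


# ---------------------------------------------------------------------------
# Vocabulary index

@dataclass
class VocabularyIndex:
    """Preprocessed lexicon vocabulary supporting exact and partial matching.

    Fields
    ------
    ec : word -> evidence content (natural log; >= 0)
    terms_of : word -> ids of terms whose descriptors contain the word
    words_of : (term_id, descriptor) -> filtered word set of that descriptor
    by_descriptor : case-folded descriptor string -> list of
        (term_id, is_name, original descriptor), for exact matching
    n_terms : number of indexed terms
    """

    ec: dict[str, float]
    terms_of: dict[str, set[str]]
    words_of: dict[tuple[str, str], frozenset[str]]
    by_descriptor: dict[str, list[tuple[str, bool, str]]]
    names: dict[str, str]
    n_terms: int
    log_base: float = math.e
    stopwords: frozenset[str] = field(default_factory=lambda: STOPWORDS)

    def query_words(self, surface: str) -> frozenset[str]:
        return descriptor_words(surface, self.stopwords)

    # -- persistence (documented key-value JSON store) --

    def save(self, path: str | Path) -> None:
        payload = {
            "n_terms": self.n_terms,
            "log_base": self.log_base,
            "stopwords": sorted(self.stopwords),
            "ec": self.ec,
            "terms_of": {w: sorted(ts) for w, ts in self.terms_of.items()},
            "words_of": [
                [tid, desc, sorted(words)] for (tid, desc), words in self.words_of.items()
            ],
            "by_descriptor": {
                k: [[tid, is_name, d] for tid, is_name, d in v]
                for k, v in self.by_descriptor.items()
            },
            "names": self.names,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "VocabularyIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            ec=payload["ec"],
            terms_of={w: set(ts) for w, ts in payload["terms_of"].items()},
            words_of={
                (tid, desc): frozenset(words)
                for tid, desc, words in payload["words_of"]
            },
            by_descriptor={
                k: [(tid, bool(is_name), d) for tid, is_name, d in v]
                for k, v in payload["by_descriptor"].items()
            },
            names=payload["names"],
            n_terms=payload["n_terms"],
            log_base=payload["log_base"],
            stopwords=frozenset(payload["stopwords"]),
        )


def build_index(
    terms: list[LexiconTerm],
    stopwords: frozenset[str] = STOPWORDS,
    log_base: float = math.e,
) -> VocabularyIndex:
    """Build the vocabulary index over a non-empty term list.

    A term all of whose descriptors reduce to empty word sets after stopword
    filtering is indexed on its raw lowercased words instead (with a warning)
    so it remains reachable by partial matching.
    """
    if not terms:
        raise ValueError("cannot index an empty lexicon")
    n_terms = len(terms)
    words_of: dict[tuple[str, str], frozenset[str]] = {}
    term_vocab: dict[str, set[str]] = {}
    by_descriptor: dict[str, list[tuple[str, bool, str]]] = {}
    names: dict[str, str] = {}

    for term in terms:
        names[term.term_id] = term.name
        vocab: set[str] = set()
        filtered = {
            desc: descriptor_words(desc, stopwords) for desc in term.descriptors
        }
        if all(not ws for ws in filtered.values()):
            warnings.warn(
                f"term {term.term_id}: all descriptors are stopwords; "
                "indexing raw words",
                stacklevel=2,
            )
            filtered = {
                desc: descriptor_words(desc, frozenset())
                for desc in term.descriptors
            }
        for i, desc in enumerate(term.descriptors):
            is_name = i == 0
            by_descriptor.setdefault(desc.lower(), []).append(
                (term.term_id, is_name, desc)
            )
            ws = filtered[desc]
            if ws:
                words_of[(term.term_id, desc)] = ws
                vocab |= ws
        term_vocab[term.term_id] = vocab

    terms_of: dict[str, set[str]] = {}
    for term_id, vocab in term_vocab.items():
        for w in vocab:  # per-term set: duplicates within a term count once
            terms_of.setdefault(w, set()).add(term_id)

    log = math.log
    ec = {
        w: -log(len(tids) / n_terms) / log(log_base) if log_base != math.e
        else -log(len(tids) / n_terms)
        for w, tids in terms_of.items()
    }
    return VocabularyIndex(
        ec=ec,
        terms_of=terms_of,
        words_of=words_of,
        by_descriptor=by_descriptor,
        names=names,
        n_terms=n_terms,
        log_base=log_base,
        stopwords=stopwords,
    )
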