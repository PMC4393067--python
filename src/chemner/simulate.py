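"""Synthetic lexicons and annotated corpora for end-to-end testing.

Generation is template-based: sentences are assembled word by word, so every
gold mention's character offsets are exact by construction.  Entity strings
use chemical-like morphology (stems plus suffixes such as -ol, -ane, -ate,
-ide; multiword names like "pentanoic acid" or "zinc oxide"), while
background words come from a plain-English pool — this suffix separation is
what a sequence tagger can learn from, and ``background_chemical_rate``
deliberately erodes it by planting unannotated chemical-shaped words in the
background.

A configurable fraction of mentions is out-of-lexicon (chemical-shaped but
absent from the lexicon, carrying no id); the default rate emulates a gold
standard in which roughly half the mentions are mapped.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import LexiconTerm
from .text import AnnotatedDocument, EntityMention

__all__ = ["FixtureConfig", "make_lexicon", "make_corpus"]

_STEMS = (
    "meth eth prop but pent hex hept oct non dec chlor brom fluor iod sulf "
    "phosph amin benz tolu phen acet glyc oxal citr lact malon succin fumar "
    "tartar stear palmit oleo linole glut adip pimel suber azel sebac"
).split()

_SUFFIXES = ("ol", "ane", "ene", "yne", "ate", "ide", "ine", "one", "anol", "oate")

_HEADS = ("acid", "oxide", "chloride", "sulfate", "acetate")

_MODIFIER_SUFFIXES = ("ic", "yl", "ous", "oyl")

_BACKGROUND = (
    "the mixture was stirred heated cooled filtered dried washed under "
    "reflux vacuum nitrogen for two three hours minutes then slowly added "
    "dropwise solution residue product yield good excellent obtained "
    "purified concentrated reduced pressure room temperature reaction "
    "treatment afforded gave resulting crude solid oil layer aqueous "
    "organic phase separated extracted combined evaporated white yellow"
).split()

_TEMPLATES = (
    ("The", None, "was dissolved in", None, "and stirred"),
    ("Treatment with", None, "gave", None, "in good yield"),
    ("A solution of", None, "and", None, "was heated under reflux"),
    ("The reaction of", None, "with", None, "afforded the product"),
    (None, "reacted slowly with", None, "at room temperature"),
    ("Addition of", None, "to the mixture gave", None, "as a white solid"),
)


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_terms: int = 50
    n_docs: int = 10
    entities_per_doc: tuple[int, int] = (8, 14)
    synonym_rate: float = 0.5
    multiword_rate: float = 0.3
    unmapped_rate: float = 0.463
    background_chemical_rate: float = 0.0
    id_prefix: str = "CHEBI"
    chemical_suffix_pool: tuple[str, ...] = _SUFFIXES
    background_vocab: tuple[str, ...] = tuple(_BACKGROUND)

    def __post_init__(self) -> None:
        for name in ("synonym_rate", "multiword_rate", "unmapped_rate",
                     "background_chemical_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_terms <= 0 or self.n_docs <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.entities_per_doc
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad entities_per_doc range {self.entities_per_doc}")


def _single_word(rng: np.random.Generator, suffixes: Sequence[str]) -> str:
    return rng.choice(_STEMS) + rng.choice(list(suffixes))


def _chemical_name(
    rng: np.random.Generator, config: FixtureConfig, multiword: bool
) -> str:
    if multiword:
        modifier = rng.choice(_STEMS) + rng.choice(list(_MODIFIER_SUFFIXES))
        return f"{modifier} {rng.choice(list(_HEADS))}"
    return _single_word(rng, config.chemical_suffix_pool)


def make_lexicon(config: FixtureConfig) -> list[LexiconTerm]:
    """Generate ``n_terms`` terms with unique chemical-like names.

    Synonyms appear on a term with probability ``synonym_rate``: either an
    "iso" variant of the name or a suffix-swapped form.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    terms = []
    for i in range(config.n_terms):
        while True:
            name = _chemical_name(rng, config, rng.random() < config.multiword_rate)
            if name.lower() not in used:
                used.add(name.lower())
                break
        synonyms = []
        if rng.random() < config.synonym_rate:
            for candidate in (f"iso{name}", _chemical_name(rng, config, " " in name)):
                if candidate.lower() not in used:
                    used.add(candidate.lower())
                    synonyms.append(candidate)
                    break
        terms.append(
            LexiconTerm(f"{config.id_prefix}:{100001 + i}", name, tuple(synonyms))
        )
    return terms


def _descriptor_pool(lexicon: Sequence[LexiconTerm]) -> list[tuple[str, str]]:
    return [(desc, term.term_id) for term in lexicon for desc in term.descriptors]


def make_corpus(
    lexicon: Sequence[LexiconTerm], config: FixtureConfig
) -> list[AnnotatedDocument]:
    """Generate annotated documents embedding lexicon descriptors as gold.

    Each document fills template sentences until its sampled entity budget is
    spent.  A mention is, with probability ``unmapped_rate``, a fresh
    out-of-lexicon chemical-shaped string (no id); otherwise a randomly drawn
    descriptor carrying its term's id.  Background slots are plain-English
    words, replaced by unannotated chemical-shaped words with probability
    ``background_chemical_rate``.
    """
    if not lexicon:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(config.seed + 1)
    pool = _descriptor_pool(lexicon)
    known = {desc.lower() for desc, _ in pool}
    docs = []
    lo, hi = config.entities_per_doc
    for d in range(config.n_docs):
        doc_id = f"doc{d:03d}"
        budget = int(rng.integers(lo, hi + 1))

        def emit_background() -> str:
            if rng.random() < config.background_chemical_rate:
                return _single_word(rng, config.chemical_suffix_pool)
            return str(rng.choice(list(config.background_vocab)))

        def emit_entity() -> tuple[str, str | None]:
            if rng.random() < config.unmapped_rate:
                while True:
                    surface = _chemical_name(
                        rng, config, rng.random() < config.multiword_rate
                    )
                    if surface.lower() not in known:
                        return surface, None
            desc, term_id = pool[int(rng.integers(len(pool)))]
            return desc, term_id

        text_parts: list[str] = []
        cursor = 0
        mentions: list[EntityMention] = []
        while budget > 0:
            template = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
            for slot in template:
                if text_parts:
                    text_parts.append(" ")
                    cursor += 1
                if slot is None and budget > 0:
                    surface, term_id = emit_entity()
                    budget -= 1
                    mentions.append(
                        EntityMention(
                            doc_id, cursor, cursor + len(surface), surface, term_id
                        )
                    )
                    text_parts.append(surface)
                    cursor += len(surface)
                else:
                    chunk = emit_background() if slot is None else slot
                    text_parts.append(chunk)
                    cursor += len(chunk)
            text_parts.append(" .")
            cursor += 2
        doc = AnnotatedDocument(doc_id, "".join(text_parts), mentions)
        doc.validate()
        docs.append(doc)
    return docs
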