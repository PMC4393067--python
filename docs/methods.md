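# Methods

This note records the models, conventions and numerical choices behind
`chemner`, and what the synthetic experiments do and do not show.

## Text model and tokenization

Offsets are 0-based, half-open `[start, end)` throughout; a mention's
surface must equal its document slice, and gold mentions within a document
may not overlap.

The tokenizer targets systematic chemical nomenclature. Rules: runs of
alphanumeric characters form tokens; a *joiner* character — hyphen, comma,
period, colon, prime, slash, parenthesis or bracket — stays inside a token
only when the characters on both sides are alphanumeric; everything else
separates. Separator punctuation produces no token (tokens carry spans, so
the text is always recoverable). Consequences worth knowing: `1,2-dimethylbenzene`
and `propan-2-ol` are single tokens; `2'-deoxyadenosine` splits after the
prime (two adjacent joiners break the chain); a terminal period detaches.
Sentence splitting is deliberately absent — nothing downstream needs it, and
chemical text is rich in sentence-final-looking periods.

## Tag set, features, and decoding repairs

Entity boundaries are encoded with five tags (`NO`, `NE`, `S-NE`, `M-NE`,
`E-NE`). Compared with BIO this distinguishes single-token entities from
multi-token starts and marks ends explicitly, which makes boundary errors
visible to the evaluation.

Per-token features: Porter stem (implemented here, classic 1980 algorithm;
words shorter than three characters or containing non-ASCII/non-letters pass
through), first three and last three characters (whole token when shorter),
and a numeric flag matching optional sign, digits, and at most one decimal
point or comma. No dictionary-derived feature is used anywhere — keeping the
recognizer strictly lexicon-independent is the design point, so the tagger
and the dictionary baseline are genuinely different methods.

A sequence model can emit tag sequences with no well-formed parse
(`S-NE` followed by `NO`, an orphan `M-NE`). Decoding is total: a dangling
start closes as a single-token entity; an orphan continuation extends the
immediately preceding entity when adjacent, otherwise it opens its own.
Every repair is logged when the caller passes a list to collect them. The
full repair behaviour is pinned by an enumeration test over all two-tag
sequences.

## The CRF

First-order linear-chain CRF with binary indicator features: the four token
features for the current, previous and next position (window ±1, with
explicit begin/end-of-sequence markers), a bias, tag-transition weights, and
separate start/stop weights. Training maximises the L2-penalised conditional
log-likelihood with L-BFGS; gradients come from forward-backward marginals;
decoding is Viterbi.

Defaults: Gaussian prior width `sigma = 10`, iteration cap 120, seed 0. The
objective is convex, so the optimum does not depend on the seed; the seed is
still threaded through configuration and metadata so per-fold seeds and any
future stochastic extension stay reproducible. Each model records its
feature-template version, hyperparameters, seed and training document ids —
enough to reproduce training bit-for-bit — and prediction refuses a model
built with a different feature template.

`leave_one_out` implements document-level cross-validation: each document is
tagged by a model trained on all others, with the held-out id excluded from
(and asserted absent from) the fold's training metadata.

## Lexicon index and resolution

Descriptors (a term's name plus synonyms) are tokenized with the same
tokenizer, case-folded, and filtered against a fixed stopword list shipped
with the package (pinned for reproducibility; deliberately free of
domain words like "acid" or "group"). Word frequency counts *distinct terms*
containing the word — duplicated synonyms within a term change nothing — and
evidence content is `EC(w) = -ln(count(w)/n_terms)`, so a ubiquitous word
has EC 0 and a word unique to one term has EC `ln n_terms`. Natural log is
the default; the partial-match score is a ratio of EC sums, so the base
cancels (property-tested against a base-2 index). A term whose descriptors
are all stopwords is indexed on its raw words, with a warning, so it stays
reachable.

Resolution is two-stage. Exact match is case-folded whole-string equality
against descriptors — equality, not substring containment, because
containment would let "dimethyl sulphate" exact-match the descriptor
"methyl" with score 1, contradicting the score semantics. Name matches score
1.0, synonym matches 0.8. Only when exact matching fails does the partial
matcher run: every descriptor sharing at least one indexed word is scored
`desc × Σ EC(shared) / Σ EC(descriptor words)`, each term keeps its best
descriptor, and results are ranked. Input words outside the lexicon
vocabulary contribute to neither sum. Descriptors whose words all have EC 0
are unrankable (the score would be 0/0) and are skipped with a warning.

Tie-breaks at equal score: name over synonym, then the descriptor with the
larger shared evidence content — i.e. the one explaining more of the input;
this is what makes "zinc oxide nanoparticles" resolve to "zinc oxide" rather
than "zinc" when both reach 1.0 — then fewer descriptor words, then the
smallest term id. No score threshold is applied; callers can filter.

## Dictionary baseline

Exact matching of descriptors in text: case-insensitive, aligned to token
boundaries (no matches inside words), longest match first, ties leftmost
then smallest term id, no stemming. Matches carry the term id by
construction. The method's characteristic false positives (common English
words that are genuine lexicon synonyms) are reproduced on purpose and
covered by a test.

## Evaluation

Five boundary assessments (exact, left, right, left-or-right, partial
overlap). Within a document, admissible (gold, prediction) pairs are matched
greedily one-to-one in document order: since both sides are non-overlapping
span lists, greedy left-to-right pairing is the natural choice, and no
mention is ever counted twice. Relaxation monotonicity — TP(exact) ≤
TP(left), TP(right) ≤ TP(left/right) ≤ TP(partial) — is not a theorem under
greedy pairing in general, but is asserted on every fixture run.

Reports: precision = 100·TP/n_predicted, recall = 100·TP/n_gold, F from the
*unrounded* P and R, all rounded half-up to two decimals only for display.
Identification reports require the paired prediction's lexicon id to equal
the gold id; gold is restricted to mapped mentions first. The restricted
resolution comparison scores two systems only on the gold mentions both
recognized under the assessment: precision over that intersection, recall
over the full mapped gold.

## Synthetic data

The generator emulates the structure of a patent-style gold standard:
documents of template sentences with exact-offset gold mentions, a lexicon
of chemical-like names (stem + suffix morphology, multiword forms like
"pentanoic acid"), synonyms at a configurable rate, and a configurable
out-of-lexicon mention rate whose default (0.463 unmapped) reproduces a
corpus in which ~53.7% of mentions carry identifiers.

The default study conditions used by the recovery experiments are 10
documents, 50 terms, 8–14 mentions per document, seed fixed — small enough
that the full leave-one-out protocol runs in seconds per fold, large enough
for stable scores. `background_chemical_rate` plants unannotated
chemical-shaped words in the background, eroding the suffix cue; recovery F
falls monotonically as it rises, which is checked at three settings.

What passing these tests shows: the pipeline is wired correctly end to end,
the CRF can learn a morphologically separable vocabulary through the
documented features, and the dictionary recovers what its lexicon contains.
What they do not show: performance on real patent text, whose entities are
longer, nested in complex noun phrases, and not morphologically separable
from context — corpus-scale scores here say nothing quantitative about that
setting.

## Known limitations

- The tokenizer is rule-based and documented, but chemical tokenization is
  genuinely hard; names mixing primes with hyphens split more eagerly than a
  specialist tokenizer would.
- The CRF uses only the four documented features in a ±1 window; richer
  orthographic features would help real corpora but would blur the
  dictionary-independence contrast the package exists to study.
- Exact dictionary matching has no plural or case-variant handling beyond
  case folding, so recall on inflected real text is understated.
- OBO synonym scopes (EXACT/RELATED/...) are not distinguished; all synonyms
  weigh 0.8 in resolution.
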