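"""Tokenize a chemical sentence, extract features, and encode entity tags.

Run:  python examples/tokenize_and_tag.py
"""

import chemner as cn

text = (
    "cosmetic compositions containing colostrum, tocopherols, "
    "zinc oxide and hyaluronic acid"
)

# gold chemical entities in this sentence, with exact character spans
entities = []
for surface in ("tocopherols", "zinc oxide", "hyaluronic acid"):
    start = text.index(surface)
    entities.append(cn.EntityMention("example", start, start + len(surface), surface))

tokens = cn.tokenize(text)
features = cn.extract_features(tokens)
tags = cn.spans_to_tags(tokens, entities)

print(f"{'Token':14s}{'Stem':12s}{'Prefix':8s}{'Suffix':8s}{'Number':8s}Tag")
for tok, feat, tag in zip(tokens, features, tags):
    num = "Yes" if feat.is_number else "No"
    print(f"{tok.text:14s}{feat.stem:12s}{feat.prefix:8s}{feat.suffix:8s}{num:8s}{tag}")

# Each token carries its stem, 3-character prefix/suffix and a numeric flag —
# the four dictionary-independent features the sequence tagger learns from.
# The tag column marks entity boundaries: NE = single-token entity,
# S-NE/M-NE/E-NE = start/middle/end of a multi-token entity, NO = background.
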