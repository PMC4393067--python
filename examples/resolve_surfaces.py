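"""Resolve recognized surface strings to lexicon identifiers with scores.

Run:  python examples/resolve_surfaces.py
"""

import chemner as cn
from chemner.lexicon import LexiconTerm

lexicon = [
    LexiconTerm("CHEBI:15377", "water", ("H2O", "aqua")),
    LexiconTerm("CHEBI:16236", "ethanol", ("ethyl alcohol",)),
    LexiconTerm("CHEBI:30563", "zinc oxide", ()),
    LexiconTerm("CHEBI:27363", "zinc", ()),
    LexiconTerm("CHEBI:17009", "hyaluronan", ("hyaluronic acid",)),
]
index = cn.build_index(lexicon)

for surface in (
    "water",                     # exact match to a name          -> 1.0
    "aqua",                      # exact match to a synonym       -> 0.8
    "zinc oxide nanoparticles",  # partial: covers a whole name   -> 1.0
    "acid hyaluronic",           # partial: covers a whole synonym-> 0.8
    "unknownium",                # nothing shared                 -> no match
):
    result = cn.resolve(surface, index)
    if result is None:
        print(f"{surface!r:30s} -> no match")
    else:
        print(
            f"{surface!r:30s} -> {result.term_id}  score={result.score:.2f}  "
            f"({result.match_kind} via {result.matched_descriptor!r})"
        )

# Exact matches score 1.0 (name) or 0.8 (synonym).  When no descriptor equals
# the surface, descriptors sharing words are ranked by an evidence-content
# weighted Jaccard score: rare shared words count for more, and a descriptor
# fully covered by the query reaches the full 1.0/0.8 weight.
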