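"""Fixed English stopword list used for lexicon vocabulary preprocessing.

The list is pinned (not taken from an external resource) so that evidence
content values are reproducible across installations.  It deliberately
contains only closed-class English words; domain words that happen to be
frequent in chemical nomenclature ("acid", "group", "oxide") are NOT
stopwords — their weight is handled by the evidence-content weighting
instead.
"""

STOPWORDS: frozenset[str] = frozenset(
    """
    a an the and or but nor of in on at to for from by with without as is
    are was were be been being am it its it's this that these those there
    here not no yes if then than so such which who whom whose what when
    where why how all any both each few more most other some own same
    very can will just do does did doing have has had having i you he she
    we they them his her their our your my me him us into over under
    about between through during before after above below up down out off
    again further once
    """.split()
)
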