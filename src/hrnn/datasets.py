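"""Reference networks for validation on real data.

IRMA is a five-gene synthetic-biology network built in *Saccharomyces
cerevisiae* for in vivo benchmarking of network-reconstruction methods:
cells are shifted between glucose (switch OFF) and galactose (switch ON)
media and the five transcripts are profiled over time.  The expression
time courses themselves are an external input (load them with
:func:`hrnn.io.read_expression` from a standard gene x time matrix); this
module ships only the published regulatory topology to score against.
"""

from __future__ import annotations

__all__ = ["IRMA_GENES", "irma_true_network"]

IRMA_GENES = ["CBF1", "GAL4", "SWI5", "GAL80", "ASH1"]

# The eight regulatory interactions of the IRMA network.  Signs follow the
# construct's biology: ASH1 represses CBF1 (HO promoter) and GAL80 represses
# GAL4 (via Gal80 binding); the remaining links are activatory.  Delays are
# not part of the published truth table and are recorded as a nominal 1;
# score such comparisons on the Link and Effect criteria only.
_IRMA_EDGES = [
    ("CBF1", "GAL4", +1),
    ("GAL4", "SWI5", +1),
    ("SWI5", "GAL80", +1),
    ("GAL80", "GAL4", -1),
    ("SWI5", "CBF1", +1),
    ("SWI5", "ASH1", +1),
    ("ASH1", "CBF1", -1),
    ("GAL4", "GAL80", +1),
]


def irma_true_network() -> list[dict]:
    """The 8-edge IRMA truth as scorer-ready records."""
    return [
        {"regulator": r, "target": t, "delay": 1, "sign": s}
        for r, t, s in _IRMA_EDGES
    ]
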