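"""Layer and compartment vocabulary shared across modules.

A *layer* is one omic table (microbial counts per gut compartment, liver
transcriptome, serum/liver metabolome, phenotypes).  Network nodes are
namespaced as ``layer:feature_id`` so the same genus measured in both
compartments yields two distinct nodes.
"""

from __future__ import annotations

MICROBES_A = "microbes_A"
MICROBES_B = "microbes_B"
GENES = "genes"
METAB_SERUM = "metab_serum"
METAB_LIVER = "metab_liver"
PHENOTYPES = "phenotypes"

MICROBE_LAYERS = (MICROBES_A, MICROBES_B)
HOST_LAYERS = (GENES, METAB_SERUM, METAB_LIVER, PHENOTYPES)
ALL_LAYERS = MICROBE_LAYERS + HOST_LAYERS

#: compartment tag per layer ("A"/"B" for the two gut segments, "host" otherwise)
COMPARTMENT = {
    MICROBES_A: "A",
    MICROBES_B: "B",
    GENES: "host",
    METAB_SERUM: "host",
    METAB_LIVER: "host",
    PHENOTYPES: "host",
}

#: layers whose values are counts (log fold changes need a pseudocount)
COUNT_LAYERS = frozenset(MICROBE_LAYERS)


def node_id(layer: str, feature: str) -> str:
    """Globally unique node identifier for a feature within a layer."""
    return f"{layer}:{feature}"


def split_node_id(node: str) -> tuple[str, str]:
    layer, _, feature = node.partition(":")
    return layer, feature
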