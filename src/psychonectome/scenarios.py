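"""Packaged planted scenarios for demos and end-to-end validation.

The demo scenario plants, at the pre occasion, two transversal construct
chains — a mindfulness/self-compassion chain and a symptom/rumination chain,
with the conventional edge magnitudes 0.18-0.45 — embedded in five
construct communities (the chain node sets cohere through weak within-block
edges so the chains stay the only strong multi-edge structures).  At the
post occasion the chains dissolve and the nodes regroup into five different
communities, emulating a reorganization of the construct network after an
intervention.
"""

from __future__ import annotations

from .synthgen import PlantedNetwork, make_planted_network

__all__ = ["demo_pre_network", "demo_post_network", "path_only_network"]

#: The two planted pre-occasion chains (node sequence, step weights).
PRE_CHAIN_MINDFULNESS = (
    ["FFMQ-O", "MAIA", "EQ", "NAS", "SCS-M", "SCS-A", "SCS-H"],
    [0.33, 0.29, 0.22, 0.23, 0.25, 0.22],
)
PRE_CHAIN_SYMPTOMS = (
    ["DASS-A", "DASS-S", "DASS-D", "RRS-B", "RRS-R"],
    [0.45, 0.18, 0.20, 0.21],
)

_PRE_BLOCKS = [
    (PRE_CHAIN_MINDFULNESS[0], 0.12),
    (PRE_CHAIN_SYMPTOMS[0], 0.12),
    (["FFMQ-D", "ACS", "FFMQ-A", "FFMQ-J", "CSP", "IRI-E"], 0.17),
    (["PHI", "SWLS", "LOT"], 0.35),
    (["FFMQ-R", "WBSI", "ERQ-R", "ERQ-S"], 0.28),
]

_POST_BLOCKS = [
    (["PHI", "SWLS", "LOT"], 0.25),
    (["NAS", "SCS-A", "SCS-H", "SCS-M", "FFMQ-J", "FFMQ-A"], 0.15),
    (["EQ", "MAIA", "FFMQ-R", "FFMQ-O", "ERQ-R"], 0.18),
    (["DASS-A", "DASS-S", "DASS-D", "WBSI", "ERQ-S", "RRS-B", "RRS-R"], 0.13),
    (["CSP", "IRI-E", "ACS", "FFMQ-D"], 0.20),
]


def demo_pre_network() -> PlantedNetwork:
    """Pre-occasion truth: two strong chains across five communities."""
    # the negative dyads sit below the path threshold (0.15) so the two
    # planted chains stay the only supra-threshold structures that span
    # communities
    return make_planted_network(
        chain_specs=[PRE_CHAIN_MINDFULNESS, PRE_CHAIN_SYMPTOMS],
        block_specs=_PRE_BLOCKS,
        negative_edges=[("WBSI", "FFMQ-J", -0.12), ("PHI", "DASS-D", -0.12)],
        description="demo pre: chains across weak communities",
    )


def demo_post_network() -> PlantedNetwork:
    """Post-occasion truth: five denser communities, chains dissolved."""
    return make_planted_network(
        block_specs=_POST_BLOCKS,
        negative_edges=[("WBSI", "FFMQ-J", -0.15), ("DASS-D", "PHI", -0.18)],
        description="demo post: five block communities",
    )


def path_only_network() -> PlantedNetwork:
    """Just the two planted chains (no communities): path-recovery fixture."""
    return make_planted_network(
        chain_specs=[PRE_CHAIN_MINDFULNESS, PRE_CHAIN_SYMPTOMS],
        description="two chains only",
    )
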