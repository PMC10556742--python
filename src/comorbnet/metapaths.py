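"""Meta-path schemas and typed-walk (instance) enumeration.

Four disease-to-disease meta-paths drive the embedding:

* ``M1``  D-G-D        two diseases sharing an associated human gene
* ``M2``  D-G-G-D      diseases whose genes encode interacting proteins
* ``M3``  D-G-M-G-D    diseases bridged by a shared mouse ortholog
* ``M4``  D-G-M-P-M-G-D diseases bridged by a shared mouse phenotype

A meta-path instance is a concrete walk whose node and edge types match the
schema positionally.  Walks may revisit nodes (the degenerate d-g-d walk
back to the same disease is a valid instance and keeps every disease in its
own neighborhood); only the type pattern is constrained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import EDGE_ENDPOINTS, EdgeType, HeterogeneousGraph, NodeType

__all__ = ["MetaPathSchema", "SCHEMAS", "enumerate_metapath_instances",
           "DEFAULT_INSTANCE_CAP"]

#: default per-(target, schema) cap on stored instances; longer schemas can
#: explode combinatorially, and a seeded uniform subsample preserves the
#: expectation of the attention aggregate while bounding memory
DEFAULT_INSTANCE_CAP = 128


@dataclass(frozen=True)
class MetaPathSchema:
    """Node-type sequence plus the edge types joining consecutive positions.

    ``edge_signs`` record whether each hop follows the edge layer's canonical
    orientation (+1) or reverses it (-1); the relational rotation encoder
    conjugates the relation phasor on reversed hops.
    """

    id: str
    node_types: tuple[NodeType, ...]
    edge_types: tuple[EdgeType, ...]
    edge_signs: tuple[int, ...]

    def __post_init__(self):
        if len(self.node_types) != len(self.edge_types) + 1:
            raise ValueError("node sequence must be one longer than edge sequence")
        if self.node_types[0] is not NodeType.DISEASE or \
                self.node_types[-1] is not NodeType.DISEASE:
            raise ValueError("meta-paths must start and end at a disease")

    @property
    def length(self) -> int:
        """Number of nodes on an instance."""
        return len(self.node_types)


def _schema(schema_id: str, type_word: str) -> MetaPathSchema:
    letter = {"D": NodeType.DISEASE, "G": NodeType.HGENE,
              "M": NodeType.MGENE, "P": NodeType.PHENO}
    node_types = tuple(letter[ch] for ch in type_word)
    edge_types, signs = [], []
    for a, b in zip(node_types, node_types[1:]):
        for et, (ta, tb) in EDGE_ENDPOINTS.items():
            if (a, b) == (ta, tb):
                edge_types.append(et)
                signs.append(+1)
                break
            if (a, b) == (tb, ta):
                edge_types.append(et)
                signs.append(-1)
                break
        else:
            raise ValueError(f"no edge layer joins {a} and {b}")
    return MetaPathSchema(schema_id, node_types, tuple(edge_types), tuple(signs))


SCHEMAS: dict[str, MetaPathSchema] = {
    "M1": _schema("M1", "DGD"),
    "M2": _schema("M2", "DGGD"),
    "M3": _schema("M3", "DGMGD"),
    "M4": _schema("M4", "DGMPMGD"),
}


def enumerate_metapath_instances(graph: HeterogeneousGraph,
                                 schema: MetaPathSchema | str,
                                 target: str,
                                 cap: int | None = DEFAULT_INSTANCE_CAP,
                                 seed: int = 0) -> list[tuple[str, ...]]:
    """All typed walks from `target` that realize `schema`.

    Returns node-id tuples ``(t0, ..., tn)`` with ``t0 == target``.  The
    enumeration is breadth-first over sorted adjacency, so the full list is
    deterministic; when `cap` is given and exceeded, a uniform subsample of
    size `cap` is drawn with a generator seeded by `seed` (order preserved).
    """
    if isinstance(schema, str):
        try:
            schema = SCHEMAS[schema]
        except KeyError:
            raise ValueError(f"unknown meta-path schema {schema!r}") from None
    if target not in graph.nodes:
        raise ValueError(f"unknown target node {target!r}")
    if graph.nodes[target] is not NodeType.DISEASE:
        raise ValueError(f"target {target!r} has type "
                         f"{graph.nodes[target].value}, expected DISEASE")
    walks: list[tuple[str, ...]] = [(target,)]
    for edge_type in schema.edge_types:
        nxt: list[tuple[str, ...]] = []
        for walk in walks:
            for nb in graph.neighbors(walk[-1], edge_type):
                nxt.append(walk + (nb,))
        walks = nxt
        if not walks:
            return []
    if cap is not None and len(walks) > cap:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(walks), size=cap, replace=False))
        walks = [walks[i] for i in keep]
    return walks
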