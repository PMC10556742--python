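"""Typed heterogeneous biological network.

Four node types — human diseases, human genes, mouse genes, mouse
phenotypes — joined by four undirected edge layers:

* ``DG``: disease - human gene association
* ``GG``: human gene - human gene (protein-protein interaction, weight 1.0)
* ``GM``: human gene - mouse gene (orthology)
* ``MP``: mouse gene - mouse phenotype association

The container keeps a per-edge-type adjacency index, which is what the
typed-walk (meta-path instance) enumeration traverses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

logger = logging.getLogger(__name__)


class NodeType(str, Enum):
    DISEASE = "DISEASE"
    HGENE = "HGENE"
    MGENE = "MGENE"
    PHENO = "PHENO"


class EdgeType(str, Enum):
    DG = "DG"
    GG = "GG"
    GM = "GM"
    MP = "MP"


#: endpoint node types demanded by each edge layer (unordered for GG)
EDGE_ENDPOINTS: dict[EdgeType, tuple[NodeType, NodeType]] = {
    EdgeType.DG: (NodeType.DISEASE, NodeType.HGENE),
    EdgeType.GG: (NodeType.HGENE, NodeType.HGENE),
    EdgeType.GM: (NodeType.HGENE, NodeType.MGENE),
    EdgeType.MP: (NodeType.MGENE, NodeType.PHENO),
}


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class HeterogeneousGraph:
    """Typed nodes, typed undirected edges stored once, per-type adjacency."""

    nodes: dict[str, NodeType] = field(default_factory=dict)
    #: canonical (u, v) -> weight, per edge type
    edges: dict[EdgeType, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {et: {} for et in EdgeType})
    #: node -> sorted neighbor list, per edge type
    adjacency: dict[EdgeType, dict[str, list[str]]] = field(
        default_factory=lambda: {et: {} for et in EdgeType})

    def add_node(self, node: str, node_type: NodeType) -> None:
        existing = self.nodes.get(node)
        if existing is not None and existing is not node_type:
            raise ValueError(
                f"type collision: node {node!r} claimed as both "
                f"{existing.value} and {node_type.value}")
        self.nodes[node] = node_type

    def add_edge(self, u: str, v: str, edge_type: EdgeType,
                 weight: float = 1.0) -> bool:
        """Insert an undirected edge; returns False if it was a duplicate."""
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r} ({edge_type.value})")
        ta, tb = EDGE_ENDPOINTS[edge_type]
        tu, tv = self.nodes.get(u), self.nodes.get(v)
        ok = (tu is ta and tv is tb) or (tu is tb and tv is ta)
        if not ok:
            raise ValueError(
                f"edge {u!r}-{v!r} of type {edge_type.value} requires endpoint "
                f"types {ta.value}/{tb.value}, got {tu and tu.value}/{tv and tv.value}")
        key = _canonical(u, v)
        if key in self.edges[edge_type]:
            return False
        self.edges[edge_type][key] = float(weight)
        self.adjacency[edge_type].setdefault(u, []).append(v)
        self.adjacency[edge_type].setdefault(v, []).append(u)
        return True

    def neighbors(self, node: str, edge_type: EdgeType) -> list[str]:
        return self.adjacency[edge_type].get(node, [])

    def nodes_of_type(self, node_type: NodeType) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t is node_type)

    def finalize(self) -> None:
        """Sort adjacency lists so traversal order is input-order invariant."""
        for et in EdgeType:
            for node in self.adjacency[et]:
                self.adjacency[et][node].sort()

    # -- summaries ---------------------------------------------------------

    def layer_summary(self) -> dict[str, dict[str, int]]:
        """Per-layer node/edge counts (the shape of a network census table)."""
        out: dict[str, dict[str, int]] = {}
        for et in EdgeType:
            touched = set()
            for u, v in self.edges[et]:
                touched.add(u)
                touched.add(v)
            out[et.value] = {"nodes": len(touched), "edges": len(self.edges[et])}
        out["total"] = {"nodes": len(self.nodes),
                        "edges": sum(len(e) for e in self.edges.values())}
        return out

    # -- serialization -----------------------------------------------------

    def write_tsv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "nodes.tsv", "w") as fh:
            fh.write("id\ttype\n")
            for node in sorted(self.nodes):
                fh.write(f"{node}\t{self.nodes[node].value}\n")
        with open(out_dir / "edges.tsv", "w") as fh:
            fh.write("src\tdst\tedge_type\tweight\n")
            for et in EdgeType:
                for (u, v), w in sorted(self.edges[et].items()):
                    fh.write(f"{u}\t{v}\t{et.value}\t{w:g}\n")

    @classmethod
    def read_tsv(cls, in_dir: str | Path) -> "HeterogeneousGraph":
        in_dir = Path(in_dir)
        graph = cls()
        with open(in_dir / "nodes.tsv") as fh:
            next(fh)
            for line in fh:
                node, type_name = line.rstrip("\n").split("\t")
                graph.add_node(node, NodeType(type_name))
        with open(in_dir / "edges.tsv") as fh:
            next(fh)
            for line in fh:
                u, v, et, w = line.rstrip("\n").split("\t")
                graph.add_edge(u, v, EdgeType(et), float(w))
        graph.finalize()
        return graph


def build_graph(dg, gg, gm, mp) -> HeterogeneousGraph:
    """Assemble the four edge layers into one typed graph.

    Each argument is an iterable of (u, v) or (u, v, weight) pairs already
    oriented as the layer demands (first endpoint of the first listed type).
    Node sets are unions over layers; an identifier claimed by two different
    node types is a fatal inconsistency.
    """
    graph = HeterogeneousGraph()
    layers = [(EdgeType.DG, dg), (EdgeType.GG, gg),
              (EdgeType.GM, gm), (EdgeType.MP, mp)]
    for edge_type, edge_list in layers:
        ta, tb = EDGE_ENDPOINTS[edge_type]
        skipped_loops = 0
        for row in edge_list:
            u, v = row[0], row[1]
            if u == v:
                skipped_loops += 1
                continue
            weight = float(row[2]) if len(row) > 2 else 1.0
            if edge_type is EdgeType.GG:
                weight = 1.0  # PPI edges are unweighted by convention
            graph.add_node(u, ta)
            graph.add_node(v, tb)
            graph.add_edge(u, v, edge_type, weight)
        if skipped_loops:
            logger.warning("layer %s: dropped %d self-loop rows",
                           edge_type.value, skipped_loops)
    graph.finalize()
    for layer, counts in graph.layer_summary().items():
        logger.info("layer %s: %d nodes, %d edges",
                    layer, counts["nodes"], counts["edges"])
    return graph
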