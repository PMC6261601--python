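"""Core skeleton containers.

A skeleton is a node/edge graph traced through an EM volume.  Positions are
always stored in nanometres in dataset coordinates:

* x — mediolateral (the slicing axis; 0 at the lateral face, increasing medially),
* y — dorsoventral,
* z — anteroposterior.

Radii are per-node, in nanometres (half the annotated process diameter).
Trees need not be acyclic: merged annotations occasionally contain cycles,
and only operations that require a rooted tree (SWC/hoc export) reject them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx
import numpy as np

from .errors import IntegrityError

__all__ = ["SkeletonNode", "SkeletonTree", "Annotation"]


@dataclass
class SkeletonNode:
    """A single annotated point: id, position (nm), radius (nm), free-text comment."""

    id: int
    position: np.ndarray
    radius: float = 0.0
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")
        if self.radius < 0:
            raise ValueError(f"node {self.id}: radius must be >= 0")

    @property
    def is_soma(self) -> bool:
        """Soma flagging convention: the comment contains 'soma' (case-insensitive)."""
        return self.comment is not None and "soma" in self.comment.lower()


class SkeletonTree:
    """Node/edge graph with nm coordinates and per-node radii.

    Edges are unordered id pairs stored as sorted tuples; self-edges are
    rejected and every edge must reference existing nodes.
    """

    def __init__(self, name: str = "", nodes: Iterable[SkeletonNode] = (),
                 edges: Iterable[tuple[int, int]] = ()):
        self.name = name
        self.nodes: dict[int, SkeletonNode] = {}
        self.edges: set[tuple[int, int]] = set()
        for n in nodes:
            self.add_node(n)
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction -----------------------------------------------------
    def add_node(self, node: SkeletonNode) -> None:
        if node.id in self.nodes:
            raise IntegrityError(f"duplicate node id {node.id} in tree '{self.name}'")
        self.nodes[node.id] = node

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise IntegrityError(f"self-edge on node {a} in tree '{self.name}'")
        for nid in (a, b):
            if nid not in self.nodes:
                raise IntegrityError(
                    f"edge ({a}, {b}) in tree '{self.name}' references missing node {nid}")
        self.edges.add((a, b) if a < b else (b, a))

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[SkeletonNode]:
        return iter(self.nodes.values())

    def node_ids(self) -> list[int]:
        return sorted(self.nodes)

    def positions(self, order: Optional[list[int]] = None) -> np.ndarray:
        """(N, 3) array of node positions in nm, by sorted id unless `order` given."""
        ids = order if order is not None else self.node_ids()
        return np.array([self.nodes[i].position for i in ids], dtype=float).reshape(-1, 3)

    def radii(self, order: Optional[list[int]] = None) -> np.ndarray:
        ids = order if order is not None else self.node_ids()
        return np.array([self.nodes[i].radius for i in ids], dtype=float)

    def degree(self, nid: int) -> int:
        return sum(1 for e in self.edges if nid in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def copy(self, name: Optional[str] = None) -> "SkeletonTree":
        t = SkeletonTree(name if name is not None else self.name)
        for n in self.nodes.values():
            t.add_node(SkeletonNode(n.id, n.position.copy(), n.radius, n.comment))
        for a, b in self.edges:
            t.add_edge(a, b)
        return t

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every edge, nm."""
        if not self.edges:
            return np.zeros(0)
        out = np.empty(len(self.edges))
        for i, (a, b) in enumerate(sorted(self.edges)):
            out[i] = float(np.linalg.norm(self.nodes[a].position - self.nodes[b].position))
        return out

    def is_tree(self) -> bool:
        """Connected and acyclic (a rooted forest with a single root)."""
        if len(self.nodes) == 0:
            return True
        g = self.to_networkx()
        return nx.is_connected(g) and len(self.edges) == len(self.nodes) - 1


@dataclass
class Annotation:
    """A set of skeleton trees plus the voxel scale of the source dataset.

    ``voxel_scale`` is nm per voxel along (x, y, z); the study's dataset used
    11 x 11 nm pixels with a 25 nm cutting thickness.
    """

    trees: list[SkeletonTree] = field(default_factory=list)
    voxel_scale: np.ndarray = field(default_factory=lambda: np.array([11.0, 11.0, 25.0]))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxel_scale = np.asarray(self.voxel_scale, dtype=float)
        if self.voxel_scale.shape != (3,) or not np.all(self.voxel_scale > 0):
            raise ValueError("voxel_scale must be a strictly positive 3-vector")

    def all_nodes(self) -> Iterator[SkeletonNode]:
        for t in self.trees:
            yield from t
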