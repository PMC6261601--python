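"""Geometric primitives on skeletons.

Resampling to a maximum inter-node spacing, cable length, component
selection, and the frustum-based volume estimate used for the per-cell
volume table.
"""

from __future__ import annotations

import math
from typing import Optional

import networkx as nx
import numpy as np

from .errors import ValidationError
from .skeleton import SkeletonNode, SkeletonTree

__all__ = ["ResampledTree", "resample_max_spacing", "cable_length",
           "largest_component", "estimate_volume"]

NM3_PER_UM3 = 1e9


class ResampledTree(SkeletonTree):
    """A skeleton with every edge subdivided to a maximum spacing.

    ``source_edge`` maps each node id to the original edge (id pair) it was
    interpolated on, or ``None`` for nodes carried over unchanged.
    """

    def __init__(self, name: str = ""):
        super().__init__(name)
        self.source_edge: dict[int, Optional[tuple[int, int]]] = {}


def resample_max_spacing(tree: SkeletonTree, max_nm: float = 400.0) -> ResampledTree:
    """Subdivide every edge so no inter-node distance exceeds ``max_nm``.

    An edge of length L is replaced by ceil(L / max_nm) colinear sub-edges of
    equal length, with radii linearly interpolated between the endpoints.
    Original nodes are kept verbatim (no smoothing), so total cable length is
    preserved and the operation is idempotent.  The default 400 nm is the
    normalization the layer analysis assumes.
    """
    if max_nm <= 0:
        raise ValueError("max_nm must be > 0")
    out = ResampledTree(name=tree.name)
    for n in tree.nodes.values():
        out.add_node(SkeletonNode(n.id, n.position.copy(), n.radius, n.comment))
        out.source_edge[n.id] = None
    next_id = max(tree.nodes, default=0) + 1
    for a, b in sorted(tree.edges):
        na, nb = tree.nodes[a], tree.nodes[b]
        length = float(np.linalg.norm(nb.position - na.position))
        # small slack so an already-resampled edge is never re-split by
        # floating-point noise (keeps the operation idempotent)
        n_sub = max(1, math.ceil(length / max_nm - 1e-9))
        prev = a
        for i in range(1, n_sub):
            t = i / n_sub
            pos = na.position + t * (nb.position - na.position)
            rad = na.radius + t * (nb.radius - na.radius)
            out.add_node(SkeletonNode(next_id, pos, rad))
            out.source_edge[next_id] = (a, b) if a < b else (b, a)
            out.add_edge(prev, next_id)
            prev = next_id
            next_id += 1
        out.add_edge(prev, b)
    return out


def cable_length(tree: SkeletonTree) -> float:
    """Total cable: sum of Euclidean edge lengths, nm."""
    return float(tree.edge_lengths().sum())


def largest_component(tree: SkeletonTree) -> SkeletonTree:
    """The connected component with the greatest cable length.

    Cable length (not node count) decides, so the result is robust to
    uneven annotation density.  Ties break toward the component containing
    the lowest node id.
    """
    if len(tree) == 0:
        return tree.copy()
    g = tree.to_networkx()
    best_nodes: Optional[set] = None
    best_key: Optional[tuple] = None
    for comp in nx.connected_components(g):
        cab = sum(
            float(np.linalg.norm(tree.nodes[a].position - tree.nodes[b].position))
            for a, b in tree.edges if a in comp)
        key = (cab, -min(comp))
        if best_key is None or key > best_key:
            best_key, best_nodes = key, comp
    out = SkeletonTree(name=tree.name)
    for nid in sorted(best_nodes):
        n = tree.nodes[nid]
        out.add_node(SkeletonNode(n.id, n.position.copy(), n.radius, n.comment))
    for a, b in tree.edges:
        if a in best_nodes:
            out.add_edge(a, b)
    return out


def estimate_volume(tree: SkeletonTree, exclude_soma: bool = True) -> float:
    """Neurite volume in μm³ from node radii, one truncated cone per edge.

    Each edge contributes the frustum volume pi * L * (r1² + r1 r2 + r2²) / 3.
    Overlap at branch points is not corrected.  With ``exclude_soma`` every
    edge touching a soma-flagged node is dropped, mirroring the study's
    exclusion of the soma reconstruction from the per-cell volume.

    Raises :class:`ValidationError` when an included edge has a zero-radius
    endpoint — radius 0 means the diameter annotation is missing, and the
    estimate would silently be wrong.
    """
    soma = {nid for nid, n in tree.nodes.items() if n.is_soma}
    total_nm3 = 0.0
    bad: set[int] = set()
    for a, b in sorted(tree.edges):
        if exclude_soma and (a in soma or b in soma):
            continue
        na, nb = tree.nodes[a], tree.nodes[b]
        if na.radius <= 0:
            bad.add(a)
        if nb.radius <= 0:
            bad.add(b)
        length = float(np.linalg.norm(na.position - nb.position))
        r1, r2 = na.radius, nb.radius
        total_nm3 += math.pi * length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    if bad:
        raise ValidationError(
            f"tree '{tree.name}': zero radius on non-soma node(s) {sorted(bad)}")
    return total_nm3 / NM3_PER_UM3
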