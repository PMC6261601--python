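"""Skeleton file I/O: NML (KNOSSOS/webKnossos), SWC, hoc export, and part merging.

NML stores positions and radii in voxels of the source dataset; on read they
are converted to nanometres with the file's ``<scale>`` element (radius uses
the x scale).  SWC follows the common convention of micrometre units and a
rooted forest per file.  The hoc exporter writes one section per unbranched
run, the format the study used to hand reconstructions to Amira/NEURON-style
viewers.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import IO, Optional, Union

import networkx as nx
import numpy as np
from lxml import etree

from .errors import IntegrityError, NmlParseError, StructureError, UnresolvedMatchError
from .skeleton import Annotation, SkeletonNode, SkeletonTree

__all__ = [
    "read_nml", "write_nml", "read_swc", "write_swc", "export_hoc",
    "merge_parts", "MergeResult",
]

PathOrStream = Union[str, IO]


def _open(stream: PathOrStream, mode: str):
    if isinstance(stream, (str,)):
        return open(stream, mode), True
    return stream, False


# ---------------------------------------------------------------------------
# NML
# ---------------------------------------------------------------------------

def read_nml(stream: PathOrStream) -> Annotation:
    """Parse a KNOSSOS/webKnossos NML file into an :class:`Annotation` (nm units).

    Accepts both dialects (``<things>`` root with ``thing`` children; node
    comments either as a ``comment`` attribute or a top-level ``<comments>``
    block).  Positions and radii are converted voxel -> nm using the file's
    scale element; nodes without a radius attribute get radius 0 and their
    ids are recorded under ``metadata['nodes_without_radius']``.
    """
    fh, close = _open(stream, "rb")
    try:
        try:
            doc = etree.parse(fh)
        except etree.XMLSyntaxError as exc:
            raise NmlParseError(f"malformed NML XML: {exc}") from exc
    finally:
        if close:
            fh.close()

    root = doc.getroot()
    scale_el = root.find(".//scale")
    if scale_el is not None:
        scale = np.array([float(scale_el.get(ax, 1.0)) for ax in "xyz"])
    else:
        scale = np.array([1.0, 1.0, 1.0])

    # webKnossos keeps comments in a separate top-level block
    comments: dict[int, str] = {}
    for c in root.findall(".//comments/comment"):
        try:
            comments[int(c.get("node"))] = c.get("content", "")
        except (TypeError, ValueError):
            continue

    no_radius: list[int] = []
    trees: list[SkeletonTree] = []
    for thing in root.iter("thing"):
        tree = SkeletonTree(name=thing.get("name", thing.get("id", "")))
        for nd in thing.findall("./nodes/node"):
            nid = int(nd.get("id"))
            pos_vox = np.array([float(nd.get(ax, 0.0)) for ax in "xyz"])
            rad_attr = nd.get("radius")
            if rad_attr is None:
                radius = 0.0
                no_radius.append(nid)
            else:
                radius = float(rad_attr) * scale[0]
            comment = nd.get("comment", comments.get(nid))
            tree.add_node(SkeletonNode(nid, pos_vox * scale, radius, comment))
        for ed in thing.findall("./edges/edge"):
            src, tgt = int(ed.get("source")), int(ed.get("target"))
            for nid in (src, tgt):
                if nid not in tree.nodes:
                    raise IntegrityError(
                        f"NML tree '{tree.name}': edge ({src}, {tgt}) references "
                        f"missing node {nid}")
            tree.add_edge(src, tgt)
        trees.append(tree)

    meta = {}
    exp = root.find(".//experiment")
    if exp is not None and exp.get("name"):
        meta["experiment"] = exp.get("name")
    if no_radius:
        meta["nodes_without_radius"] = no_radius
    return Annotation(trees=trees, voxel_scale=scale, metadata=meta)


def write_nml(annotation: Annotation, stream: PathOrStream) -> None:
    """Write an Annotation as KNOSSOS-flavor NML (voxel units, nm -> voxel)."""
    scale = annotation.voxel_scale
    root = etree.Element("things")
    params = etree.SubElement(root, "parameters")
    if "experiment" in annotation.metadata:
        etree.SubElement(params, "experiment", name=str(annotation.metadata["experiment"]))
    etree.SubElement(params, "scale", x=f"{scale[0]:.10g}",
                     y=f"{scale[1]:.10g}", z=f"{scale[2]:.10g}")
    comments_el = etree.Element("comments")
    for i, tree in enumerate(annotation.trees, start=1):
        thing = etree.SubElement(root, "thing", id=str(i), name=tree.name)
        nodes_el = etree.SubElement(thing, "nodes")
        for nid in tree.node_ids():
            n = tree.nodes[nid]
            vox = n.position / scale
            etree.SubElement(
                nodes_el, "node", id=str(n.id),
                radius=f"{n.radius / scale[0]:.10g}",
                x=f"{vox[0]:.10g}", y=f"{vox[1]:.10g}", z=f"{vox[2]:.10g}")
            if n.comment:
                etree.SubElement(comments_el, "comment", node=str(n.id), content=n.comment)
        edges_el = etree.SubElement(thing, "edges")
        for a, b in sorted(tree.edges):
            etree.SubElement(edges_el, "edge", source=str(a), target=str(b))
    root.append(comments_el)
    payload = etree.tostring(root, pretty_print=True, xml_declaration=True,
                             encoding="UTF-8")
    fh, close = _open(stream, "wb")
    try:
        fh.write(payload)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(stream: PathOrStream) -> SkeletonTree:
    """Read a single-root SWC file (μm) into a SkeletonTree (nm)."""
    fh, close = _open(stream, "r")
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()
    tree = SkeletonTree(name="swc")
    parents: dict[int, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise NmlParseError(f"SWC line {lineno}: expected 7 columns, got {len(parts)}")
        nid, ntype = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        comment = "soma" if ntype == 1 else None
        tree.add_node(SkeletonNode(nid, np.array([x, y, z]) * 1000.0, r * 1000.0, comment))
        parents[nid] = parent
    for nid, parent in parents.items():
        if parent == -1:
            continue
        if parent not in tree.nodes:
            raise IntegrityError(f"SWC node {nid} references missing parent {parent}")
        tree.add_edge(nid, parent)
    return tree


def write_swc(tree: SkeletonTree, stream: PathOrStream) -> None:
    """Write an acyclic connected tree as SWC (μm units, root parent -1).

    Nodes are renumbered 1..N in breadth-first order from the lowest-id node.
    """
    if len(tree) and not tree.is_tree():
        raise StructureError(
            f"tree '{tree.name}' is not a connected acyclic tree; cannot write SWC")
    lines = ["# generated by lptc", "# id type x y z radius parent  (μm)"]
    if len(tree):
        g = tree.to_networkx()
        root = min(tree.nodes)
        order = list(nx.bfs_tree(g, root))
        renum = {old: i + 1 for i, old in enumerate(order)}
        preds = dict(nx.bfs_predecessors(g, root))
        for old in order:
            n = tree.nodes[old]
            parent = renum[preds[old]] if old in preds else -1
            ntype = 1 if n.is_soma else 3
            p = n.position / 1000.0
            lines.append(f"{renum[old]} {ntype} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                         f"{n.radius / 1000.0:.6f} {parent}")
    payload = "\n".join(lines) + "\n"
    fh, close = _open(stream, "w")
    try:
        fh.write(payload)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# hoc export
# ---------------------------------------------------------------------------

def _unbranched_runs(tree: SkeletonTree) -> list[list[int]]:
    """Decompose a tree into maximal unbranched runs of node ids.

    Run boundaries are nodes of degree != 2; boundary nodes are duplicated
    into every run that touches them.
    """
    g = tree.to_networkx()
    if g.number_of_nodes() == 1:
        return [list(g.nodes)]
    boundary = {n for n in g if g.degree(n) != 2}
    if not boundary:  # pure cycle — caller rejects beforehand
        boundary = {min(g.nodes)}
    runs: list[list[int]] = []
    visited_edges: set[tuple[int, int]] = set()
    for start in sorted(boundary):
        for nb in sorted(g.neighbors(start)):
            e = (start, nb) if start < nb else (nb, start)
            if e in visited_edges:
                continue
            run = [start, nb]
            visited_edges.add(e)
            prev, cur = start, nb
            while cur not in boundary:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                e = (cur, nxt) if cur < nxt else (nxt, cur)
                visited_edges.add(e)
                run.append(nxt)
                prev, cur = cur, nxt
            runs.append(run)
    return runs


def export_hoc(tree: SkeletonTree, stream: PathOrStream) -> None:
    """Export an acyclic connected tree as a hoc morphology script.

    One ``create``d section per unbranched run; each section lists its 3D
    points with diameters (μm).  Branch points appear in every section they
    bound, so the total point count is node count plus duplicates.
    """
    if len(tree) and not tree.is_tree():
        raise StructureError(
            f"tree '{tree.name}' is not a connected acyclic tree; cannot export hoc")
    runs = _unbranched_runs(tree) if len(tree) else []
    # orient runs away from a root and record parentage for connect statements
    lines = [f"// hoc export of '{tree.name}' ({len(tree)} nodes, {len(runs)} sections)"]
    if runs:
        lines.append(f"create sect[{len(runs)}]")
        root = min(tree.nodes)
        # BFS over runs: a run is attached at whichever end is already placed
        placed = {root}
        ordered: list[tuple[int, list[int], Optional[int], ]] = []
        remaining = list(range(len(runs)))
        parent_of: dict[int, Optional[tuple[int, int]]] = {}
        while remaining:
            progressed = False
            for ri in list(remaining):
                run = runs[ri]
                if run[0] in placed or run[-1] in placed:
                    if run[-1] in placed and run[0] not in placed:
                        run.reverse()
                    parent_of[ri] = None
                    for pj, (prun, _) in enumerate(ordered):
                        if runs[prun][-1] == run[0] or runs[prun][0] == run[0]:
                            parent_of[ri] = (pj, 1 if runs[prun][-1] == run[0] else 0)
                            break
                    ordered.append((ri, run))
                    placed.update(run)
                    remaining.remove(ri)
                    progressed = True
            if not progressed:  # disconnected guard; is_tree() should prevent this
                raise StructureError("could not order sections; tree disconnected?")
        for si, (ri, run) in enumerate(ordered):
            lines.append(f"sect[{si}] {{")
            lines.append("  pt3dclear()")
            for nid in run:
                n = tree.nodes[nid]
                p = n.position / 1000.0
                lines.append(f"  pt3dadd({p[0]:.6f}, {p[1]:.6f}, {p[2]:.6f}, "
                             f"{2.0 * n.radius / 1000.0:.6f})")
            lines.append("}")
        for si, (ri, run) in enumerate(ordered):
            par = parent_of.get(ri)
            if par is not None:
                pj, end = par
                lines.append(f"connect sect[{si}](0), sect[{pj}]({end})")
    payload = "\n".join(lines) + "\n"
    fh, close = _open(stream, "w")
    try:
        fh.write(payload)
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# merging lateral/medial dataset parts
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    """Output of :func:`merge_parts`: merged annotation plus bookkeeping."""

    annotation: Annotation
    id_map: dict = field(default_factory=dict)      # old medial id -> new id
    provenance: dict = field(default_factory=dict)  # node id -> 'lateral' | 'medial'


def merge_parts(lateral: Annotation, medial: Annotation, seam: float,
                tolerance: float, axis: int = 0) -> MergeResult:
    """Join reconstructions split across two sub-datasets along a seam plane.

    The study's volume was cut into a lateral and a medial dataset; every
    cell therefore has two part-skeletons.  Tree endpoints (degree <= 1)
    lying within ``tolerance`` (nm) of the seam plane on either side are
    paired by proximity; a unique pair within ``tolerance`` Euclidean
    distance is joined by a bridging edge.  Ambiguous multi-way matches
    raise :class:`UnresolvedMatchError` listing the candidates.

    Medial node ids are renumbered with an offset to avoid collisions;
    ``id_map`` records the renumbering and ``provenance`` records the origin
    part of every output node.  No node is ever dropped.
    """
    offset = max((nid for t in lateral.trees for nid in t.nodes), default=0)

    provenance: dict[int, str] = {}
    id_map: dict[int, int] = {}
    trees: list[SkeletonTree] = []
    for t in lateral.trees:
        c = t.copy()
        trees.append(c)
        for nid in c.nodes:
            provenance[nid] = "lateral"
    n_lateral = len(trees)
    for t in medial.trees:
        c = SkeletonTree(name=t.name)
        for n in t.nodes.values():
            new_id = n.id + offset
            id_map[n.id] = new_id
            c.add_node(SkeletonNode(new_id, n.position.copy(), n.radius, n.comment))
            provenance[new_id] = "medial"
        for a, b in t.edges:
            c.add_edge(a + offset, b + offset)
        trees.append(c)

    def seam_endpoints(tree_indices):
        out = []  # (tree_idx, node_id, position)
        for ti in tree_indices:
            t = trees[ti]
            for nid, n in t.nodes.items():
                if t.degree(nid) <= 1 and abs(n.position[axis] - seam) <= tolerance:
                    out.append((ti, nid, n.position))
        return out

    lat_eps = seam_endpoints(range(n_lateral))
    med_eps = seam_endpoints(range(n_lateral, len(trees)))

    pairs: list[tuple[int, int, int, int]] = []  # (lat_tree, lat_node, med_tree, med_node)
    for lt, ln, lp in lat_eps:
        cands = [(mt, mn) for mt, mn, mp in med_eps
                 if np.linalg.norm(lp - mp) <= tolerance]
        if len(cands) > 1:
            raise UnresolvedMatchError(
                f"lateral endpoint {ln} matches {len(cands)} medial endpoints "
                f"within {tolerance} nm: {[c[1] for c in cands]}",
                candidates=[c[1] for c in cands])
        if cands:
            pairs.append((lt, ln, cands[0][0], cands[0][1]))
    matched_medial = [p[3] for p in pairs]
    if len(set(matched_medial)) != len(matched_medial):
        dup = [m for m in matched_medial if matched_medial.count(m) > 1]
        raise UnresolvedMatchError(
            f"medial endpoint(s) {sorted(set(dup))} match multiple lateral endpoints",
            candidates=sorted(set(dup)))

    # union-find over trees, then rebuild merged trees with bridging edges
    parent = list(range(len(trees)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for lt, _, mt, _ in pairs:
        parent[find(mt)] = find(lt)

    groups: dict[int, list[int]] = {}
    for i in range(len(trees)):
        groups.setdefault(find(i), []).append(i)

    merged: list[SkeletonTree] = []
    for gi in sorted(groups):
        members = groups[gi]
        if len(members) == 1:
            merged.append(trees[members[0]])
            continue
        name = "+".join(trees[m].name for m in members if trees[m].name)
        out = SkeletonTree(name=name)
        for m in members:
            for n in trees[m].nodes.values():
                out.add_node(n)
            for a, b in trees[m].edges:
                out.add_edge(a, b)
        for lt, ln, mt, mn in pairs:
            if lt in members:
                out.add_edge(ln, mn)
        merged.append(out)

    meta = dict(lateral.metadata)
    meta["merged_pairs"] = [(ln, mn) for _, ln, _, mn in pairs]
    ann = Annotation(trees=merged, voxel_scale=lateral.voxel_scale, metadata=meta)
    return MergeResult(annotation=ann, id_map=id_map, provenance=provenance)
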