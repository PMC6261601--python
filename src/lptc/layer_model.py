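"""Two-surface layer model of the lobula plate.

The lobula plate is modelled as the slab between an anterior and a posterior
surface, each interpolated from an expert outline skeleton.  A skeleton node
inside the footprint of both surfaces gets a normalized anteroposterior
depth d (0 on the anterior surface, 1 on the posterior), and the slab is
quartered into the four direction-selective layers: d in [0, .25) is
layer 1 (most anterior), ..., [.75, 1] is layer 4.

Axis convention (configurable at the call sites that need it): dataset
x = mediolateral (slicing axis, lateral face at 0), y = dorsoventral,
z = anteroposterior.  Surfaces are scalar fields z = f(x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateOutlineError, EmptyHistogramError, ModelError
from .skeleton import SkeletonNode, SkeletonTree

__all__ = [
    "PlateOutline", "LayerModel", "DepthAssignment", "split_outline",
    "build_layer_model", "assign_depth", "layer_histogram",
    "depth_boxplot_stats", "layer_report", "slice_to_depth", "sagittal_clip",
    "HISTOGRAM_BINS",
]

HISTOGRAM_BINS = ("layer1", "layer2", "layer3", "layer4", "anterior", "posterior")


@dataclass
class PlateOutline:
    """Point cloud delimiting the plate, optionally with per-point side labels.

    ``side_label`` entries, when present, are the strings ``'anterior'`` /
    ``'posterior'``.
    """

    points: np.ndarray                      # (N, 3) nm
    side_label: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.side_label is not None:
            self.side_label = np.asarray(self.side_label, dtype=object)
            if len(self.side_label) != len(self.points):
                raise ValueError("side_label length must match points")

    @classmethod
    def from_trees(cls, trees: Sequence[SkeletonTree]) -> "PlateOutline":
        """Collect outline points from skeleton trees; node comments containing
        'anterior'/'posterior' become side labels (all-or-nothing)."""
        pts, labels = [], []
        for t in trees:
            for n in t:
                pts.append(n.position)
                c = (n.comment or "").lower()
                labels.append("anterior" if "anterior" in c
                              else "posterior" if "posterior" in c else None)
        lab = np.array(labels, dtype=object)
        if any(l is None for l in labels):
            lab = None
        return cls(points=np.array(pts), side_label=lab)


def split_outline(outline: PlateOutline, min_separation_nm: float = 1.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Split the outline cloud into anterior and posterior surface points.

    With side labels the split follows the labels.  Otherwise a quadratic
    mid-surface z = g(x, y) is fit by least squares and points are split by
    the sign of their residual (anterior = smaller z).  A cloud whose
    residuals never exceed ``min_separation_nm`` is a single surface, not a
    slab, and is rejected.
    """
    pts = outline.points
    if len(pts) < 8:
        raise DegenerateOutlineError(f"outline has {len(pts)} points; need >= 8")
    if outline.side_label is not None:
        ant = pts[outline.side_label == "anterior"]
        post = pts[outline.side_label == "posterior"]
    else:
        x, y, z = pts.T
        design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
        resid = z - design @ coef
        if np.max(np.abs(resid)) <= min_separation_nm:
            raise DegenerateOutlineError(
                "outline points are (near-)coplanar along z; cannot split into "
                "two surfaces")
        ant, post = pts[resid < 0], pts[resid >= 0]
    if len(ant) == 0 or len(post) == 0:
        raise DegenerateOutlineError(
            f"degenerate split: {len(ant)} anterior / {len(post)} posterior points")
    return ant, post


class LayerModel:
    """Piecewise-linear anterior/posterior surfaces over the (x, y) plane.

    Each surface is a linear interpolant over the Delaunay triangulation of
    its support points; the footprint is the region where both are defined.
    """

    def __init__(self, anterior_pts: np.ndarray, posterior_pts: np.ndarray):
        anterior_pts = np.asarray(anterior_pts, dtype=float).reshape(-1, 3)
        posterior_pts = np.asarray(posterior_pts, dtype=float).reshape(-1, 3)
        for name, p in (("anterior", anterior_pts), ("posterior", posterior_pts)):
            if len(p) < 4:
                raise DegenerateOutlineError(
                    f"{name} surface needs >= 4 support points, got {len(p)}")
        try:
            self._tri_a = Delaunay(anterior_pts[:, :2])
            self._tri_p = Delaunay(posterior_pts[:, :2])
        except QhullError as exc:
            raise DegenerateOutlineError(
                f"surface support points are degenerate in (x, y): {exc}") from exc
        self._fa = LinearNDInterpolator(self._tri_a, anterior_pts[:, 2])
        self._fp = LinearNDInterpolator(self._tri_p, posterior_pts[:, 2])
        self._support = np.vstack([anterior_pts[:, :2], posterior_pts[:, :2]])
        self._check_thickness()

    def _check_thickness(self) -> None:
        # probe support points and a coarse grid over the footprint
        lo = self._support.min(axis=0)
        hi = self._support.max(axis=0)
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 25),
                             np.linspace(lo[1], hi[1], 25))
        probe = np.vstack([self._support, np.column_stack([gx.ravel(), gy.ravel()])])
        inside = self.in_footprint(probe)
        if not np.any(inside):
            raise ModelError("the two surface footprints do not overlap")
        th = self.thickness(probe[inside])
        if np.any(th <= 0):
            bad = probe[inside][np.argmin(th)]
            raise ModelError(
                f"surfaces cross or touch near (x={bad[0]:.0f} nm, y={bad[1]:.0f} nm): "
                f"thickness {th.min():.1f} nm")

    # -- evaluation -------------------------------------------------------
    def anterior(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(self._fa(np.atleast_2d(xy)))

    def posterior(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(self._fp(np.atleast_2d(xy)))

    def thickness(self, xy: np.ndarray) -> np.ndarray:
        return self.posterior(xy) - self.anterior(xy)

    def in_footprint(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (self._tri_a.find_simplex(xy) >= 0) & (self._tri_p.find_simplex(xy) >= 0)

    def depth(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(in_footprint, normalized depth) for (N, 3) nm points; depth is NaN
        outside the footprint."""
        points = np.atleast_2d(points)
        xy, z = points[:, :2], points[:, 2]
        inside = self.in_footprint(xy)
        d = np.full(len(points), np.nan)
        if np.any(inside):
            za = self.anterior(xy[inside])
            zp = self.posterior(xy[inside])
            d[inside] = (z[inside] - za) / (zp - za)
        return inside, d


def build_layer_model(anterior_pts: np.ndarray, posterior_pts: np.ndarray) -> LayerModel:
    """Interpolate the two point sets into a :class:`LayerModel`."""
    return LayerModel(anterior_pts, posterior_pts)


@dataclass
class DepthAssignment:
    """Per-node footprint flag, normalized depth and layer.

    ``layer`` is 1..4 for nodes with 0 <= d <= 1 and 0 otherwise;
    ``category`` is the histogram bin name ('layer1'..'layer4', 'anterior',
    'posterior') or 'outside' for nodes off the footprint.
    """

    node_ids: np.ndarray
    in_footprint: np.ndarray
    depth: np.ndarray
    layer: np.ndarray
    category: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.category is None:
            cat = np.full(len(self.node_ids), "outside", dtype=object)
            inf = self.in_footprint
            cat[inf & (self.depth < 0)] = "anterior"
            cat[inf & (self.depth > 1)] = "posterior"
            for l in (1, 2, 3, 4):
                cat[self.layer == l] = f"layer{l}"
            self.category = cat


def assign_depth(tree: SkeletonTree, model: LayerModel) -> DepthAssignment:
    """Project every node into the layer model.

    Depth is evaluated along the z axis at the node's (x, y): the node
    "overlaps both surfaces" exactly when (x, y) lies in both triangulations.
    Layers are the half-open quarters [0,.25), [.25,.5), [.5,.75), [.75,1],
    with d = 1 belonging to layer 4.  The tree should be resampled (<= 400 nm
    spacing) so node counts approximate cable length.
    """
    ids = np.array(tree.node_ids())
    pts = tree.positions(order=list(ids))
    inside, d = model.depth(pts)
    layer = np.zeros(len(ids), dtype=int)
    ok = inside & (d >= 0) & (d <= 1)
    layer[ok] = np.minimum(np.floor(4 * d[ok]).astype(int) + 1, 4)
    return DepthAssignment(node_ids=ids, in_footprint=inside, depth=d, layer=layer)


def layer_histogram(assignment: DepthAssignment) -> pd.Series:
    """Node-count fractions over layer1..4 / anterior-of / posterior-of plate.

    Fractions are over in-footprint nodes and sum to 1.
    """
    n = int(np.count_nonzero(assignment.in_footprint))
    if n == 0:
        raise EmptyHistogramError("no nodes inside the plate footprint")
    counts = pd.Series(0.0, index=list(HISTOGRAM_BINS))
    vals, cnts = np.unique(assignment.category[assignment.in_footprint],
                           return_counts=True)
    for v, c in zip(vals, cnts):
        counts[v] = c / n
    return counts


def _tukey_hinges(x: np.ndarray) -> tuple[float, float, float]:
    """Median and Tukey hinges (each half includes the median when n is odd)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    med = float(np.median(x))
    half = (n + 1) // 2
    return float(np.median(x[:half])), med, float(np.median(x[n - half:]))


def depth_boxplot_stats(assignment: DepthAssignment,
                        window: tuple[float, float] = (-0.5, 1.5)) -> dict:
    """Boxplot statistics of normalized depth.

    Nodes further than 50% anterior or posterior of the plate (d outside
    [-0.5, 1.5]) are excluded before computing median, Tukey-hinge
    quartiles, 1.5 x IQR whiskers and outliers.
    """
    d = assignment.depth[assignment.in_footprint]
    d = d[~np.isnan(d)]
    d = d[(d >= window[0]) & (d <= window[1])]
    if len(d) == 0:
        raise EmptyHistogramError("no depth values inside the inclusion window")
    q1, med, q3 = _tukey_hinges(d)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = d[(d >= lo_fence) & (d <= hi_fence)]
    return {
        "n": int(len(d)),
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(v) for v in d[(d < lo_fence) | (d > hi_fence)]),
    }


def layer_report(tree: SkeletonTree, model: LayerModel,
                 resample_nm: float = 400.0) -> pd.DataFrame:
    """Layer fractions under three weightings: raw nodes, resampled nodes, cable.

    Published layer percentages rarely say whether they count annotation
    nodes, spacing-normalized nodes, or cable length; this report computes
    all three (rows) over the six histogram bins (columns) to bracket any
    printed value.  Cable weighting assigns each resampled edge's length to
    the bin of its midpoint.
    """
    from .skeleton_ops import resample_max_spacing

    res = resample_max_spacing(tree, resample_nm)
    raw = layer_histogram(assign_depth(tree, model))
    resampled = layer_histogram(assign_depth(res, model))

    cable = pd.Series(0.0, index=list(HISTOGRAM_BINS))
    mids, weights = [], []
    for a, b in sorted(res.edges):
        pa, pb = res.nodes[a].position, res.nodes[b].position
        mids.append((pa + pb) / 2.0)
        weights.append(float(np.linalg.norm(pb - pa)))
    inside, d = model.depth(np.array(mids).reshape(-1, 3))
    weights = np.asarray(weights)
    total = 0.0
    for i in range(len(mids)):
        if not inside[i]:
            continue
        total += weights[i]
        if d[i] < 0:
            cable["anterior"] += weights[i]
        elif d[i] > 1:
            cable["posterior"] += weights[i]
        else:
            cable[f"layer{min(int(4 * d[i]) + 1, 4)}"] += weights[i]
    if total > 0:
        cable /= total
    return pd.DataFrame({"raw_nodes": raw, "resampled_nodes": resampled,
                         "cable": cable}).T


def slice_to_depth(slice_index: int, thickness_nm: float = 25.0) -> float:
    """Depth of a slice from the lateral end of the dataset, in μm.

    The study cut 25 nm slices lateral -> medial, so slice 3960 sits at
    99.0 μm.
    """
    if slice_index < 0:
        raise ValueError("slice_index must be >= 0")
    return slice_index * thickness_nm / 1000.0


def sagittal_clip(trees: Sequence[SkeletonTree], window_um: float = 118.0,
                  axis: int = 0) -> list[SkeletonTree]:
    """Restrict skeletons to the most lateral ``window_um`` micrometres.

    Nodes beyond the window along ``axis`` are removed and dangling edges
    dropped; used for the normalized sagittal renders.
    """
    limit = window_um * 1000.0
    out = []
    for t in trees:
        keep = {nid for nid, n in t.nodes.items() if n.position[axis] <= limit}
        c = SkeletonTree(name=t.name)
        for nid in sorted(keep):
            n = t.nodes[nid]
            c.add_node(SkeletonNode(n.id, n.position.copy(), n.radius, n.comment))
        for a, b in t.edges:
            if a in keep and b in keep:
                c.add_edge(a, b)
        out.append(c)
    return out
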