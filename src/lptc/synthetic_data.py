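"""Synthetic inputs with known ground truth for every pipeline stage.

The original EM volume is not required to exercise the pipeline: these
generators produce (i) a curved-slab plate outline with closed-form
surfaces, (ii) radius-annotated tangential-cell skeletons whose cable is
placed with prescribed per-layer fractions, (iii) bundles of intertwined
tubular axons with an analytically known pairwise wall-to-wall gap, and
(iv) grids of overlapping noisy image tiles with known true positions.
Every generator is deterministic given its seed and returns machine-
readable ground truth usable as a test oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import SpecError
from .layer_model import HISTOGRAM_BINS, PlateOutline
from .skeleton import SkeletonNode, SkeletonTree

__all__ = [
    "SlabSurfaces", "gen_plate_outline",
    "CellSpec", "gen_tangential_cell", "measure_cable_fractions",
    "BundleSpec", "gen_axon_bundle", "make_parallel_bundle", "make_braid_spec",
    "gen_tile_grid",
]

UM = 1000.0  # nm per μm


# ---------------------------------------------------------------------------
# plate outline with analytic surfaces
# ---------------------------------------------------------------------------

@dataclass
class SlabSurfaces:
    """Closed-form anterior/posterior surfaces of a synthetic plate.

    anterior(x, y) = z0 + A sin(2πx/Lx) sin(2πy/Ly); the posterior surface
    is parallel at constant thickness.  All lengths nm.
    """

    z0_nm: float
    amplitude_nm: float
    thickness_nm: float
    extent_nm: tuple[float, float]

    def anterior(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        lx, ly = self.extent_nm
        return (self.z0_nm + self.amplitude_nm
                * np.sin(2 * np.pi * xy[:, 0] / lx)
                * np.sin(2 * np.pi * xy[:, 1] / ly))

    def posterior(self, xy: np.ndarray) -> np.ndarray:
        return self.anterior(xy) + self.thickness_nm

    def z_at_depth(self, xy: np.ndarray, d) -> np.ndarray:
        return self.anterior(xy) + np.asarray(d) * self.thickness_nm

    def depth(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return (points[:, 2] - self.anterior(points[:, :2])) / self.thickness_nm


def gen_plate_outline(curvature_um: float = 5.0, thickness_um: float = 20.0,
                      extent_um: tuple[float, float] = (120.0, 150.0),
                      n_points: int = 200, seed: int = 0,
                      z0_um: float = 40.0, z_noise_um: float = 0.0
                      ) -> tuple[PlateOutline, SlabSurfaces]:
    """Sample an expert-outline point cloud from analytic slab surfaces.

    ``curvature_um`` is the amplitude of the sinusoidal corrugation (0 gives
    a flat slab).  Points lie on a regular (x, y) grid covering the full
    extent — so the model footprint is the extent rectangle — with side
    labels attached; ``z_noise_um`` optionally roughens the sampled z.
    Returns the outline and the closed-form surfaces for oracle use.
    """
    if thickness_um <= 0:
        raise SpecError("thickness must be > 0")
    rng = np.random.default_rng(seed)
    surf = SlabSurfaces(z0_nm=z0_um * UM, amplitude_nm=curvature_um * UM,
                        thickness_nm=thickness_um * UM,
                        extent_nm=(extent_um[0] * UM, extent_um[1] * UM))
    per_side = max(n_points // 2, 4)
    nx = max(int(round(math.sqrt(per_side * extent_um[0] / extent_um[1]))), 2)
    ny = max(int(math.ceil(per_side / nx)), 2)
    gx, gy = np.meshgrid(np.linspace(0, surf.extent_nm[0], nx),
                         np.linspace(0, surf.extent_nm[1], ny))
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    za = surf.anterior(xy) + rng.normal(0, z_noise_um * UM, len(xy))
    zp = surf.posterior(xy) + rng.normal(0, z_noise_um * UM, len(xy))
    pts = np.vstack([np.column_stack([xy, za]), np.column_stack([xy, zp])])
    labels = np.array(["anterior"] * len(xy) + ["posterior"] * len(xy), dtype=object)
    return PlateOutline(points=pts, side_label=labels), surf


# ---------------------------------------------------------------------------
# tangential cells
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """Recipe for a synthetic tangential cell.

    ``layer_fractions`` are the target cable fractions in layers 1-4 (sum 1);
    the dendritic field covers ``field_extent_um`` starting at
    ``field_offset_um`` in the (mediolateral, dorsoventral) plane.  Dendrite
    radii are drawn uniformly from ``radius_nm``; the axon leaves the plate
    medially with ``axon_radius_nm`` and an optional soma blob at its end.
    """

    layer_fractions: tuple = (0.0, 0.0, 0.0, 1.0)
    field_extent_um: tuple = (100.0, 130.0)
    field_offset_um: tuple = (10.0, 10.0)
    total_cable_mm: float = 5.0
    segment_um: float = 2.0
    branch_prob: float = 0.25
    radius_nm: tuple = (150.0, 500.0)
    axon_radius_nm: float = 700.0
    soma: bool = True
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.layer_fractions, dtype=float)
        if f.shape != (4,) or np.any(f < 0):
            raise SpecError("layer_fractions must be 4 non-negative values")
        if abs(f.sum() - 1.0) > 1e-9:
            raise SpecError(f"layer_fractions must sum to 1, got {f.sum()}")


_BAND_MARGIN = 0.02  # keep walk depths clear of layer boundaries


def gen_tangential_cell(spec: CellSpec, surfaces: SlabSurfaces
                        ) -> tuple[SkeletonTree, pd.Series, dict]:
    """Grow a random branching skeleton with prescribed per-layer cable.

    Per target layer a branching random walk is grown inside that depth
    band (depths rejected outside the band, headings reflected at the field
    boundary) until the band's cable budget is spent; the four band
    subtrees hang off a trunk crossing the slab, and an axon runs medially
    out of the plate.  Returns the tree, the realized per-bin cable
    fractions measured against the analytic surfaces (the ground truth the
    layer analysis should recover), and an info dict with cable totals.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = np.asarray(spec.layer_fractions, dtype=float)
    seg = spec.segment_um * UM
    total = spec.total_cable_mm * 1e6
    off = np.asarray(spec.field_offset_um) * UM
    ext = np.asarray(spec.field_extent_um) * UM
    lo_xy, hi_xy = off, off + ext
    center = off + ext / 2.0

    tree = SkeletonTree(name=f"synthetic_cell_seed{spec.seed}")
    next_id = 1

    def add(pos, radius, comment=None, attach=None):
        nonlocal next_id
        tree.add_node(SkeletonNode(next_id, pos, radius, comment))
        if attach is not None:
            tree.add_edge(attach, next_id)
        next_id += 1
        return next_id - 1

    def pos_at(xy, d):
        return np.array([xy[0], xy[1], float(surf_z(xy, d))])

    def surf_z(xy, d):
        return surfaces.z_at_depth(np.asarray(xy)[None, :], d)[0]

    # trunk through the slab at the field center, one node per band center
    band_centers = [0.125, 0.375, 0.625, 0.875]
    trunk_ids = []
    prev = None
    for d in band_centers:
        prev = add(pos_at(center, d), 600.0, attach=prev)
        trunk_ids.append(prev)

    # the axon runs in-plate from the field center to the medial edge at a
    # layer-4 depth; charge that cable against the layer-4 budget up front
    axon_in_plate = ext[0] / 2.0
    budgets = fractions * total
    budgets[3] = max(budgets[3] - axon_in_plate, 0.0)
    for band in range(4):
        budget = budgets[band]
        if budget <= 0:
            continue
        d_lo = band / 4.0 + _BAND_MARGIN
        d_hi = (band + 1) / 4.0 - _BAND_MARGIN
        band_nodes = [trunk_ids[band]]
        cur_id = trunk_ids[band]
        cur_xy = center.copy()
        cur_d = band_centers[band]
        heading = rng.uniform(0, 2 * np.pi)
        spent = 0.0
        while spent < budget:
            if rng.uniform() < spec.branch_prob and len(band_nodes) > 1:
                cur_id = int(rng.choice(band_nodes))
                n = tree.nodes[cur_id]
                cur_xy = n.position[:2].copy()
                cur_d = float(surfaces.depth(n.position[None, :])[0])
                heading = rng.uniform(0, 2 * np.pi)
            d_new = float(np.clip(cur_d + rng.uniform(-0.05, 0.05), d_lo, d_hi))
            dz_est = (d_new - cur_d) * surfaces.thickness_nm
            s_xy = math.sqrt(max(seg ** 2 - dz_est ** 2, (0.25 * seg) ** 2))
            heading += rng.normal(0, 0.6)
            step = s_xy * np.array([math.cos(heading), math.sin(heading)])
            new_xy = cur_xy + step
            # reflect at the field boundary
            for ax in range(2):
                if new_xy[ax] < lo_xy[ax] or new_xy[ax] > hi_xy[ax]:
                    new_xy[ax] = float(np.clip(2 * np.clip(new_xy[ax], lo_xy[ax],
                                                           hi_xy[ax]) - new_xy[ax],
                                               lo_xy[ax], hi_xy[ax]))
                    heading = rng.uniform(0, 2 * np.pi)
            new_pos = pos_at(new_xy, d_new)
            spent += float(np.linalg.norm(new_pos - tree.nodes[cur_id].position))
            cur_id = add(new_pos, rng.uniform(*spec.radius_nm), attach=cur_id)
            band_nodes.append(cur_id)
            cur_xy, cur_d = new_xy, d_new
    # axon: leaves the plate medially (increasing x) from the posterior trunk node
    axon_from = trunk_ids[-1]
    ax_y = center[1]
    x = center[0]
    x_end = hi_xy[0] + 30.0 * UM
    prev = axon_from
    while x < x_end:
        x = min(x + 2.0 * UM, x_end)
        z = surf_z(np.array([min(x, hi_xy[0]), ax_y]), 0.875)
        prev = add(np.array([x, ax_y, z]), spec.axon_radius_nm, attach=prev)
    if spec.soma:
        base = tree.nodes[prev].position
        for i in range(1, 4):
            prev = add(base + np.array([i * 2.0 * UM, 0, 0]), 2000.0,
                       comment="soma", attach=prev)

    realized, info = measure_cable_fractions(tree, surfaces, (lo_xy, hi_xy))
    return tree, realized, info


def measure_cable_fractions(tree: SkeletonTree, surfaces: SlabSurfaces,
                            xy_box: tuple[np.ndarray, np.ndarray],
                            samples_per_edge: int = 10
                            ) -> tuple[pd.Series, dict]:
    """Ground-truth cable fractions per histogram bin, from the analytic surfaces.

    Each edge is sampled at ``samples_per_edge`` midpoints; sample length is
    binned by analytic depth.  Only cable whose (x, y) lies inside
    ``xy_box`` (the plate region) counts; the rest is reported as
    out-of-plate cable.
    """
    lo, hi = xy_box
    totals = pd.Series(0.0, index=list(HISTOGRAM_BINS))
    out_of_plate = 0.0
    for a, b in sorted(tree.edges):
        pa, pb = tree.nodes[a].position, tree.nodes[b].position
        length = float(np.linalg.norm(pb - pa))
        if length == 0:
            continue
        t = (np.arange(samples_per_edge) + 0.5) / samples_per_edge
        pts = pa[None, :] + t[:, None] * (pb - pa)[None, :]
        inside = np.all((pts[:, :2] >= lo) & (pts[:, :2] <= hi), axis=1)
        d = surfaces.depth(pts)
        w = length / samples_per_edge
        out_of_plate += w * np.count_nonzero(~inside)
        d_in = d[inside]
        totals["anterior"] += w * np.count_nonzero(d_in < 0)
        totals["posterior"] += w * np.count_nonzero(d_in > 1)
        ok = d_in[(d_in >= 0) & (d_in <= 1)]
        layer = np.minimum(np.floor(4 * ok).astype(int), 3)
        for l in range(4):
            totals[f"layer{l + 1}"] += w * np.count_nonzero(layer == l)
    in_plate = float(totals.sum())
    fractions = totals / in_plate if in_plate > 0 else totals
    return fractions, {"in_plate_cable_nm": in_plate,
                       "out_of_plate_cable_nm": float(out_of_plate)}


# ---------------------------------------------------------------------------
# axon bundles
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Tube axes (nm polylines), radii (nm, one per tube) and the roi window."""

    axes_nm: list
    radii_nm: list
    roi_um: tuple = (86.0, 203.0)
    names: Optional[list] = None
    seed: int = 0

    def __post_init__(self):
        if len(self.axes_nm) != len(self.radii_nm):
            raise SpecError("one radius per tube axis required")
        if any(r <= 0 for r in self.radii_nm):
            raise SpecError("tube radii must be > 0")


def _clip_polyline_x(poly: np.ndarray, x0: float, x1: float) -> np.ndarray:
    """Restrict a polyline to the slab x0 <= x <= x1, interpolating at cuts."""
    pts = []
    for a, b in zip(poly[:-1], poly[1:]):
        xa, xb = a[0], b[0]
        lo, hi = (a, b) if xa <= xb else (b, a)
        if hi[0] < x0 or lo[0] > x1:
            continue
        seg = [lo, hi]
        for i, bound in ((0, x0), (1, x1)):
            p, q = seg
            if i == 0 and p[0] < bound:
                t = (bound - p[0]) / (q[0] - p[0])
                seg[0] = p + t * (q - p)
            if i == 1 and q[0] > bound:
                t = (bound - p[0]) / (q[0] - p[0])
                seg[1] = p + t * (q - p)
        if not pts or not np.allclose(pts[-1], seg[0]):
            pts.append(seg[0])
        pts.append(seg[1])
    return np.asarray(pts).reshape(-1, 3)


def _segment_pair_distance(p0, p1, q0, q1) -> np.ndarray:
    """Min distance between segment sets, broadcast (n, 1, 3) x (1, m, 3)."""
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t_clipped = np.clip(t, 0.0, 1.0)
    # re-project s where t was clipped
    s = np.where(t != t_clipped,
                 np.clip((t_clipped * b - c) / np.where(a > 1e-12, a, 1.0), 0.0, 1.0),
                 s)
    t = t_clipped
    closest_p = p0 + s[..., None] * d1
    closest_q = q0 + t[..., None] * d2
    return np.linalg.norm(closest_p - closest_q, axis=-1)


def polyline_min_distance(poly_a: np.ndarray, poly_b: np.ndarray) -> float:
    """Minimum distance between two 3D polylines (exact over all segment pairs)."""
    p0 = poly_a[:-1][:, None, :]
    p1 = poly_a[1:][:, None, :]
    q0 = poly_b[:-1][None, :, :]
    q1 = poly_b[1:][None, :, :]
    return float(_segment_pair_distance(p0, p1, q0, q1).min())


def gen_axon_bundle(spec: BundleSpec) -> tuple[list, pd.DataFrame, dict]:
    """Materialize a bundle spec into skeletons plus analytic contact truth.

    Returns radius-annotated polyline skeletons, a table of pairwise minimal
    wall-to-wall gaps inside the roi (negative = overlapping walls), and the
    classification dict {(i, j): 'touching' | 'separated'} where touching
    means gap <= 0.
    """
    names = spec.names or [f"tube{i}" for i in range(len(spec.axes_nm))]
    trees = []
    for name, axis, radius in zip(names, spec.axes_nm, spec.radii_nm):
        t = SkeletonTree(name=name)
        prev = None
        for i, p in enumerate(np.asarray(axis, dtype=float), start=1):
            t.add_node(SkeletonNode(i, p, float(radius)))
            if prev is not None:
                t.add_edge(prev, i)
            prev = i
        trees.append(t)

    x0, x1 = spec.roi_um[0] * UM, spec.roi_um[1] * UM
    clipped = [_clip_polyline_x(np.asarray(a, dtype=float), x0, x1)
               for a in spec.axes_nm]
    rows = []
    classification = {}
    for i, j in itertools.combinations(range(len(trees)), 2):
        dist = polyline_min_distance(clipped[i], clipped[j])
        gap = dist - spec.radii_nm[i] - spec.radii_nm[j]
        touching = gap <= 0
        classification[(i, j)] = "touching" if touching else "separated"
        rows.append({"tube_a": names[i], "tube_b": names[j],
                     "gap_um": gap / UM, "touching": touching})
    return trees, pd.DataFrame(rows), classification


def make_parallel_bundle(wall_gap_um: float, n_tubes: int = 2,
                         radius_um: float = 0.7,
                         roi_um: tuple[float, float] = (86.0, 106.0),
                         axis_jitter_nm: float = 0.0, seed: int = 0) -> BundleSpec:
    """Straight parallel tubes along x separated by a given wall gap.

    ``axis_jitter_nm`` adds sub-voxel transverse roughness to the axes
    (nodes every 0.3 μm): physically negligible, but it decoheres the
    voxel discretization of an otherwise perfectly flat interface, making
    voxel-derived contact areas stable across grid resolution and phase.
    """
    rng = np.random.default_rng(seed)
    r = radius_um * UM
    pitch = 2 * r + wall_gap_um * UM
    if axis_jitter_nm > 0:
        x = np.arange(roi_um[0] - 2, roi_um[1] + 2, 0.3) * UM
    else:
        x = np.array([roi_um[0] - 2, roi_um[1] + 2]) * UM
    axes = []
    for i in range(n_tubes):
        y = np.full(len(x), i * pitch)
        z = np.zeros(len(x))
        if axis_jitter_nm > 0:
            y = y + rng.uniform(-axis_jitter_nm, axis_jitter_nm, len(x))
            z = z + rng.uniform(-axis_jitter_nm, axis_jitter_nm, len(x))
        axes.append(np.column_stack([x, y, z]))
    return BundleSpec(axes_nm=axes, radii_nm=[r] * n_tubes, roi_um=roi_um, seed=seed)


def make_braid_spec(n_tubes: int = 9, skip_pair: tuple[int, int] = (0, 4),
                    radius_um: float = 0.7, ring_radius_um: float = 9.0,
                    contact_um: float = 1.0, transition_um: float = 1.0,
                    gap_between_um: float = 0.5, overlap_um: float = 0.15,
                    x_start_um: float = 86.0, seed: int = 0) -> BundleSpec:
    """A braid of tubes in which every pair makes wall contact except one.

    Tubes rest on a ring (radius ``ring_radius_um`` in the y-z plane) and
    run along x.  Pairs take turns: during a pair's interval both members
    travel to the ring center and sit in wall contact (walls overlapping by
    ``overlap_um``) for ``contact_um`` micrometres of x, then return.  The
    ``skip_pair`` never gets an interval, and the ring is wide enough that
    a traveling tube keeps a wall gap well above the reach of the contact
    pipeline's dilations from every bystander — so the skipped pair is the
    unique non-touching pair by construction.
    """
    r = radius_um * UM
    ring = ring_radius_um * UM
    angles = 2 * np.pi * np.arange(n_tubes) / n_tubes
    base = np.column_stack([ring * np.cos(angles), ring * np.sin(angles)])
    skip = tuple(sorted(skip_pair))
    pairs = [p for p in itertools.combinations(range(n_tubes), 2) if p != skip]

    # control points per tube: (x, y, z); constant base position in between
    controls: dict[int, list] = {i: [] for i in range(n_tubes)}
    x = x_start_um * UM + 2.0 * UM
    for a, b in pairs:
        x1 = x
        x2 = x1 + transition_um * UM
        x3 = x2 + contact_um * UM
        x4 = x3 + transition_um * UM
        u = base[b] - base[a]
        u = u / np.linalg.norm(u)
        half = (2 * r - overlap_um * UM) / 2.0
        meet_a, meet_b = -u * half, u * half
        for tube, meet in ((a, meet_a), (b, meet_b)):
            controls[tube] += [(x1, *base[tube]), (x2, *meet),
                               (x3, *meet), (x4, *base[tube])]
        x = x4 + gap_between_um * UM
    x_end = x + 2.0 * UM
    x_begin = x_start_um * UM
    axes = []
    for i in range(n_tubes):
        pts = ([(x_begin, *base[i])] + controls[i] + [(x_end, *base[i])])
        axes.append(np.array(pts, dtype=float))
    return BundleSpec(axes_nm=axes, radii_nm=[r] * n_tubes,
                      roi_um=(x_begin / UM, x_end / UM),
                      names=[f"tube{i}" for i in range(n_tubes)], seed=seed)


# ---------------------------------------------------------------------------
# image tile grids
# ---------------------------------------------------------------------------

def gen_tile_grid(tile_shape: tuple[int, int] = (128, 128), rows: int = 4,
                  cols: int = 4, overlap_px: int = 32,
                  jitter_px: float = 2.0, intensity_noise: float = 0.05,
                  seed: int = 0) -> tuple[dict, dict, dict]:
    """Crop a textured mother image into overlapping tiles at jittered positions.

    True positions are nominal grid positions plus integer Gaussian jitter
    (σ = ``jitter_px``); tiles get independent additive intensity noise.
    Returns (tiles, true_positions, nominal_positions) keyed by (row, col).
    """
    rng = np.random.default_rng(seed)
    h, w = tile_shape
    stride = (h - overlap_px, w - overlap_px)
    margin = int(4 * jitter_px) + 4
    mother_shape = (rows * stride[0] + overlap_px + 2 * margin,
                    cols * stride[1] + overlap_px + 2 * margin)
    mother = gaussian_filter(rng.standard_normal(mother_shape), 2.0)
    mother /= mother.std()

    tiles, truth, nominal = {}, {}, {}
    for ri in range(rows):
        for ci in range(cols):
            nom = np.array([ri * stride[0], ci * stride[1]], dtype=float)
            jit = np.round(rng.normal(0, jitter_px, 2)).astype(int)
            pos = nom + jit
            r0 = int(pos[0]) + margin
            c0 = int(pos[1]) + margin
            img = mother[r0:r0 + h, c0:c0 + w].copy()
            img += intensity_noise * rng.standard_normal(img.shape)
            tiles[(ri, ci)] = img
            truth[(ri, ci)] = pos
            nominal[(ri, ci)] = nom
    return tiles, truth, nominal
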