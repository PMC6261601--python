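"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's implementation paths: volume by
counting fine voxels on a full dense grid, morphology by explicit shifted
slices, so that agreement is evidence rather than tautology.
"""


import numpy as np

_OFFSETS = [(i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]


def voxel_volume_um3(tree, voxel_nm=20.0):
    """Voxel-counting oracle for the additive frustum volume model.

    Each edge is a flat-ended cone (radius linear along the axis, cut by the
    end planes); its volume is counted independently on a fine grid and the
    counts are summed — matching the model's additive assembly, in which
    branch-point overlap is deliberately not corrected.
    """
    pts = tree.positions()
    rads = tree.radii()
    lo = pts.min(axis=0) - rads.max() - voxel_nm
    hi = pts.max(axis=0) + rads.max() + voxel_nm
    shape = np.ceil((hi - lo) / voxel_nm).astype(int)
    centers = [lo[i] + voxel_nm * (np.arange(shape[i]) + 0.5) for i in range(3)]
    n_inside = 0
    for a, b in sorted(tree.edges):
        p0 = tree.nodes[a].position
        p1 = tree.nodes[b].position
        r0, r1 = tree.nodes[a].radius, tree.nodes[b].radius
        pad = max(r0, r1) + voxel_nm
        i0 = np.maximum(((np.minimum(p0, p1) - pad - lo) // voxel_nm).astype(int), 0)
        i1 = np.minimum(((np.maximum(p0, p1) + pad - lo) // voxel_nm).astype(int) + 1,
                        shape)
        cx = centers[0][i0[0]:i1[0]][:, None, None]
        cy = centers[1][i0[1]:i1[1]][None, :, None]
        cz = centers[2][i0[2]:i1[2]][None, None, :]
        seg = p1 - p0
        L2 = float(seg @ seg)
        if L2 == 0:
            continue
        dx, dy, dz = cx - p0[0], cy - p0[1], cz - p0[2]
        t = (dx * seg[0] + dy * seg[1] + dz * seg[2]) / L2
        qx, qy, qz = dx - t * seg[0], dy - t * seg[1], dz - t * seg[2]
        rad = r0 + t * (r1 - r0)
        inside = (t >= 0) & (t <= 1) & (qx * qx + qy * qy + qz * qz <= rad * rad)
        n_inside += int(np.count_nonzero(inside))
    return float(n_inside) * (voxel_nm / 1000.0) ** 3


def _shift_or(dst, src, off):
    """dst |= src shifted by off, zero-filled (no wraparound)."""
    slc_dst, slc_src = [], []
    for o, n in zip(off, src.shape):
        if o >= 0:
            slc_dst.append(slice(o, n))
            slc_src.append(slice(0, n - o))
        else:
            slc_dst.append(slice(0, n + o))
            slc_src.append(slice(-o, n))
    dst[tuple(slc_dst)] |= src[tuple(slc_src)]


def dilate26(mask, rounds=1):
    """Binary dilation with the 3x3x3 cube by explicit neighbor shifts."""
    out = mask.copy()
    for _ in range(rounds):
        cur = out.copy()
        for off in _OFFSETS:
            _shift_or(out, cur, off)
    return out


def erode26(mask, rounds=1):
    """Binary erosion with the 3x3x3 cube (complement dilation)."""
    return ~dilate26(~mask, rounds)


def constrained_dilate_oracle(labels, rounds):
    """Naive synchronous constrained dilation: per sweep, every label grows
    by the cube into free background; multiply-claimed voxels become
    permanently contested background."""
    labels = labels.copy()
    contested = np.zeros(labels.shape, dtype=bool)
    ids = [int(v) for v in np.unique(labels) if v != 0]
    for _ in range(rounds):
        count = np.zeros(labels.shape, dtype=np.int16)
        winner = np.zeros_like(labels)
        for k in ids:
            grown = dilate26(labels == k) & (labels == 0) & ~contested
            count += grown
            winner[grown] = k
        labels[count == 1] = winner[count == 1]
        contested |= count >= 2
    return labels, contested


def _polyline_mask(axis_nm, radius_nm, lo, shape, voxel_nm):
    """Capsule sweep of a polyline on a voxel grid (distance-to-segment test)."""
    centers = [lo[i] + voxel_nm * (np.arange(shape[i]) + 0.5) for i in range(3)]
    mask = np.zeros(tuple(shape), dtype=bool)
    for p0, p1 in zip(axis_nm[:-1], axis_nm[1:]):
        pad = radius_nm + voxel_nm
        i0 = np.maximum(((np.minimum(p0, p1) - pad - lo) // voxel_nm).astype(int), 0)
        i1 = np.minimum(((np.maximum(p0, p1) + pad - lo) // voxel_nm).astype(int) + 1,
                        shape)
        if np.any(i0 >= i1):
            continue
        cx = centers[0][i0[0]:i1[0]][:, None, None]
        cy = centers[1][i0[1]:i1[1]][None, :, None]
        cz = centers[2][i0[2]:i1[2]][None, None, :]
        seg = p1 - p0
        L2 = float(seg @ seg)
        dx, dy, dz = cx - p0[0], cy - p0[1], cz - p0[2]
        if L2 == 0:
            t = np.zeros(np.broadcast_shapes(dx.shape, dy.shape, dz.shape))
        else:
            t = np.clip((dx * seg[0] + dy * seg[1] + dz * seg[2]) / L2, 0.0, 1.0)
        qx, qy, qz = dx - t * seg[0], dy - t * seg[1], dz - t * seg[2]
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= (
            qx * qx + qy * qy + qz * qz <= radius_nm * radius_nm)
    return mask


def polyline_contact_area_um2(axes_nm, radii_nm, voxel_nm,
                              closing_rounds, growth_rounds, final_rounds=1,
                              roi_x_nm=None):
    """Full contact procedure for two tubes, brute force on a dense grid.

    Independent of the library: capsule membership by per-segment distance,
    shifted-slice morphology, exact face-area conversion, symmetrized mean.
    Run at half the production voxel with closing/growth rounds doubled
    (preserving their physical reach; the measuring dilation stays a single
    kernel application as the procedure defines it) this is the reference
    the production measurement is compared against.
    """
    pts = np.vstack(axes_nm)
    rmax = max(radii_nm)
    margin = (closing_rounds + growth_rounds + final_rounds + 2) * voxel_nm
    lo = pts.min(axis=0) - rmax - margin
    hi = pts.max(axis=0) + rmax + margin
    if roi_x_nm is not None:  # only the roi window is rasterized along x
        lo[0], hi[0] = roi_x_nm
    shape = np.ceil((hi - lo) / voxel_nm).astype(int)
    masks = [_polyline_mask(np.asarray(a, dtype=float), r, lo, shape, voxel_nm)
             for a, r in zip(axes_nm, radii_nm)]
    closed = [erode26(dilate26(m, closing_rounds), closing_rounds) for m in masks]
    labels = np.zeros(tuple(shape), dtype=np.int8)
    labels[closed[0]] = 1
    labels[closed[1] & ~closed[0]] = 2
    labels[closed[0] & closed[1]] = 0  # contested at voxelization
    labels, _ = constrained_dilate_oracle(labels, growth_rounds)
    ab = np.count_nonzero(dilate26(labels == 1, final_rounds) & (labels == 2))
    ba = np.count_nonzero(dilate26(labels == 2, final_rounds) & (labels == 1))
    return (ab + ba) / 2.0 / (1000.0 / voxel_nm) ** 2
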