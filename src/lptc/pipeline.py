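"""End-to-end study orchestration: layer tables, volumes, contact matrices.

Every report embeds the fully resolved configuration so a result can be
audited, and identical config + inputs give byte-identical CSV output.
The defaults are the study's printed constants: 400 nm resampling,
(140 nm)^3 voxels, 2 closing rounds, 7 restricted growth rounds, area
divisor 51, contact window 86-203 μm, 118 μm sagittal window, 500 μm³
volume threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import contact_analysis, layer_model, skeleton_io, skeleton_ops
from .errors import LptcError
from .skeleton import SkeletonTree

__all__ = ["StudyConfig", "run_layers", "run_volumes", "run_contacts"]


@dataclass
class StudyConfig:
    """All pipeline constants; defaults are the study's printed values."""

    resample_nm: float = 400.0
    voxel_nm: float = 140.0
    closing_rounds: int = 2
    growth_rounds: int = 7
    area_divisor: Optional[float] = 51.0
    contact_roi_um: tuple = (86.0, 203.0)
    sagittal_window_um: float = 118.0
    volume_threshold_um3: float = 500.0
    seed: int = 0

    def __post_init__(self):
        for name in ("resample_nm", "voxel_nm", "closing_rounds", "growth_rounds",
                     "sagittal_window_um", "volume_threshold_um3"):
            if getattr(self, name) <= 0:
                raise LptcError(f"config {name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contact_roi_um"] = list(d["contact_roi_um"])
        return d


CellInput = Union[SkeletonTree, str]


def _load_cell(cell: CellInput) -> SkeletonTree:
    if isinstance(cell, SkeletonTree):
        return cell
    ann = skeleton_io.read_nml(cell)
    if not ann.trees:
        raise LptcError(f"{cell}: no trees in file")
    # single-file cells: pool all trees into one skeleton (ids offset per tree)
    pooled = SkeletonTree(name=ann.trees[0].name)
    offset = 0
    for t in ann.trees:
        for n in t.nodes.values():
            pooled.add_node(dataclasses.replace(n, id=n.id + offset,
                                                position=n.position.copy()))
        for a, b in t.edges:
            pooled.add_edge(a + offset, b + offset)
        offset += max(t.nodes, default=0)
    return pooled


def run_layers(config: StudyConfig, cells: dict, model: layer_model.LayerModel,
               out_dir: Optional[str] = None) -> dict:
    """Per-cell layer histograms and depth boxplot statistics.

    ``cells`` maps cell name -> SkeletonTree (or NML path).  Each skeleton
    is resampled to the configured spacing, projected into the layer model,
    and reduced to layer fractions and boxplot statistics.  Returns a dict
    with 'table' (DataFrame), 'boxplots', 'config'; with ``out_dir`` the
    table, stats and a sagittal figure are also written.
    """
    if not cells:
        raise LptcError("empty cell list")
    rows = []
    boxplots = {}
    clipped_trees = []
    for name, cell in cells.items():
        tree = _load_cell(cell)
        res = skeleton_ops.resample_max_spacing(tree, config.resample_nm)
        assignment = layer_model.assign_depth(res, model)
        hist = layer_model.layer_histogram(assignment)
        row = {"cell": name}
        row.update({k: float(hist[k]) for k in layer_model.HISTOGRAM_BINS})
        row["n_nodes"] = int(np.count_nonzero(assignment.in_footprint))
        rows.append(row)
        boxplots[name] = layer_model.depth_boxplot_stats(assignment)
        clipped_trees.append(
            layer_model.sagittal_clip([res], config.sagittal_window_um)[0])
    table = pd.DataFrame(rows)
    result = {"table": table, "boxplots": boxplots, "config": config.to_dict()}
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "layers.csv"), index=False)
        with open(os.path.join(out_dir, "layer_stats.json"), "w") as fh:
            json.dump({"config": result["config"], "boxplots": boxplots}, fh,
                      indent=2, sort_keys=True)
        _render_sagittal(clipped_trees, list(cells),
                         os.path.join(out_dir, "sagittal.png"))
    return result


def _render_sagittal(trees: Sequence[SkeletonTree], names: Sequence[str],
                     path: str) -> None:
    """Convenience figure: normalized sagittal view (y vs z) of clipped cells."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for tree, name in zip(trees, names):
        if not len(tree):
            continue
        pts = tree.positions() / 1000.0
        ax.plot(pts[:, 2], pts[:, 1], ".", ms=1, label=name)
    ax.set_xlabel("anteroposterior z (μm)")
    ax.set_ylabel("dorsoventral y (μm)")
    ax.invert_yaxis()
    ax.legend(markerscale=8, fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_volumes(config: StudyConfig, cells: dict,
                out_dir: Optional[str] = None) -> dict:
    """Per-cell frustum volume with the >= 500 μm³ candidate classification.

    Each cell (tree or NML path) is reduced to its largest component (by
    cable), the soma reconstruction is excluded, and the volume classified
    against the threshold (inclusive >=, to avoid float-equality traps on
    the boundary).
    """
    if not cells:
        raise LptcError("empty cell list")
    rows = []
    for name, cell in cells.items():
        tree = skeleton_ops.largest_component(_load_cell(cell))
        vol = skeleton_ops.estimate_volume(tree, exclude_soma=True)
        rows.append({
            "cell": name,
            "volume_um3": vol,
            "cable_mm": skeleton_ops.cable_length(tree) / 1e6,
            "above_threshold": bool(vol >= config.volume_threshold_um3),
        })
    table = pd.DataFrame(rows)
    result = {"table": table, "config": config.to_dict()}
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "volumes.csv"), index=False)
    return result


def run_contacts(config: StudyConfig, cells: dict,
                 out_dir: Optional[str] = None) -> dict:
    """Axon-axon contact matrix over the configured depth window.

    Cells are resampled, rasterized into a (voxel_nm)^3 label volume over
    ``contact_roi_um``, closed, grown under the no-invasion restriction,
    and measured pairwise.  Zero pairs are flagged for manual review.
    """
    if len(cells) < 2:
        raise LptcError("contact analysis needs >= 2 cells")
    trees = []
    for name, cell in cells.items():
        t = _load_cell(cell)
        t = skeleton_ops.resample_max_spacing(t, config.resample_nm)
        t.name = name
        trees.append(t)
    vol = contact_analysis.voxelize(trees, voxel_nm=config.voxel_nm,
                                    roi_um=config.contact_roi_um)
    vol = contact_analysis.close_labels(vol, rounds=config.closing_rounds)
    vol = contact_analysis.constrained_dilate(vol, rounds=config.growth_rounds)
    matrix = contact_analysis.contact_matrix(vol, divisor=config.area_divisor)
    table = matrix.to_table()
    result = {"table": table, "matrix": matrix, "config": config.to_dict()}
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "contacts.csv"), index=False)
        with open(os.path.join(out_dir, "contacts_config.json"), "w") as fh:
            json.dump(result["config"], fh, indent=2, sort_keys=True)
    return result
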