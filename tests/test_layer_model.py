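"""Two-surface plate model: splitting, interpolation, depth and statistics."""

import numpy as np
import pytest

from conftest import make_tree
from lptc.errors import DegenerateOutlineError, EmptyHistogramError, ModelError
from lptc import layer_model as lm
from lptc import skeleton_ops as ops
from lptc import synthetic_data as sd


def _grid_xy(n=6, extent=40000.0):
    g = np.linspace(0, extent, n)
    gx, gy = np.meshgrid(g, g)
    return np.column_stack([gx.ravel(), gy.ravel()])


class TestSplitOutline:
    def test_two_parallel_planes_split_exactly(self):
        xy = _grid_xy()
        pts = np.vstack([np.column_stack([xy, np.zeros(len(xy))]),
                         np.column_stack([xy, np.full(len(xy), 10000.0)])])
        ant, post = lm.split_outline(lm.PlateOutline(points=pts))
        assert len(ant) == len(xy) and len(post) == len(xy)
        assert ant[:, 2].max() == 0.0
        assert post[:, 2].min() == 10000.0

    def test_labels_override_geometry(self):
        xy = _grid_xy(3)
        pts = np.column_stack([xy, np.arange(len(xy), dtype=float)])
        labels = np.array(["anterior", "posterior"] * (len(pts) // 2)
                          + ["anterior"] * (len(pts) % 2), dtype=object)
        ant, post = lm.split_outline(lm.PlateOutline(points=pts, side_label=labels))
        assert len(ant) + len(post) == len(pts)
        assert len(ant) == np.count_nonzero(labels == "anterior")

    def test_coplanar_unlabeled_is_degenerate(self):
        xy = _grid_xy()
        pts = np.column_stack([xy, np.full(len(xy), 5000.0)])
        with pytest.raises(DegenerateOutlineError):
            lm.split_outline(lm.PlateOutline(points=pts))


class TestBuildLayerModel:
    def test_parallel_planes_constant_thickness(self, flat_model):
        probe = np.array([[5000.0, 5000.0], [20000.0, 30000.0]])
        assert np.allclose(flat_model.thickness(probe), 20000.0)

    def test_linear_precision_on_tilted_plane(self):
        xy = _grid_xy()
        ant = np.column_stack([xy, xy[:, 0]])          # z = x
        post = np.column_stack([xy, xy[:, 0] + 20000.0])
        model = lm.build_layer_model(ant, post)
        probe = np.array([[12345.0, 23456.0], [31000.0, 7000.0]])
        assert np.allclose(model.anterior(probe), probe[:, 0], atol=1e-6)

    def test_curved_slab_thickness_within_5pct(self, curved_plate):
        outline, surf, model = curved_plate
        rng = np.random.default_rng(0)
        probe = rng.uniform([10000, 10000],
                            [surf.extent_nm[0] - 10000, surf.extent_nm[1] - 10000],
                            (200, 2))
        th = model.thickness(probe)
        assert np.all(np.abs(th - surf.thickness_nm) / surf.thickness_nm < 0.05)

    def test_crossing_surfaces_rejected(self):
        xy = _grid_xy()
        ant = np.column_stack([xy, xy[:, 0]])            # z = x
        post = np.column_stack([xy, 40000.0 - xy[:, 0]])  # crosses at x = 20 μm
        with pytest.raises(ModelError):
            lm.build_layer_model(ant, post)


class TestAssignDepth:
    def test_flat_slab_closed_form(self, flat_model):
        t = make_tree("n", [(1, (5000, 5000, 2500), 100.0),
                            (2, (5000, 5000, 10000), 100.0)], [(1, 2)])
        a = lm.assign_depth(t, flat_model)
        assert a.in_footprint.all()
        assert a.depth[0] == pytest.approx(0.125)
        assert a.layer[0] == 1
        assert a.depth[1] == pytest.approx(0.5)
        assert a.layer[1] == 3  # half-open bins: d = 0.5 starts layer 3

    def test_boundary_quarter_goes_to_next_layer(self, flat_model):
        t = make_tree("n", [(1, (5000, 5000, 5000), 100.0),
                            (2, (6000, 6000, 20000), 100.0)], [(1, 2)])
        a = lm.assign_depth(t, flat_model)
        assert a.depth[0] == pytest.approx(0.25)
        assert a.layer[0] == 2
        assert a.depth[1] == pytest.approx(1.0)
        assert a.layer[1] == 4  # d = 1 exactly belongs to layer 4

    def test_outside_footprint_excluded(self, flat_model):
        t = make_tree("n", [(1, (99000, 5000, 2500), 100.0),
                            (2, (5000, 5000, 2500), 100.0)], [(1, 2)])
        a = lm.assign_depth(t, flat_model)
        assert not a.in_footprint[0]
        assert np.isnan(a.depth[0])
        assert a.category[0] == "outside"

    def test_depth_invariant_under_common_translation(self, curved_plate):
        outline, surf, model = curved_plate
        shift = np.array([0.0, 0.0, 7000.0])
        ant, post = lm.split_outline(outline)
        model2 = lm.build_layer_model(ant + shift, post + shift)
        t = make_tree("n", [(1, (30000, 40000, 45000), 100.0),
                            (2, (60000, 70000, 52000), 100.0)], [(1, 2)])
        a1 = lm.assign_depth(t, model)
        t2 = t.copy()
        for n in t2:
            n.position = n.position + shift
        a2 = lm.assign_depth(t2, model2)
        assert np.allclose(a1.depth, a2.depth, atol=1e-9)


class TestLayerHistogram:
    def test_all_nodes_one_layer(self, flat_model):
        t = make_tree("n", [(i, (5000 + i, 5000, 18000), 100.0) for i in range(1, 6)],
                      [(i, i + 1) for i in range(1, 5)])
        h = lm.layer_histogram(lm.assign_depth(t, flat_model))
        assert h["layer4"] == 1.0  # d = 0.9
        assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_anterior_posterior_bins(self, flat_model):
        t = make_tree("n", [(1, (5000, 5000, -3000), 100.0),
                            (2, (5000, 5000, 25000), 100.0)], [(1, 2)])
        h = lm.layer_histogram(lm.assign_depth(t, flat_model))
        assert h["anterior"] == pytest.approx(0.5)
        assert h["posterior"] == pytest.approx(0.5)

    def test_empty_histogram_raises(self, flat_model):
        t = make_tree("n", [(1, (99000, 99000, 0), 100.0)], [])
        with pytest.raises(EmptyHistogramError):
            lm.layer_histogram(lm.assign_depth(t, flat_model))

    def test_layer_report_weightings_agree_on_uniform_tree(self, curved_plate):
        # with uniform segment lengths the three counting modes bracket the
        # same underlying distribution tightly
        outline, surf, model = curved_plate
        spec = sd.CellSpec(layer_fractions=(0.0, 0.4, 0.0, 0.6),
                           total_cable_mm=2.0, seed=22)
        tree, realized, _ = sd.gen_tangential_cell(spec, surf)
        report = lm.layer_report(tree, model)
        assert set(report.index) == {"raw_nodes", "resampled_nodes", "cable"}
        for mode in report.index:
            assert report.loc[mode].sum() == pytest.approx(1.0, abs=1e-9)
            assert report.loc[mode, "layer2"] == pytest.approx(
                realized["layer2"], abs=0.03)

    def test_recovers_generated_fractions(self, curved_plate):
        outline, surf, model = curved_plate
        spec = sd.CellSpec(layer_fractions=(0.0, 0.4, 0.0, 0.6),
                           total_cable_mm=3.0, seed=21)
        tree, realized, _ = sd.gen_tangential_cell(spec, surf)
        res = ops.resample_max_spacing(tree, 400.0)
        h = lm.layer_histogram(lm.assign_depth(res, model))
        assert abs(h["layer2"] - realized["layer2"]) < 0.02
        assert abs(h["layer4"] - realized["layer4"]) < 0.02


class TestBoxplotStats:
    def _assignment(self, d):
        d = np.asarray(d, dtype=float)
        return lm.DepthAssignment(node_ids=np.arange(len(d)),
                                  in_footprint=np.ones(len(d), dtype=bool),
                                  depth=d, layer=np.zeros(len(d), dtype=int))

    def test_tukey_midpoint_quartiles(self):
        s = lm.depth_boxplot_stats(self._assignment([0.1, 0.2, 0.3, 0.4, 0.5]))
        assert s["median"] == pytest.approx(0.3)
        assert s["q1"] == pytest.approx(0.2)
        assert s["q3"] == pytest.approx(0.4)

    def test_inclusion_window_drops_far_nodes(self):
        s = lm.depth_boxplot_stats(self._assignment([0.1, 0.2, 0.3, 0.4, 0.5, 1.7]))
        assert s["n"] == 5
        assert s["median"] == pytest.approx(0.3)

    def test_uniform_depth_median(self):
        rng = np.random.default_rng(9)
        s = lm.depth_boxplot_stats(self._assignment(rng.uniform(0, 1, 10_000)))
        assert s["median"] == pytest.approx(0.5, abs=0.02)
        assert s["q1"] == pytest.approx(0.25, abs=0.02)

    def test_outliers_beyond_fences(self):
        d = [0.4] * 20 + [0.5] * 20 + [0.6] * 20 + [1.4]
        s = lm.depth_boxplot_stats(self._assignment(d))
        assert s["outliers"] == [1.4]
        assert s["whisker_high"] == pytest.approx(0.6)


class TestSliceDepthAndClip:
    @pytest.mark.parametrize("slice_index,depth_um", [
        (3960, 99.0), (6120, 153.0), (0, 0.0)])
    def test_slice_to_depth(self, slice_index, depth_um):
        assert lm.slice_to_depth(slice_index) == pytest.approx(depth_um)

    def test_clip_keeps_lateral_nodes(self):
        t = make_tree("n", [(1, (50000, 0, 0), 100.0), (2, (120000, 0, 0), 100.0)],
                      [(1, 2)])
        (c,) = lm.sagittal_clip([t], window_um=118.0)
        assert set(c.nodes) == {1}
        assert not c.edges  # dangling edge dropped

    def test_clip_idempotent(self):
        t = make_tree("n", [(i, (i * 30000.0, 0, 0), 100.0) for i in range(1, 6)],
                      [(i, i + 1) for i in range(1, 5)])
        once = lm.sagittal_clip([t], 118.0)
        twice = lm.sagittal_clip(once, 118.0)
        assert set(twice[0].nodes) == set(once[0].nodes)
        assert twice[0].edges == once[0].edges
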