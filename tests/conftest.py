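import numpy as np
import pytest

from lptc.skeleton import SkeletonNode, SkeletonTree
from lptc import layer_model as lm
from lptc import synthetic_data as sd


def make_tree(name, nodes, edges):
    """nodes: iterable of (id, (x, y, z) nm, radius nm[, comment])."""
    t = SkeletonTree(name=name)
    for spec in nodes:
        nid, pos, rad = spec[0], spec[1], spec[2]
        comment = spec[3] if len(spec) > 3 else None
        t.add_node(SkeletonNode(nid, np.asarray(pos, dtype=float), rad, comment))
    for a, b in edges:
        t.add_edge(a, b)
    return t


def random_tree(rng, n_nodes=12, extent_nm=3000.0, radius_nm=(100.0, 300.0)):
    """Random connected acyclic tree: each node attaches to a random earlier one."""
    t = SkeletonTree(name="random")
    for i in range(1, n_nodes + 1):
        pos = rng.uniform(0, extent_nm, 3)
        t.add_node(SkeletonNode(i, pos, rng.uniform(*radius_nm)))
        if i > 1:
            t.add_edge(i, int(rng.integers(1, i)))
    return t


def random_walk_tree(rng, n_edges=15, step_nm=2000.0, radius_nm=(250.0, 400.0),
                     branch_prob=0.15):
    """Branching walk in the thin-gently-turning regime where a frustum sum
    is a valid volume model: headings persist with small wiggle and branches
    leave their parent at a wide angle, so capsule overlap is confined to
    small junction neighborhoods."""

    def _perp(v):
        p = np.cross(v, rng.standard_normal(3))
        return p / np.linalg.norm(p)

    t = SkeletonTree(name="walk")
    t.add_node(SkeletonNode(1, np.zeros(3), rng.uniform(*radius_nm)))
    heading = rng.standard_normal(3)
    heading /= np.linalg.norm(heading)
    tips = [(1, heading)]
    next_id = 2
    while next_id <= n_edges + 1:
        branching = rng.uniform() < branch_prob and next_id > 2
        i = int(rng.integers(len(tips))) if branching else -1
        nid, heading = tips[i]
        if branching:  # diverge 60-90 degrees off the parent direction
            ang = rng.uniform(np.pi / 3, np.pi / 2)
            new_h = np.cos(ang) * heading + np.sin(ang) * _perp(heading)
        else:
            new_h = heading + 0.2 * rng.standard_normal(3)
        new_h /= np.linalg.norm(new_h)
        pos = t.nodes[nid].position + step_nm * new_h
        t.add_node(SkeletonNode(next_id, pos, rng.uniform(*radius_nm)))
        t.add_edge(nid, next_id)
        tips.append((next_id, new_h))
        if not branching:  # the walk moves on: new tip replaces its parent
            tips[-2] = tips[-1]
            tips.pop()
        next_id += 1
    return t


@pytest.fixture
def path_tree():
    """5-node straight path along x, 1 μm steps, constant radius 200 nm."""
    return make_tree("path",
                     [(i, (i * 1000.0, 0, 0), 200.0) for i in range(1, 6)],
                     [(i, i + 1) for i in range(1, 5)])


@pytest.fixture
def y_tree():
    """Y-shaped tree: one degree-3 branch point."""
    return make_tree("y",
                     [(1, (0, 0, 0), 200.0), (2, (1000, 0, 0), 200.0),
                      (3, (2000, 1000, 0), 200.0), (4, (2000, -1000, 0), 200.0)],
                     [(1, 2), (2, 3), (2, 4)])


@pytest.fixture
def flat_model():
    """Flat slab: anterior plane z = 0, posterior z = 20 μm, 40 μm square."""
    g = np.linspace(0, 40000.0, 5)
    gx, gy = np.meshgrid(g, g)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    ant = np.column_stack([xy, np.zeros(len(xy))])
    post = np.column_stack([xy, np.full(len(xy), 20000.0)])
    return lm.build_layer_model(ant, post)


@pytest.fixture(scope="session")
def curved_plate():
    """Session-wide synthetic curved plate: outline, analytic surfaces, model."""
    outline, surf = sd.gen_plate_outline(curvature_um=5.0, thickness_um=20.0,
                                         extent_um=(120.0, 150.0),
                                         n_points=400, seed=11)
    ant, post = lm.split_outline(outline)
    model = lm.build_layer_model(ant, post)
    return outline, surf, model
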