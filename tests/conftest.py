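import numpy as np
import pytest

from barreltree.morphometry import (
    Barrel,
    BarrelMap,
    DendriticTree,
    TracedNeuron,
)


def square_barrel(barrel_id="b0", center=(0.0, 0.0), half=75.0):
    """Square barrel: exact distances to the boundary are easy to reason about."""
    cx, cy = center
    ring = np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
        ]
    )
    return Barrel(barrel_id=barrel_id, center=np.array([cx, cy]), boundary=ring)


@pytest.fixture
def barrel_map():
    return BarrelMap(barrels=[square_barrel()])


def path_tree(points, tree_id="t", kind="BD"):
    """Unbranched polyline tree through the given 3-D points."""
    pts = np.asarray(points, float)
    parents = np.arange(-1, len(pts) - 1)
    return DendriticTree(tree_id=tree_id, nodes=pts, parents=parents, kind=kind)


def y_tree(origin=(0, 0, 0), stem=10.0, arm=10.0, tree_id="y"):
    """Stem along +x then two arms at +/-45 degrees, all in the plane."""
    o = np.asarray(origin, float)
    c = np.sqrt(2) / 2
    nodes = np.array(
        [
            o,
            o + [stem, 0, 0],
            o + [stem + arm * c, arm * c, 0],
            o + [stem + arm * c, -arm * c, 0],
        ]
    )
    parents = np.array([-1, 0, 1, 1])
    return DendriticTree(tree_id=tree_id, nodes=nodes, parents=parents, kind="BD")


def neuron_with_trees(trees, soma=(0, 0, 0), home="b0", nid="n0", session="P3_L"):
    return TracedNeuron(
        neuron_id=nid,
        session_id=session,
        soma_center=np.asarray(soma, float),
        trees=list(trees),
        home_barrel_id=home,
    )


def random_arbor(rng, origin, n_segments=4, seg_len=(8.0, 40.0)):
    """Random tortuous unbranched BD tree starting at ``origin``."""
    pts = [np.asarray(origin, float)]
    d = rng.normal(size=3)
    d[2] *= 0.2
    d /= np.linalg.norm(d)
    total = 0.0
    n_pts = rng.integers(3, 8)
    target = rng.uniform(*seg_len)
    for _ in range(n_pts):
        step = target / n_pts
        d2 = d + 0.4 * rng.normal(size=3) * [1, 1, 0.2]
        d2 /= np.linalg.norm(d2)
        pts.append(pts[-1] + d2 * step)
        total += step
    parents = np.arange(-1, len(pts) - 1)
    return DendriticTree(
        tree_id=f"r{rng.integers(1e9)}", nodes=np.array(pts), parents=parents,
        kind="BD",
    )
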