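"""Segment partition, orientation bias, soma position and AD-group rules."""

import numpy as np
import pytest

from barreltree.morphometry import (
    ADTrajectory,
    BarrelMap,
    Barrel,
    DegenerateGeometryError,
    DendriticTree,
    MorphometryError,
    StructuralError,
    UndefinedOBIError,
    classify_barrel_position,
    classify_group,
    compute_obi,
    fold_change,
    inside_outside_boundary,
    neuron_totals,
    partition_segments,
    tree_metrics,
    tree_origin_angle,
    tree_side,
)

from conftest import neuron_with_trees, path_tree, random_arbor, square_barrel, y_tree


# ---------------------------------------------------------------------------
# tree structure validation
# ---------------------------------------------------------------------------


def test_tree_requires_single_root_and_no_cycles():
    with pytest.raises(StructuralError):
        DendriticTree("bad", np.zeros((2, 3)), np.array([-1, -1]))
    nodes = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
    with pytest.raises(StructuralError):
        DendriticTree("cyc", nodes, np.array([2, 0, 1]))


def test_zero_length_edge_rejected():
    nodes = np.array([[0, 0, 0], [0, 0, 0]], float)
    with pytest.raises(StructuralError):
        DendriticTree("z", nodes, np.array([-1, 0]))


# ---------------------------------------------------------------------------
# segment partition and the 5 µm rule
# ---------------------------------------------------------------------------


def test_unbranched_path_is_one_segment():
    tree = path_tree([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
    segments, excluded = partition_segments(tree)
    assert len(segments) == 1
    assert segments[0].length == pytest.approx(20.0)
    assert segments[0].terminal
    assert excluded == 0.0


def test_y_tree_has_three_segments():
    segments, excluded = partition_segments(y_tree())
    assert len(segments) == 3
    assert excluded == 0.0
    assert sum(s.terminal for s in segments) == 2


def test_short_twig_is_pruned_and_shaft_merges():
    # 30 µm shaft with a 3 µm side twig at its midpoint: the twig is not a
    # segment, and without it the branch point dissolves
    nodes = np.array(
        [[0, 0, 0], [15, 0, 0], [30, 0, 0], [15, 3, 0]], float
    )
    parents = np.array([-1, 0, 1, 1])
    tree = DendriticTree("twig", nodes, parents)
    segments, excluded = partition_segments(tree)
    assert len(segments) == 1
    assert segments[0].length == pytest.approx(30.0)
    assert excluded == pytest.approx(3.0)
    # total length still includes the twig
    assert tree.total_length() == pytest.approx(33.0)


def test_twig_of_exactly_five_um_is_excluded():
    nodes = np.array([[0, 0, 0], [15, 0, 0], [30, 0, 0], [15, 5, 0]], float)
    tree = DendriticTree("t5", nodes, np.array([-1, 0, 1, 1]))
    segments, excluded = partition_segments(tree)
    assert len(segments) == 1 and excluded == pytest.approx(5.0)


def test_partition_conserves_total_length_on_random_trees():
    rng = np.random.default_rng(11)
    for _ in range(50):
        # random binary-ish tree built by attaching paths to random nodes
        nodes = [np.zeros(3)]
        parents = [-1]
        for _ in range(rng.integers(1, 5)):
            attach = int(rng.integers(len(nodes)))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n_steps = int(rng.integers(1, 5))
            step = rng.uniform(1.0, 12.0)
            idx = attach
            for _ in range(n_steps):
                nodes.append(nodes[idx] + d * step)
                parents.append(idx)
                idx = len(nodes) - 1
        tree = DendriticTree("r", np.array(nodes), np.array(parents))
        segments, excluded = partition_segments(tree)
        assert sum(s.length for s in segments) + excluded == pytest.approx(
            tree.total_length()
        )


# ---------------------------------------------------------------------------
# inside/outside boundary
# ---------------------------------------------------------------------------


def test_boundary_normal_points_at_barrel_center():
    bmap = BarrelMap([square_barrel(center=(10.0, 0.0), half=75.0)])
    neu = neuron_with_trees([], soma=(0, 0, 0))
    point, normal = inside_outside_boundary(neu, bmap)
    assert np.allclose(point, [0, 0])
    assert np.allclose(normal, [1, 0])


def test_boundary_normal_is_unit_vector():
    bmap = BarrelMap([square_barrel(center=(0.0, 0.0))])
    neu = neuron_with_trees([], soma=(3, 4, 0))
    _, normal = inside_outside_boundary(neu, bmap)
    assert np.allclose(normal, [-0.6, -0.8])


def test_soma_at_barrel_center_is_degenerate():
    bmap = BarrelMap([square_barrel()])
    neu = neuron_with_trees([], soma=(0, 0, 0))
    with pytest.raises(DegenerateGeometryError):
        inside_outside_boundary(neu, bmap)


# ---------------------------------------------------------------------------
# OBI
# ---------------------------------------------------------------------------


def _edge_map():
    # barrel center at (100, 0); soma at origin -> inside is x > 0
    return BarrelMap([square_barrel(center=(100.0, 0.0), half=75.0)])


def test_obi_is_one_when_all_bd_inside():
    tree = path_tree([[7, 0, 0], [30, 0, 0], [60, 0, 0]])
    neu = neuron_with_trees([tree])
    res = compute_obi(neu, _edge_map())
    assert res.obi == pytest.approx(1.0)


def test_obi_of_mirror_symmetric_arbor_is_exactly_half():
    inner = path_tree([[7, 0, 0], [20, 5, 0], [40, 10, 0]], tree_id="in")
    outer = path_tree([[-7, 0, 0], [-20, 5, 0], [-40, 10, 0]], tree_id="out")
    neu = neuron_with_trees([inner, outer])
    res = compute_obi(neu, _edge_map())
    assert res.obi == 0.5
    assert res.inner_length == pytest.approx(res.outer_length)


def test_obi_hand_example_30_in_10_out():
    inner = path_tree([[7, 0, 0], [22, 0, 0], [37, 0, 0]], tree_id="in")  # 30 µm
    outer = path_tree([[-7, 0, 0], [-17, 0, 0]], tree_id="out")  # 10 µm
    neu = neuron_with_trees([inner, outer])
    res = compute_obi(neu, _edge_map())
    assert res.obi == pytest.approx(0.75)


def test_obi_undefined_without_bd_length():
    neu = neuron_with_trees([])
    with pytest.raises(UndefinedOBIError):
        compute_obi(neu, _edge_map())


def test_obi_excludes_apical_dendrite_and_axon():
    inner = path_tree([[7, 0, 0], [37, 0, 0]], tree_id="in")
    ad = path_tree([[0, 0, 7], [0, 0, 120]], tree_id="ad", kind="AD")
    ax = path_tree([[-7, 0, -7], [-60, 0, -7]], tree_id="ax", kind="axon")
    neu = neuron_with_trees([inner, ad, ax])
    res = compute_obi(neu, _edge_map())
    assert res.obi == pytest.approx(1.0)
    assert res.inner_length + res.outer_length == pytest.approx(30.0)


def test_obi_conservation_and_mirror_identity_random_arbors():
    rng = np.random.default_rng(5)
    bmap = _edge_map()
    for _ in range(60):
        trees = [
            random_arbor(rng, origin=[rng.uniform(-7, 7), rng.uniform(-7, 7), 0])
            for _ in range(rng.integers(1, 4))
        ]
        neu = neuron_with_trees(trees)
        res = compute_obi(neu, bmap)
        total = sum(
            s.length
            for t in trees
            for s in partition_segments(t)[0]
        )
        assert res.inner_length + res.outer_length == pytest.approx(total, rel=1e-9)
        # mirror across the boundary (x -> -x): OBI flips to 1 - OBI
        mirrored = [
            DendriticTree(t.tree_id, t.nodes * [-1, 1, 1], t.parents, t.kind)
            for t in trees
        ]
        res_m = compute_obi(neuron_with_trees(mirrored), bmap)
        assert res_m.obi == pytest.approx(1.0 - res.obi, abs=1e-9)


def test_obi_invariant_under_rigid_rotation():
    rng = np.random.default_rng(9)
    trees = [random_arbor(rng, origin=[7, 0, 0]) for _ in range(3)]
    neu = neuron_with_trees(trees, soma=(0, 0, 0))
    base = compute_obi(neu, _edge_map()).obi
    for theta in (30.0, 117.0, -66.0):
        th = np.radians(theta)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rtrees = [
            DendriticTree(t.tree_id, t.nodes @ rot.T, t.parents, t.kind)
            for t in trees
        ]
        center2 = rot[:2, :2] @ np.array([100.0, 0.0])
        half = 75.0
        ring = np.array(
            [
                center2 + rot[:2, :2] @ np.array(v)
                for v in [[-half, -half], [half, -half], [half, half], [-half, half]]
            ]
        )
        bmap = BarrelMap([Barrel("b0", center2, ring)])
        rneu = neuron_with_trees(rtrees, soma=(0, 0, 0))
        assert compute_obi(rneu, bmap).obi == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# soma position classification (12.5 µm rule)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "soma_x, expected",
    [
        (70.0, "edge"),       # 5 µm inside the x = 75 boundary
        (0.0, "center"),      # barrel centroid of a 150 µm barrel
        (62.5, "edge"),       # exactly 12.5 µm: inclusive
        (50.0, "center"),     # 25 µm from boundary
        (95.0, "outside_field"),  # 20 µm beyond the boundary
        (80.0, "edge"),       # 5 µm outside the polygon still counts as edge
    ],
)
def test_barrel_position_rule(soma_x, expected):
    bmap = BarrelMap([square_barrel()])
    neu = neuron_with_trees([], soma=(soma_x, 0, 0))
    assert classify_barrel_position(neu, bmap) == expected


# ---------------------------------------------------------------------------
# AD group classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lengths, expected",
    [
        ([150, 120, 60, 10], "Group1"),
        ([100, 130, 170, 210], "Group2"),
        ([0, 0, 0, 0], "Group1"),
        ([150, 190, 230, 120], "Group1"),   # extension before retraction
        ([100, 95, 100, 98], "Group2"),     # jitter below the 10 µm delta
    ],
)
def test_group_classification(lengths, expected):
    traj = ADTrajectory("n", [f"s{i}" for i in range(len(lengths))], lengths)
    assert classify_group(traj) == expected


def test_group_needs_two_sessions():
    with pytest.raises(MorphometryError):
        classify_group(ADTrajectory("n", ["s0"], [100.0]))


def test_group_invariant_to_session_relabeling():
    lengths = [150.0, 120.0, 60.0, 10.0]
    a = ADTrajectory("n", ["a", "b", "c", "d"], lengths)
    b = ADTrajectory("n", ["P3_L", "P4_L", "P5_L", "P6_L"], lengths)
    assert classify_group(a) == classify_group(b)


def test_monotone_trajectory_flips_class_under_reversal():
    up = [40.0, 80.0, 120.0, 160.0]
    t_up = ADTrajectory("n", list("abcd"), up)
    t_down = ADTrajectory("n", list("abcd"), up[::-1])
    assert classify_group(t_up) == "Group2"
    assert classify_group(t_down) == "Group1"


# ---------------------------------------------------------------------------
# tree side, angle, totals, fold change
# ---------------------------------------------------------------------------


def test_tree_side_and_angle():
    boundary = (np.array([0.0, 0.0]), np.array([1.0, 0.0]))
    inner = path_tree([[7, 0, 0], [20, 0, 0]])
    outer = path_tree([[-7, 0, 0], [-20, 0, 0]])
    on_boundary = path_tree([[0, 7, 0], [0, 20, 0]])
    assert tree_side(inner, boundary) == "inner"
    assert tree_side(outer, boundary) == "outer"
    assert tree_side(on_boundary, boundary) == "inner"  # tie rule
    assert tree_origin_angle(inner, boundary) == pytest.approx(0.0)
    assert abs(tree_origin_angle(outer, boundary)) == pytest.approx(180.0)
    assert tree_origin_angle(on_boundary, boundary) == pytest.approx(90.0)


def test_tree_metrics_examples():
    length, tips, segs = tree_metrics(y_tree(stem=10, arm=10))
    assert (length, tips, segs) == (pytest.approx(30.0), 2, 3)
    length, tips, segs = tree_metrics(path_tree([[0, 0, 0], [20, 0, 0]]))
    assert (length, tips, segs) == (pytest.approx(20.0), 1, 1)


def test_neuron_totals_counts_sides():
    boundary = (np.array([0.0, 0.0]), np.array([1.0, 0.0]))
    inner = [
        path_tree([[7, y, 0], [30, y, 0]], tree_id=f"i{y}") for y in range(4)
    ]
    outer = [
        path_tree([[-7, y, 0], [-30, y, 0]], tree_id=f"o{y}") for y in range(2)
    ]
    totals = neuron_totals(neuron_with_trees(inner + outer), boundary)
    assert totals["n_trees_inner"] == 4
    assert totals["n_trees_outer"] == 2
    assert totals["total_bd_length"] == pytest.approx(6 * 23.0)


def test_fold_change_examples():
    assert fold_change([100, 50], [100, 50])[0] == pytest.approx(1.0)
    assert fold_change([100, 50], [300, 150])[0] == pytest.approx(3.0)
    ratio, per = fold_change([100, 100], [200, 400])
    assert ratio == pytest.approx(3.0)
    assert per == pytest.approx([2.0, 4.0])
    with pytest.raises(MorphometryError):
        fold_change([0.0], [10.0])
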