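"""Network structure, rescaling, classification, layout and file I/O."""

import numpy as np
import pandas as pd
import pytest

import lungdep as ld
from lungdep.network import attach_default_acini

from conftest import build_network


@pytest.fixture
def three_airway_net():
    return build_network(
        parent=[-1, 0, 0], generation=[1, 2, 2],
        length=[0.05, 0.02, 0.018], radius=[0.004, 0.0022, 0.002],
        proximal=[[0, 0, 0], [0, 0, -0.05], [0, 0, -0.05]],
        distal=[[0, 0, -0.05], [0.012, 0, -0.06], [-0.011, 0, -0.062]],
        lobe=["TR", "RU", "LU"])


def test_generation_bookkeeping_matches_path_traversal(small_net):
    """g equals 1 + number of edges on the path to the trachea."""
    net = small_net
    for i in range(net.n_airways):
        depth, j = 0, i
        while net.parent_index[j] >= 0:
            j = net.parent_index[j]
            depth += 1
        assert net.generation[i] == depth + 1


def test_dead_space_is_summed_airway_volume(three_airway_net):
    net = three_airway_net
    expected = np.sum(np.pi * net.radius**2 * net.length)
    assert net.dead_space == pytest.approx(expected, rel=1e-12)


class TestRescale:
    def test_identity_at_same_frc(self, three_airway_net):
        out = ld.rescale_to_frc(three_airway_net, 3.3)
        assert np.allclose(out.length, three_airway_net.length, rtol=1e-14)
        assert np.allclose(out.radius, three_airway_net.radius, rtol=1e-14)

    def test_half_frc_gives_cube_root_two(self, three_airway_net):
        net = three_airway_net
        net.frc = 1.65e-3
        out = ld.rescale_to_frc(net, 3.3)
        assert out.length[0] / net.length[0] == pytest.approx(
            2.0 ** (1.0 / 3.0), rel=1e-12)

    def test_dead_space_scales_with_cube(self, small_net):
        out = ld.rescale_to_frc(small_net, 4.5)
        factor = (4.5e-3 / small_net.frc) ** (1.0 / 3.0)
        assert out.dead_space / small_net.dead_space == pytest.approx(
            factor**3, rel=1e-10)

    def test_aspect_ratios_invariant(self, small_net):
        out = ld.rescale_to_frc(small_net, 2.0)
        assert np.allclose(out.length / out.radius,
                           small_net.length / small_net.radius, rtol=1e-12)

    def test_rejects_nonpositive_target(self, three_airway_net):
        with pytest.raises(ValueError):
            ld.rescale_to_frc(three_airway_net, -1.0)


class TestClassify:
    def test_boundary_at_generation_ten(self, medium_net):
        labels = ld.classify_airways(medium_net)
        g = medium_net.generation
        assert np.all(labels[g <= 9] == "central")
        assert np.all(labels[g >= 10] == "distal")
        assert labels[medium_net.root] == "central"  # trachea, g=1

    def test_shallow_tree_is_all_central(self, symmetric_net):
        assert np.all(ld.classify_airways(symmetric_net) == "central")


class TestPlanarLayout:
    def test_radii_are_generation_rings(self, small_net):
        lay = ld.planar_layout(small_net, R0=2.0)
        assert np.allclose(lay.radius,
                           (small_net.generation - 1) * 2.0)

    def test_daughters_at_half_generation_angle(self, symmetric_net):
        net = symmetric_net
        lay = ld.planar_layout(net)
        children = net.children()
        root = net.root
        a, b = children[root]
        assert lay.theta[root] == 0.0
        assert sorted([lay.theta[a], lay.theta[b]]) == pytest.approx(
            [-np.pi / 2, np.pi / 2])
        # a generation-2 parent offsets its daughters by 2^-2 pi
        ga, gb = children[a]
        assert sorted([lay.theta[ga] - lay.theta[a],
                       lay.theta[gb] - lay.theta[a]]) == pytest.approx(
            [-np.pi / 4, np.pi / 4])

    def test_sibling_subtrees_do_not_interleave(self, small_net):
        """Angular intervals of the two subtrees under any bifurcation are
        disjoint (the 2^-g halving guarantees this)."""
        net = small_net
        lay = ld.planar_layout(net)
        children = net.children()

        def subtree_angles(i):
            out, stack = [], [i]
            while stack:
                j = stack.pop()
                out.append(lay.theta[j])
                stack.extend(children[j])
            return min(out), max(out)

        for i in range(net.n_airways):
            if len(children[i]) == 2:
                a, b = children[i]
                lo_a, hi_a = subtree_angles(a)
                lo_b, hi_b = subtree_angles(b)
                assert hi_a < lo_b or hi_b < lo_a


class TestNetworkIO:
    def test_write_read_round_trip(self, three_airway_net, tmp_path):
        path = tmp_path / "net.csv"
        ld.write_network(path, three_airway_net)
        back = ld.read_network(path)
        for attr in ("ids", "parent_index", "generation"):
            assert np.array_equal(getattr(back, attr),
                                  getattr(three_airway_net, attr))
        for attr in ("length", "radius", "proximal", "distal"):
            assert np.allclose(getattr(back, attr),
                               getattr(three_airway_net, attr), rtol=1e-12)
        assert list(back.lobe) == list(three_airway_net.lobe)
        assert back.frc == pytest.approx(three_airway_net.frc, rel=1e-12)

    def test_missing_parent_is_reported_with_id(self, three_airway_net,
                                                tmp_path):
        path = tmp_path / "net.csv"
        ld.write_network(path, three_airway_net)
        frame = pd.read_csv(path, comment=None, skiprows=1)
        frame.loc[frame["id"] == 2, "parent_id"] = 99
        path2 = tmp_path / "bad.csv"
        path2.write_text("# frc_m3=0.0033\n" + frame.to_csv(index=False))
        with pytest.raises(ValueError, match="2"):
            ld.read_network(path2)

    def test_two_roots_rejected(self, three_airway_net, tmp_path):
        path = tmp_path / "net.csv"
        ld.write_network(path, three_airway_net)
        frame = pd.read_csv(path, skiprows=1)
        frame.loc[frame["id"] == 1, ["parent_id", "generation"]] = [-1, 1]
        path2 = tmp_path / "bad.csv"
        path2.write_text("# frc_m3=0.0033\n" + frame.to_csv(index=False))
        with pytest.raises(ValueError, match="roots"):
            ld.read_network(path2)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# frc_m3=0.0033\nid,parent_id\n0,-1\n")
        with pytest.raises(ValueError, match="missing columns"):
            ld.read_network(path)


def test_airway_view_fields(three_airway_net):
    aw = three_airway_net.airway(1)
    assert aw.parent_id == 0
    assert aw.generation == 2
    assert aw.lobe == "RU"
    assert aw.acinus_id is not None


def test_terminal_airways_have_exactly_one_acinus(small_net):
    net = small_net
    counts = np.zeros(net.n_airways, dtype=int)
    for t in net.acinus_terminal_airway:
        counts[t] += 1
    term = net.is_terminal
    assert np.all(counts[term] == 1)
    assert np.all(counts[~term] == 0)
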