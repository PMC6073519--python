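"""Mode classification: synthetic pure fields, invariances, labeling rules."""

import numpy as np
import pytest

from dnanma import (analyze, ball_mode_scores, get_design, label_modes,
                    ring_mode_scores, tile_mode_scores)
from dnanma.builder import build_tile
from dnanma.coarse_grain import coarse_grain
from dnanma.mode_metrics import degenerate_groups


def field(cg, fn):
    """(3N, 1) column from a per-bead displacement function."""
    v = np.array([fn(cg.positions[b], b) for b in range(cg.n_beads)])
    return v.reshape(-1, 1).reshape(3 * cg.n_beads, 1)


@pytest.fixture(scope="module")
def tile_cg():
    return coarse_grain(build_tile(get_design("tile")))


class TestRingScores:
    def test_uniform_inner_z_is_pure_out_of_plane_translation(self, r1c_cg):
        inner = r1c_cg.nt_roles == "inner_circle"
        v = np.zeros((r1c_cg.n_beads, 3))
        v[inner, 2] = 1.0
        s = ring_mode_scores(v.reshape(-1, 1).reshape(3 * r1c_cg.n_beads, 1),
                             r1c_cg)
        assert s["O_T"] == pytest.approx(1.0, abs=1e-9)
        assert all(val < 0.1 for key, val in s.items() if key != "O_T")

    def test_cosine_inner_z_is_seesaw(self, r1c_cg):
        theta = np.arctan2(r1c_cg.positions[:, 1], r1c_cg.positions[:, 0])
        inner = r1c_cg.nt_roles == "inner_circle"
        v = np.zeros((r1c_cg.n_beads, 3))
        v[inner, 2] = np.cos(theta[inner])
        s = ring_mode_scores(v.reshape(3 * r1c_cg.n_beads, 1), r1c_cg)
        assert s["O_R"] > 0.9
        assert all(val < 0.1 for key, val in s.items() if key != "O_R")

    def test_uniform_inner_xy_is_in_plane_translation(self, r1c_cg):
        inner = r1c_cg.nt_roles == "inner_circle"
        v = np.zeros((r1c_cg.n_beads, 3))
        v[inner, 0] = 1.0
        s = ring_mode_scores(v.reshape(3 * r1c_cg.n_beads, 1), r1c_cg)
        assert s["I_T"] == pytest.approx(1.0, abs=1e-9)

    def test_outer_wave_is_zigzag(self, r1c_cg):
        theta = np.arctan2(r1c_cg.positions[:, 1], r1c_cg.positions[:, 0])
        outer = r1c_cg.nt_roles == "outer_circle"
        v = np.zeros((r1c_cg.n_beads, 3))
        v[outer, 2] = np.cos(3 * theta[outer])
        s = ring_mode_scores(v.reshape(3 * r1c_cg.n_beads, 1), r1c_cg)
        assert s["zigzag"] > 0.9
        assert all(val < 0.1 for key, val in s.items() if key != "zigzag")

    def test_coherent_bridge_lift_is_spiderlike(self, r1c_cg):
        bridge = r1c_cg.nt_roles == "bridge"
        v = np.zeros((r1c_cg.n_beads, 3))
        v[bridge, 2] = 1.0
        s = ring_mode_scores(v.reshape(3 * r1c_cg.n_beads, 1), r1c_cg)
        assert s["spiderlike"] == pytest.approx(1.0, abs=1e-9)
        assert s["mixed_spiderlike"] < 0.1

    def test_alternating_bridges_are_mixed_spiderlike(self, r1c_cg):
        bridge = r1c_cg.nt_roles == "bridge"
        tiles = r1c_cg.nt_tiles
        v = np.zeros((r1c_cg.n_beads, 3))
        v[bridge, 2] = np.where(tiles[bridge] % 2 == 0, 1.0, -1.0)
        s = ring_mode_scores(v.reshape(3 * r1c_cg.n_beads, 1), r1c_cg)
        assert s["mixed_spiderlike"] > 0.9
        assert s["spiderlike"] < 0.05

    def test_scores_invariant_to_sign_and_scale(self, r1c_cg):
        theta = np.arctan2(r1c_cg.positions[:, 1], r1c_cg.positions[:, 0])
        inner = r1c_cg.nt_roles == "inner_circle"
        v = np.zeros((r1c_cg.n_beads, 3))
        v[inner, 2] = np.cos(theta[inner])
        base = ring_mode_scores(v.reshape(3 * r1c_cg.n_beads, 1), r1c_cg)
        for factor in (-1.0, 17.3):
            s = ring_mode_scores(factor * v.reshape(3 * r1c_cg.n_beads, 1),
                                 r1c_cg)
            for key in base:
                assert s[key] == pytest.approx(base[key], abs=1e-9)


class TestBallScores:
    def test_uniform_radial_field_is_overall_breathing(self, mini_ball):
        cg = mini_ball.cg
        x = cg.positions - cg.positions.mean(axis=0)
        v = x / np.linalg.norm(x, axis=1)[:, None]
        s = ball_mode_scores(v.reshape(3 * cg.n_beads, 1), cg)
        assert s["O_B"] == pytest.approx(1.0, abs=1e-9)

    def test_rigid_rotation_has_no_breathing(self, mini_ball):
        cg = mini_ball.cg
        x = cg.positions - cg.positions.mean(axis=0)
        v = np.cross(np.array([0.0, 0.0, 1.0]), x)
        s = ball_mode_scores(v.reshape(3 * cg.n_beads, 1), cg)
        assert s["O_B"] < 1e-9
        assert s["L_B"] < 0.1


class TestTileScores:
    def test_arm_scissor_is_tweezer(self, tile_cg):
        cg = tile_cg
        arm_of = np.array([s.split(":")[-1][:2] for s in cg.nt_strands])
        center = cg.positions[cg.nt_roles == "arm"].mean(axis=0)
        x = cg.positions - center
        v = np.zeros_like(x)
        for aid, sign in (("A0", 1.0), ("A1", -1.0)):
            sel = np.isin(cg.nt_roles, ("arm", "sticky_end")) & (arm_of == aid)
            # per-arm rotation about the tile normal
            v[sel] = sign * np.cross(np.array([0.0, 0.0, 1.0]), x[sel])
        s = tile_mode_scores(v.reshape(3 * cg.n_beads, 1), cg)
        assert s["tweezer"] > 0.9
        assert s["bending"] < 0.05

    def test_out_of_plane_arm_field_is_bending(self, tile_cg):
        cg = tile_cg
        v = np.zeros((cg.n_beads, 3))
        arm = cg.nt_roles == "arm"
        rho = np.linalg.norm(cg.positions[:, :2], axis=1)
        v[arm, 2] = rho[arm]
        s = tile_mode_scores(v.reshape(3 * cg.n_beads, 1), cg)
        assert s["bending"] > 0.9


class TestLabeling:
    def test_rigid_modes_never_labeled(self, toy_fixtures):
        fx = toy_fixtures[4]
        ms = analyze(fx.cg, n_modes=12)
        labels = label_modes(ms, fx.cg, "ring")
        assert len(labels) == 12 - ms.zero_mode_count
        assert min(lab.mode_number for lab in labels) == 1

    def test_degenerate_pair_shares_label_under_remixing(self, r1c_run, rng):
        """Any orthonormal remixing of a degenerate pair keeps its scores."""
        ms = r1c_run["modes"]
        cg = r1c_run["cg"]
        lam, vecs = ms.nonrigid()
        groups = [g for g in degenerate_groups(lam[:8]) if len(g) == 2]
        assert groups, "expected at least one degenerate pair"
        pair = vecs[:, groups[0]]
        a = rng.uniform(0, 2 * np.pi)
        Q = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        s1 = ring_mode_scores(pair, cg)
        s2 = ring_mode_scores(pair @ Q, cg)
        for key in s1:
            assert s2[key] == pytest.approx(s1[key], abs=1e-8)

    def test_mixed_label_when_scores_tie(self, toy_fixtures):
        from dnanma.mode_metrics import label_modes as lm
        fx = toy_fixtures[4]
        ms = analyze(fx.cg, n_modes=10)
        labels = lm(ms, fx.cg, "ring", margin=2.0)   # force ties
        assert all(lab.label == "mixed" for lab in labels)
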