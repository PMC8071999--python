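import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from watermaze import cueweight, synthetic
from watermaze.geometry import dist, rotate_about
from watermaze.synthetic import AgentParams, ScheduleConfig


class TestMoveMountain:
    def test_quarter_turn_about_target(self, env):
        target = np.asarray(env.target_pos("T1"))
        m = env.mountains[0]
        d = dist(m.pos, target)
        # construct a mountain due north of the target and rotate +90 (CCW)
        north = synthetic.Mountain("MN", 0.0, 300.0)
        env2 = synthetic.build_environment(
            seed=1, mountains=(north,) + env.mountains[1:])
        # place target at origin for a clean quarter-turn check
        move = cueweight.move_mountain(env2, "MN", (0.0, 0.0), 90.0)
        assert move.moved_pos[0] == pytest.approx(-300.0)  # due west
        assert abs(move.moved_pos[1]) < 1e-9

    def test_zero_angle_forbidden(self, env):
        with pytest.raises(ValueError):
            cueweight.move_mountain(env, env.mountains[0].id, (0, 0), 0.0)

    def test_unknown_mountain(self, env):
        with pytest.raises(KeyError):
            cueweight.move_mountain(env, "M99", (0, 0), 20.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_preserves_radius(self, env, seed):
        rng = np.random.default_rng(seed)
        target = rng.uniform(-2, 2, 2)
        angle = rng.uniform(-180, 180)
        if angle == 0:
            angle = 20.0
        move = cueweight.move_mountain(env, env.mountains[1].id, target, angle)
        assert dist(move.moved_pos, target) == pytest.approx(
            dist(move.original_pos, target), abs=1e-6)


class TestImpliedTarget:
    def test_target_at_centre_is_fixed_point(self, env):
        move = cueweight.move_mountain(env, env.mountains[0].id, (0.5, 0.5), 20.0)
        implied = cueweight.implied_moved_target((0.0, 0.0), move)
        assert np.allclose(implied, (0.0, 0.0))

    def test_quarter_turn_of_bearing_moves_target_quarter_turn(self):
        # distal mountain due north rotated so its bearing shifts +90 (to west)
        m = synthetic.Mountain("MN", 0.0, 300.0)
        move = cueweight.MountainMove("MN", 90.0, tuple(m.pos), (-300.0, 0.0))
        implied = cueweight.implied_moved_target((1.0, 0.0), move)  # 1 m east
        # +90 CCW about the centre carries east to north
        assert np.allclose(implied, (0.0, 1.0), atol=1e-9)

    def test_distal_rotation_bearing_shift_near_nominal(self):
        # mountain 350 m away rotated 20 deg about a target 1 m from centre
        m = synthetic.Mountain("M1", 37.0, 350.0)
        target = (0.0, 1.0)
        moved = rotate_about(m.pos, target, 20.0)
        move = cueweight.MountainMove("M1", 20.0, tuple(m.pos), tuple(moved))
        implied = cueweight.implied_moved_target(target, move)
        from watermaze.geometry import bearing, wrap_angle
        dphi = wrap_angle(bearing(implied) - bearing(target))
        assert abs(dphi - 20.0) < 0.2
        # and stays at the target's radius from the centre
        assert np.linalg.norm(implied) == pytest.approx(1.0, abs=1e-9)

    def test_translation_mode_preserves_mountain_vector(self):
        m = synthetic.Mountain("M1", 0.0, 300.0)
        moved = rotate_about(m.pos, (0, 1), 20.0)
        move = cueweight.MountainMove("M1", 20.0, tuple(m.pos), tuple(moved))
        implied = cueweight.implied_moved_target((0, 1), move, mode="translation")
        shift = np.asarray(move.moved_pos) - np.asarray(move.original_pos)
        assert np.allclose(implied, np.asarray([0, 1]) + shift)


class TestWeightingIndex:
    target = (1.0, 0.0)
    implied = (0.0, 1.0)

    def test_response_at_static_target_weights_static_cues_fully(self):
        res = cueweight.weighting_index(self.target, self.target, self.implied)
        assert res.w == pytest.approx(1.0)

    def test_response_at_implied_target_weights_moved_cue_fully(self):
        res = cueweight.weighting_index(self.implied, self.target, self.implied)
        assert res.w == pytest.approx(0.0)

    def test_equidistant_response_weights_equally(self):
        res = cueweight.weighting_index((0.5, 0.5), self.target, self.implied)
        assert res.w == pytest.approx(0.5)

    def test_undefined_when_targets_coincide(self):
        with pytest.raises(ValueError):
            cueweight.weighting_index((0, 0), self.target, self.target)

    @given(st.floats(-170, 170), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_rigid_transforms(self, angle, dx, dy):
        response = np.array([0.3, 0.6])
        pts = [response, np.asarray(self.target), np.asarray(self.implied)]
        moved = [rotate_about(p, (0, 0), angle) + np.array([dx, dy]) for p in pts]
        a = cueweight.weighting_index(*pts)
        b = cueweight.weighting_index(*moved)
        assert b.w == pytest.approx(a.w, abs=1e-9)

    def test_monotone_along_segment(self):
        ws = []
        for lam in np.linspace(0, 1, 11):
            p = (1 - lam) * np.asarray(self.implied) + lam * np.asarray(self.target)
            ws.append(cueweight.weighting_index(p, self.target, self.implied).w)
        assert all(b > a for a, b in zip(ws, ws[1:]))

    def test_mean_index_biased_toward_half_under_noise(self):
        # per-trial W is not an unbiased estimator of the generative w:
        # under symmetric noise its mean is pulled toward 0.5
        rng = np.random.default_rng(0)
        w_true = 0.1
        centre = w_true * np.asarray(self.target) + (1 - w_true) * np.asarray(self.implied)
        responses = centre + rng.normal(0, 0.8, size=(4000, 2))
        ws = [cueweight.weighting_index(r, self.target, self.implied).w
              for r in responses]
        assert np.mean(ws) > w_true + 0.05


class TestFitAgentParams:
    target = np.array([1.5, 0.5])
    implied = np.array([0.2, 1.6])

    def _trials(self, w, sigma, n, seed=0):
        rng = np.random.default_rng(seed)
        centre = w * self.target + (1 - w) * self.implied
        return [(centre + rng.normal(0, sigma, 2), self.target, self.implied)
                for _ in range(n)]

    def test_noiseless_recovery_exact(self):
        w_hat, s_hat = cueweight.fit_agent_params(self._trials(0.3, 0.0, 5))
        assert w_hat == pytest.approx(0.3, abs=1e-12)
        assert s_hat == pytest.approx(0.0, abs=1e-12)

    def test_all_responses_at_static_target(self):
        trials = [(self.target, self.target, self.implied)] * 3
        w_hat, s_hat = cueweight.fit_agent_params(trials)
        assert w_hat == 1.0 and s_hat == pytest.approx(0.0)

    def test_monte_carlo_recovery(self):
        w_hat, s_hat = cueweight.fit_agent_params(self._trials(0.45, 0.5, 100, seed=7))
        assert abs(w_hat - 0.45) <= 0.10
        assert abs(s_hat - 0.5) / 0.5 <= 0.20

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            cueweight.fit_agent_params(self._trials(0.5, 0.1, 1))

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            cueweight.fit_agent_params([((0, 0), (1, 1), (1, 1))] * 3)
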