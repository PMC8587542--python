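"""Ground reactions: totals, contact state machine, QP decomposition."""

import numpy as np
import pytest

from wbid.constants import G
from wbid.grf import (decompose_grf, detect_contact, hand_loads,
                      stance_moment_map, total_grf, total_grm)
from wbid.synthetic import contact_profile


class TestTotals:
    def test_stationary_subject_supports_body_weight(self, stand_trial,
                                                     model, subject):
        F = total_grf(stand_trial.states, model)
        assert np.abs(F[:, :2]).max() < 1e-9
        assert np.abs(F[:, 2] - subject.mass * G).max() < 1e-9

    def test_static_held_mass_adds_its_weight(self, lift_trial, model,
                                              subject):
        # within the grip plateau the vertical total carries body + box
        F = total_grf(lift_trial.states, model, lift_trial.loads)
        a, b = lift_trial.manifest["load_schedule"]["interval"]
        ramp = lift_trial.manifest["load_schedule"]["ramp_frames"]
        mid = (a + b) // 2
        static_expected = (subject.mass + 17.0) * G
        # remove the motion contribution using the truth states
        inertial = sum(model.segments[s].mass
                       * lift_trial.states.segments[s].acc[mid, 2]
                       for s in model.segments)
        assert F[mid, 2] - inertial == pytest.approx(static_expected, rel=1e-9)
        assert ramp < (b - a) / 2

    def test_total_grm_symmetric_stance_has_no_horizontal_moment(
            self, stand_trial, model):
        M = total_grm(stand_trial.states, model)
        assert np.abs(M[:, 0]).max() < 1e-6   # roll
        # pitch moment is a constant posture offset (CoM slightly anterior
        # of the pelvic origin) and must be constant in time
        assert np.ptp(M[:, 1]) < 1e-9

    def test_point_mass_weight_moment_cross_product(self):
        # single point mass at l=(0.5,0,0): -l x W = (0, -49.05, 0)
        l = np.array([0.5, 0.0, 0.0])
        W = np.array([0.0, 0.0, -98.1])
        assert np.allclose(-np.cross(l, W), [0.0, -49.05, 0.0])

    def test_totals_match_independent_oracle(self, gait_trial, model):
        from wbid.synthetic import truth_total_reaction
        F = total_grf(gait_trial.states, model, gait_trial.loads)
        M = total_grm(gait_trial.states, model, gait_trial.loads)
        F2, M2 = truth_total_reaction(gait_trial.states, model,
                                      gait_trial.loads)
        assert np.abs(F - F2).max() < 1e-6
        assert np.abs(M - M2).max() < 1e-6


class TestContactDetection:
    def test_slow_constant_toe_speed_is_stance_throughout(self):
        n = 200
        tl = detect_contact({"r": np.full(n, 0.5)}, {"r": np.full(n, 0.5)},
                            v_th=1.2)
        assert tl.stance["r"].all()

    def test_upward_threshold_crossing_starts_swing(self):
        n = 120
        toe = np.linspace(0.0, 2.4, n)     # crosses 1.2 at frame 60
        tl = detect_contact({"r": toe}, {"r": np.zeros(n)}, v_th=1.2)
        first_swing = int(np.flatnonzero(~tl.stance["r"])[0])
        assert abs(first_swing - 60) <= 1
        assert not tl.stance["r"][first_swing:].any()

    def test_heel_peak_starts_swing_while_toe_slow(self):
        p = contact_profile("leg_lift")
        tl = detect_contact({"x": p["toe_speed"]}, {"x": p["heel_speed"]},
                            v_th=p["v_th"], frame_rate=p["frame_rate"])
        trans = dict((kind, frame) for frame, kind in
                     [(f, k) for f, k in tl.transitions("x")])
        swing_onsets = [f for f, k in tl.transitions("x") if k == "swing"]
        assert len(swing_onsets) == 1
        assert abs(swing_onsets[0] - p["events"]["lift"]) <= 1

    def test_gait_profile_recovers_both_rules(self):
        p = contact_profile("gait")
        tl = detect_contact({"x": p["toe_speed"]}, {"x": p["heel_speed"]},
                            v_th=p["v_th"], frame_rate=p["frame_rate"])
        trans = tl.transitions("x")
        assert len(trans) == 2
        (f_off, k_off), (f_on, k_on) = trans
        assert (k_off, k_on) == ("swing", "stance")
        assert abs(f_off - p["events"]["toe_off"]) <= 1      # heel rule
        assert abs(f_on - p["events"]["heel_strike"]) <= 1   # threshold rule

    def test_weight_shift_detected_as_non_bearing(self):
        p = contact_profile("weight_shift")
        tl = detect_contact({"l": p["toe_speed"], "r": np.zeros_like(p["toe_speed"])},
                            {"l": p["heel_speed"], "r": np.zeros_like(p["heel_speed"])},
                            v_th=p["v_th"], frame_rate=p["frame_rate"])
        a, b = p["events"]["window"]
        assert not tl.stance["l"][a:b].all()    # left unloads in the window
        assert tl.stance["r"].all()             # right stays planted
        assert tl.stance["l"][:a].all() and tl.stance["l"][b + 2:].all()

    def test_unequal_trace_lengths_rejected(self):
        with pytest.raises(ValueError):
            detect_contact({"r": np.zeros(10)}, {"r": np.zeros(12)})

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_contact({"r": np.zeros(10)}, {"r": np.zeros(10)}, v_th=0.0)


class TestDecomposition:
    def test_symmetric_static_stance_splits_evenly(self, stand_trial, model,
                                                   subject):
        r = stand_trial.reactions
        half = subject.mass * G / 2
        assert np.abs(r.force["r"][:, 2] - half).max() < 1e-6
        assert np.abs(r.force["l"][:, 2] - half).max() < 1e-6

    def test_single_stance_frame_gets_full_total(self, gait_trial):
        r = gait_trial.reactions
        s_r, s_l = r.stance["r"], r.stance["l"]
        only_r = s_r & ~s_l
        assert only_r.any()
        assert np.allclose(r.force["r"][only_r], r.force_total[only_r])
        assert np.allclose(r.force["l"][only_r], 0.0)

    def test_conservation_and_vertical_sign_on_all_trials(
            self, stand_trial, gait_trial, lift_trial):
        for trial in (stand_trial, gait_trial, lift_trial):
            r = trial.reactions
            contact = r.stance["r"] | r.stance["l"]
            errF = np.linalg.norm(
                r.force["r"] + r.force["l"] - r.force_total, axis=1)
            errM = np.linalg.norm(
                r.moment["r"] + r.moment["l"] - r.moment_total, axis=1)
            assert errF[contact].max() <= 1e-8
            assert errM[contact].max() <= 1e-8
            assert r.force["r"][:, 2].min() >= -1e-10
            assert r.force["l"][:, 2].min() >= -1e-10

    def test_qp_beats_random_feasible_points(self, offset_stand_trial, rng):
        trial = offset_stand_trial
        model = trial.model
        A, c0 = stance_moment_map(trial.states, model, trial.total_force,
                                  trial.total_moment)
        t = 30
        x_star = np.concatenate([trial.reactions.force["r"][t],
                                 trial.reactions.moment["r"][t]])
        best = np.sum((A[t] @ x_star + c0[t]) ** 2)
        Fgz = trial.total_force[t, 2]
        for _ in range(1000):
            x = x_star + rng.normal(0.0, 30.0, 6)
            x[2] = rng.uniform(0.0, Fgz)
            assert np.sum((A[t] @ x + c0[t]) ** 2) >= best - 1e-6

    def test_qp_matches_brute_force_grid(self, offset_stand_trial):
        """Partial-minimization grid over vertical and AP force splits."""
        trial = offset_stand_trial
        A, c0 = stance_moment_map(trial.states, trial.model,
                                  trial.total_force, trial.total_moment)
        for t in (5, 40, 80):
            At, ct = A[t], c0[t]
            Fg = trial.total_force[t]
            x_star = np.concatenate([trial.reactions.force["r"][t],
                                     trial.reactions.moment["r"][t]])
            qp_cost = np.sum((At @ x_star + ct) ** 2)
            free = [1, 3, 4, 5]
            Af = At[:, free]
            pinv = np.linalg.pinv(Af)
            grid = np.linspace(0.0, 1.0, 61)
            best = np.inf
            for u in grid:
                for s in grid:
                    b = -(ct + At[:, 0] * (u * Fg[0]) + At[:, 2] * (s * Fg[2]))
                    best = min(best, float(np.sum((Af @ (pinv @ b) - b) ** 2)))
            assert qp_cost <= best + 1e-6

    def test_flight_frames_leave_feet_unloaded(self, subject):
        # a contrived timeline with no stance anywhere
        from wbid.grf import ContactTimeline
        from wbid.synthetic import generate_stand
        trial = generate_stand(subject, duration=0.5)
        n = trial.states.n_frames
        timeline = ContactTimeline(
            v_th=1.2, stance={"r": np.zeros(n, bool), "l": np.zeros(n, bool)},
            toe_speed={}, heel_speed={}, heel_accel={})
        r = decompose_grf(trial.total_force, trial.total_moment, timeline,
                          trial.states, trial.model)
        assert np.allclose(r.force["r"], 0.0) and np.allclose(r.force["l"], 0.0)
        assert np.allclose(r.residual_force, trial.total_force)

    def test_moment_objective_rotation_invariant(self, offset_stand_trial,
                                                 rng):
        """The summed squared chain moments are frame-invariant, so the
        minimizer is unaffected by a global rotation of moment axes."""
        trial = offset_stand_trial
        A, c0 = stance_moment_map(trial.states, trial.model,
                                  trial.total_force, trial.total_moment)
        t = 20
        x = rng.normal(size=6)
        m = (A[t] @ x + c0[t]).reshape(6, 3)
        from scipy.spatial.transform import Rotation
        Q = Rotation.random(random_state=7).as_matrix()
        assert np.sum(m ** 2) == pytest.approx(np.sum((m @ Q.T) ** 2))


def test_hand_loads_window_and_split(stand_trial):
    loads = hand_loads(stand_trial.states, 10.0, (100, 200), (0.7, 0.3))
    F_r, F_l = loads[0].force, loads[1].force
    assert np.allclose(F_r[150, 2], -0.7 * 10.0 * G)
    assert np.allclose(F_l[150, 2], -0.3 * 10.0 * G)
    assert np.allclose(F_r[:100], 0.0) and np.allclose(F_r[200:], 0.0)
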