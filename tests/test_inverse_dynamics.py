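"""Newton-Euler recursion: statics closed forms, oracles, conservation."""

import numpy as np
import pytest

from wbid.body_model import SegmentSpec
from wbid.constants import G
from wbid.inverse_dynamics import (peak_ratio, pelvis_residual,
                                   segment_balance, solve_dynamic,
                                   solve_static)
from wbid.kinematics import SegmentKinematics


def _static_kin(com, n=1):
    return SegmentKinematics(
        orientation=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        com=np.tile(np.asarray(com, float), (n, 1)),
        acc=np.zeros((n, 3)), omega=np.zeros((n, 3)), alpha=np.zeros((n, 3)))


class TestSegmentBalance:
    def test_horizontal_bar_pinned_at_one_end(self):
        """Uniform 2 kg, 0.4 m bar: support force m*g, moment m*g*L/2."""
        spec = SegmentSpec(name="bar", mass=2.0, length=0.4,
                           com_offset=np.array([0.2, 0.0, 0.0]),
                           inertia=np.zeros((3, 3)), proximal_joint="pin")
        kin = _static_kin([0.2, 0.0, 0.0])
        F, M = segment_balance(spec, kin, np.zeros((1, 3)))
        assert np.allclose(F[0], [0.0, 0.0, 2.0 * G])
        assert np.linalg.norm(M[0]) == pytest.approx(2.0 * G * 0.2)
        assert np.allclose(M[0], [0.0, -2.0 * G * 0.2, 0.0])

    def test_hand_holding_half_box_weight(self, model):
        spec = model.segments["hand_r"]
        com = np.array([0.0, 0.0, -0.05])
        kin = _static_kin(com)
        ext_F = np.array([[0.0, 0.0, -8.5 * G]])
        F, M = segment_balance(
            spec, kin, np.zeros((1, 3)),
            externals=[(ext_F, np.zeros((1, 3)), kin.com)])
        assert F[0, 2] == pytest.approx((spec.mass + 8.5) * G)

    def test_random_dynamic_instance_matches_independent_oracle(self, rng):
        """Plain textbook evaluation, written without the shared helper."""
        spec = SegmentSpec(name="seg", mass=3.2, length=0.3,
                           com_offset=np.zeros(3),
                           inertia=np.diag([0.02, 0.03, 0.01]),
                           proximal_joint="j")
        n = 8
        from scipy.spatial.transform import Rotation
        R = Rotation.random(n, random_state=4).as_matrix()
        kin = SegmentKinematics(
            orientation=R, com=rng.normal(size=(n, 3)),
            acc=rng.normal(size=(n, 3)), omega=rng.normal(size=(n, 3)),
            alpha=rng.normal(size=(n, 3)))
        p_prox = rng.normal(size=(n, 3))
        Fc = rng.normal(size=(n, 3))
        Mc = rng.normal(size=(n, 3))
        pc = rng.normal(size=(n, 3))
        F, M = segment_balance(spec, kin, p_prox, children=[(Fc, Mc, pc)])

        for t in range(n):
            Ig = R[t] @ spec.inertia @ R[t].T
            w = kin.omega[t]
            mstar = Ig @ kin.alpha[t] + np.cross(w, Ig @ w)
            weight = np.array([0.0, 0.0, -spec.mass * G])
            f_expected = spec.mass * kin.acc[t] - weight + Fc[t]
            # moment balance about the CoM, solved for the proximal moment
            m_expected = (mstar + Mc[t]
                          + np.cross(pc[t] - kin.com[t], Fc[t])
                          - np.cross(p_prox[t] - kin.com[t], f_expected))
            assert np.allclose(F[t], f_expected, atol=1e-10)
            assert np.allclose(M[t], m_expected, atol=1e-10)


class TestSolve:
    def test_symmetric_stance_mirrors_left_right(self, stand_trial, model):
        jls = solve_dynamic(stand_trial.states, model, [],
                            stand_trial.reactions)
        for r_joint, l_joint in (("ankle_r", "ankle_l"), ("knee_r", "knee_l"),
                                 ("hip_r", "hip_l"),
                                 ("shoulder_r", "shoulder_l")):
            assert np.abs(np.linalg.norm(jls.moment[r_joint], axis=1)
                          - np.linalg.norm(jls.moment[l_joint], axis=1)
                          ).max() < 1e-6

    @pytest.mark.parametrize("trial_name", ["gait_trial", "lift_trial"])
    def test_recursion_matches_subtree_oracle(self, trial_name, model,
                                              request):
        trial = request.getfixturevalue(trial_name)
        jls = solve_dynamic(trial.states, model, trial.loads, trial.reactions)
        for joint in jls.joints:
            assert np.abs(jls.moment[joint]
                          - trial.joint_loads.moment[joint]).max() < 1e-6
            assert np.abs(jls.force[joint]
                          - trial.joint_loads.force[joint]).max() < 1e-6

    def test_pelvis_closure_with_exact_reactions(self, gait_trial, model):
        jls = solve_dynamic(gait_trial.states, model, gait_trial.loads,
                            gait_trial.reactions)
        F_res, M_res = pelvis_residual(gait_trial.states, model,
                                       gait_trial.loads, jls)
        assert np.abs(F_res).max() < 1e-6
        assert np.abs(M_res).max() < 1e-6

    def test_whole_body_force_closure(self, lift_trial, model):
        r = lift_trial.reactions
        total_inertial = sum(model.segments[s].mass
                             * lift_trial.states.segments[s].acc
                             for s in model.segments)
        weight = sum(model.segments[s].mass for s in model.segments) * G
        external = sum(l.force for l in lift_trial.loads)
        rhs = r.force["r"] + r.force["l"] + external
        rhs[:, 2] -= weight
        assert np.abs(total_inertial - rhs).max() < 1e-6

    def test_missing_reactions_raise(self, stand_trial, model):
        from wbid.errors import SolverError
        with pytest.raises(SolverError):
            solve_dynamic(stand_trial.states, model, [], None)


class TestStaticFlavor:
    def test_equals_dynamic_on_stationary_trial(self, stand_trial, model):
        dyn = solve_dynamic(stand_trial.states, model, [],
                            stand_trial.reactions)
        stat = solve_static(stand_trial.states, model, [],
                            contacts=stand_trial.contacts)
        for joint in dyn.joints:
            assert np.abs(dyn.moment[joint] - stat.moment[joint]).max() < 1e-9

    def test_differs_from_dynamic_exactly_where_motion_exists(
            self, lift_trial, model):
        dyn = solve_dynamic(lift_trial.states, model, lift_trial.loads,
                            lift_trial.reactions)
        stat = solve_static(lift_trial.states, model, lift_trial.loads,
                            contacts=lift_trial.contacts)
        torso_acc = np.linalg.norm(lift_trial.states.segments["torso"].acc,
                                   axis=1)
        gap = np.linalg.norm(dyn.moment["l5s1"] - stat.moment["l5s1"], axis=1)
        moving = torso_acc > 1e-3
        assert gap[moving].max() > 0.1
        quiet = torso_acc < 1e-12
        assert quiet.any()

    def test_invariant_under_time_reversal(self, lift_trial, model):
        from wbid.grf import ContactTimeline
        from wbid.kinematics import SegmentKinematics, SegmentStateSeries
        st = lift_trial.states
        rev = SegmentStateSeries(
            frame_rate=st.frame_rate,
            segments={k: SegmentKinematics(
                orientation=v.orientation[::-1], com=v.com[::-1],
                acc=v.acc[::-1], omega=v.omega[::-1], alpha=v.alpha[::-1])
                for k, v in st.segments.items()},
            node_positions={k: v[::-1] for k, v in st.node_positions.items()},
            root_position=st.root_position[::-1])
        c = lift_trial.contacts
        rev_contacts = ContactTimeline(
            v_th=c.v_th, stance={f: s[::-1] for f, s in c.stance.items()},
            toe_speed={}, heel_speed={}, heel_accel={})
        from wbid.grf import ExternalLoad
        rev_loads = [ExternalLoad(segment=l.segment, force=l.force[::-1],
                                  moment=l.moment[::-1], point=l.point[::-1],
                                  name=l.name) for l in lift_trial.loads]
        stat = solve_static(st, model, lift_trial.loads,
                            contacts=lift_trial.contacts)
        stat_rev = solve_static(rev, model, rev_loads, contacts=rev_contacts)
        for joint in stat.joints:
            assert np.abs(stat.moment[joint]
                          - stat_rev.moment[joint][::-1]).max() < 1e-9


class TestPeakRatio:
    def test_identical_series_gives_one(self, stand_trial, model):
        stat = solve_static(stand_trial.states, model, [],
                            contacts=stand_trial.contacts)
        assert peak_ratio(stat, stat, "l5s1") == pytest.approx(1.0)

    def test_doubled_series_gives_two(self, stand_trial, model):
        from wbid.inverse_dynamics import JointLoadSeries
        stat = solve_static(stand_trial.states, model, [],
                            contacts=stand_trial.contacts)
        doubled = JointLoadSeries(
            flavor="dynamic", frame_rate=stat.frame_rate,
            force={j: 2 * f for j, f in stat.force.items()},
            moment={j: 2 * m for j, m in stat.moment.items()})
        assert peak_ratio(doubled, stat, "knee_r") == pytest.approx(2.0)

    def test_zero_static_peak_is_an_error(self, stand_trial, model):
        from wbid.inverse_dynamics import JointLoadSeries
        stat = solve_static(stand_trial.states, model, [],
                            contacts=stand_trial.contacts)
        zero = JointLoadSeries(
            flavor="static", frame_rate=stat.frame_rate,
            force={j: 0 * f for j, f in stat.force.items()},
            moment={j: 0 * m for j, m in stat.moment.items()})
        with pytest.raises(ZeroDivisionError):
            peak_ratio(stat, zero, "l5s1")

    def test_lift_ratio_matches_truth_series_arithmetic(self, lift_trial):
        expected = (lift_trial.joint_loads.moment_norm("l5s1").max()
                    / lift_trial.joint_loads_static.moment_norm("l5s1").max())
        got = peak_ratio(lift_trial.joint_loads,
                         lift_trial.joint_loads_static, "l5s1")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 1.0
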