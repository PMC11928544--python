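import numpy as np
import pytest

from conftest import limb_arrays, segment
from gaitwork.energetics import (
    com_energy_rate,
    joint_rotational_power,
    joint_translational_power,
    limb_com_power,
    limb_power,
    peak_metrics,
    peripheral_power,
    socket_power,
    ud_ankle_foot_power,
    whole_body_com,
    work_components,
)
from gaitwork.gait_io import SegmentState
from gaitwork.preprocess import Stride


def point_segment(name, mass, pos, vel, limb="left"):
    n = len(pos)
    return SegmentState(
        name, mass, np.zeros((3, 3)), np.asarray(pos, float),
        np.asarray(vel, float), np.zeros((n, 3)), limb,
    )


class TestWholeBodyCom:
    def test_single_segment_identity(self):
        pos = np.random.default_rng(0).normal(size=(10, 3))
        seg = point_segment("s", 3.0, pos, pos * 0.1)
        p, v = whole_body_com([seg])
        assert np.allclose(p, pos, atol=1e-15)

    def test_symmetric_masses_cancel(self):
        a = point_segment("a", 2.0, np.full((5, 3), 1.0), np.zeros((5, 3)))
        b = point_segment("b", 2.0, np.full((5, 3), -1.0), np.zeros((5, 3)))
        p, _ = whole_body_com([a, b])
        assert np.abs(p).max() == 0.0

    def test_weighted_mean_by_hand(self):
        # 2 kg at x=0, 1 kg at x=3 -> COM at x=1
        a = point_segment("a", 2.0, np.zeros((4, 3)), np.zeros((4, 3)))
        pos_b = np.zeros((4, 3))
        pos_b[:, 0] = 3.0
        b = point_segment("b", 1.0, pos_b, np.zeros((4, 3)))
        p, _ = whole_body_com([a, b])
        assert p[:, 0] == pytest.approx(1.0)

    def test_zero_total_mass_rejected(self):
        seg = point_segment("s", 0.0, np.zeros((4, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            whole_body_com([seg])


class TestLimbComPower:
    def test_hand_dot_product(self):
        f = np.array([[100.0, 800.0, 0.0]])
        v = np.array([[1.2, 0.1, 0.0]])
        assert limb_com_power(f, v).values[0] == pytest.approx(200.0)

    def test_zero_velocity_or_swing_is_zero(self):
        f = np.array([[0.0, 769.0, 0.0], [0.0, 0.0, 0.0]])
        v = np.array([[0.0, 0.0, 0.0], [1.3, 0.2, 0.0]])
        assert np.all(limb_com_power(f, v).values == 0.0)

    def test_mass_normalization(self):
        f = np.array([[0.0, 800.0, 0.0]])
        v = np.array([[0.0, 0.1, 0.0]])
        assert limb_com_power(f, v, body_mass=80.0).values[0] == pytest.approx(1.0)


class TestPeripheralPower:
    def test_segment_moving_with_com_contributes_nothing(self):
        v = np.tile([1.1, 0.2, 0.0], (50, 1))
        seg = point_segment("s", 5.0, np.cumsum(v, 0) / 120, v)
        p = peripheral_power([seg], v, 120.0)
        assert np.abs(p.values).max() < 1e-12

    def test_linear_speed_ramp_analytic_derivative(self):
        # |v_rel|(t) = t for 1 kg: KE = t^2/2, peripheral power = t
        n, rate = 1001, 500.0
        t = np.arange(n) / rate
        vel = np.column_stack([t, np.zeros(n), np.zeros(n)])
        seg = point_segment("s", 1.0, np.column_stack([t**2 / 2, 0 * t, 0 * t]), vel)
        p = peripheral_power([seg], np.zeros((n, 3)), rate)
        assert p.values[-1] == pytest.approx(t[-1], abs=1e-6)
        assert np.abs(p.values[1:-1] - t[1:-1]).max() < 1e-6

    def test_constant_rotation_constant_inertia_is_zero(self):
        n = 50
        seg = SegmentState(
            "s", 2.0, np.diag([0.1, 0.1, 0.1]), np.zeros((n, 3)),
            np.zeros((n, 3)), np.tile([0.0, 0.0, 3.0], (n, 1)), "left",
        )
        p = peripheral_power([seg], np.zeros((n, 3)), 120.0)
        assert np.abs(p.values).max() < 1e-12


class TestJointPowers:
    def test_hand_products(self):
        assert joint_rotational_power(
            np.array([50.0]), np.array([2.0])
        ).values[0] == pytest.approx(100.0)
        assert joint_translational_power(
            np.array([769.0]), np.array([0.05])
        ).values[0] == pytest.approx(38.45)

    def test_isometric_and_cancelling_dofs(self):
        m = np.array([[30.0, -15.0]])
        w = np.array([[1.0, 2.0]])
        assert joint_rotational_power(m, w).values[0] == pytest.approx(0.0)
        assert joint_rotational_power(np.array([50.0]), np.array([0.0])).values[
            0
        ] == pytest.approx(0.0)

    def test_mismatched_dofs_rejected(self):
        with pytest.raises(ValueError, match="DOF"):
            joint_rotational_power(np.zeros((5, 2)), np.zeros((5, 3)))

    def test_resistive_translational_power_is_negative(self):
        # compression at positive velocity against an opposing force
        p = joint_translational_power(np.array([-500.0]), np.array([0.05]))
        assert p.values[0] < 0


class TestSocketPower:
    def test_oi_interface_rejected(self):
        with pytest.raises(ValueError, match="socket DOF absent"):
            socket_power(np.zeros(5), np.zeros(5), interface="OI")

    def test_rigid_socket_zero_velocity_zero_power(self):
        p = socket_power(np.full(10, 700.0), np.zeros(10))
        assert np.all(p.values == 0.0)

    def test_compression_burst_is_negative(self):
        # rising load with proximally increasing displacement absorbs energy
        f = np.array([100.0, 400.0, 700.0])
        v = np.array([0.01, 0.02, 0.01])
        assert np.all(socket_power(f, v).values < 0)


class TestUdAnkleFootPower:
    def test_stationary_rigid_system_zero(self):
        n = 20
        shank = SegmentState(
            "shank", 3.0, np.diag([0, 0, 0.05]),
            np.tile([0.0, 0.4, 0.0], (n, 1)), np.zeros((n, 3)),
            np.zeros((n, 3)), "left",
        )
        grf = np.tile([0.0, 800.0, 0.0], (n, 1))
        cop = np.tile([0.05, 0.0, 0.0], (n, 1))
        p = ud_ankle_foot_power(grf, cop, shank)
        assert np.abs(p.values).max() < 1e-12

    def test_hand_value_translating_shank_point(self):
        n = 3
        shank = SegmentState(
            "shank", 3.0, np.diag([0, 0, 0.05]),
            np.tile([0.0, 0.4, 0.0], (n, 1)),
            np.tile([0.0, -0.01, 0.0], (n, 1)), np.zeros((n, 3)), "left",
        )
        grf = np.tile([0.0, 800.0, 0.0], (n, 1))
        cop = np.tile([0.0, 0.0, 0.0], (n, 1))
        p = ud_ankle_foot_power(grf, cop, shank)
        assert p.values[0] == pytest.approx(-8.0)

    def test_undefined_cop_under_load_rejected(self):
        n = 4
        shank = SegmentState(
            "shank", 3.0, np.diag([0, 0, 0.05]), np.zeros((n, 3)),
            np.zeros((n, 3)), np.zeros((n, 3)), "left",
        )
        grf = np.tile([0.0, 800.0, 0.0], (n, 1))
        cop = np.full((n, 3), np.nan)
        with pytest.raises(ValueError, match="COP undefined"):
            ud_ankle_foot_power(grf, cop, shank, stance_mask=np.ones(n, bool))

    def test_rigid_ankle_matches_summed_ankle_rotational_power(
        self, rigid_ankle_trial
    ):
        trial, truth = rigid_ankle_trial
        for limb in trial.limbs:
            grf, cop = limb_arrays(trial, limb)
            shank = segment(trial, f"{limb}_shank")
            pud = ud_ankle_foot_power(grf, cop, shank, limb=limb)
            pank = joint_rotational_power(
                trial.joints[f"{limb}_ankle_moment"].to_numpy(),
                trial.joints[f"{limb}_ankle_ang_vel"].to_numpy(),
            )
            for i0, i1 in truth.stance_windows[limb]:
                diff = np.trapezoid(
                    pud.values[i0 : i1 + 1] - pank.values[i0 : i1 + 1],
                    trial.time[i0 : i1 + 1],
                )
                assert abs(diff) < 1e-3


class TestWorkComponents:
    def test_sine_wave_analytic_integrals(self):
        t = np.linspace(0, 1, 2001)
        p = np.sin(2 * np.pi * t)
        ws = work_components(p, t)
        assert ws.positive == pytest.approx(1 / np.pi, abs=1e-5)
        assert ws.negative == pytest.approx(-1 / np.pi, abs=1e-5)
        assert ws.net == pytest.approx(0.0, abs=1e-12)

    def test_zero_and_nonnegative_power(self):
        t = np.linspace(0, 1, 100)
        ws = work_components(np.zeros(100), t)
        assert (ws.net, ws.positive, ws.negative) == (0.0, 0.0, 0.0)
        ws = work_components(np.abs(np.sin(8 * t)), t)
        assert ws.negative == 0.0 and ws.net == ws.positive

    def test_decomposition_identity_random_power(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1.3, 163)
        p = rng.normal(size=163)
        ws = work_components(p, t)
        assert ws.positive + ws.negative == pytest.approx(ws.net, abs=1e-12)
        assert ws.positive >= 0 and ws.negative <= 0

    def test_empty_stride_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            work_components(np.array([]), np.array([]))


class TestPeakMetrics:
    def test_vgrf_peak_mass_normalized(self):
        vgrf = np.zeros(200)
        vgrf[40:140] = 800.0
        stride = Stride("l", 0, 180, 120.0)
        pm = peak_metrics(vgrf, np.zeros(200), np.zeros(200), stride, 80.0)
        assert pm.max_vgrf == pytest.approx(10.0)
        assert pm.peak_hip_flexion_moment == pytest.approx(0.0)

    def test_flexor_peak_found_in_late_stance_window(self):
        n = 200
        stride = Stride("l", 0, n - 1, 120.0)
        frac = np.arange(n) / (n - 1)
        moment = np.where(
            (frac > 0.30) & (frac < 0.60),
            80.0 * np.sin(np.pi * (frac - 0.30) / 0.30),
            0.0,
        )
        pm = peak_metrics(np.zeros(n), moment, np.zeros(n), stride, 80.0)
        assert pm.peak_hip_flexion_moment == pytest.approx(1.0, abs=1e-3)

    def test_stride_not_covered_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            peak_metrics(
                np.zeros(50), np.zeros(50), np.zeros(50),
                Stride("l", 0, 100, 120.0), 80.0,
            )


class TestLimbPowerOnSyntheticWalkers:
    def test_point_mass_limb_power_equals_com_power(self, point_mass_trial):
        trial, _ = point_mass_trial
        _, com_vel = whole_body_com(trial.segments)
        grf, _ = limb_arrays(trial, "intact")
        total = limb_power(grf, com_vel, [], trial.rate, "intact")
        external = limb_com_power(grf, com_vel, limb="intact")
        assert np.array_equal(total.values, external.values)

    def test_steady_state_net_limb_work_near_zero(self, point_mass_trial):
        trial, truth = point_mass_trial
        for limb in trial.limbs:
            for w in truth.work[limb]["net"]:
                assert abs(w) < 0.005

    def test_com_power_bookkeeping_sum_equals_energy_rate(self, point_mass_fast):
        trial, _ = point_mass_fast
        pos, vel = whole_body_com(trial.segments)
        psum = sum(
            limb_com_power(
                trial.grf[l][["fx", "fy", "fz"]].to_numpy(), vel
            ).values
            for l in trial.limbs
        )
        dedt = com_energy_rate(vel, pos[:, 1], trial.body_mass, trial.rate)
        resid = np.abs(psum - dedt)[2:-2] / trial.body_mass
        assert resid.max() < 1e-3

    def test_socket_energy_audit(self, socket_trial):
        trial, truth = socket_trial
        f = trial.joints["prosthetic_socket_piston_force"].to_numpy()
        v = trial.joints["prosthetic_socket_piston_vel"].to_numpy()
        p = socket_power(f, v)
        for k, (i0, i1) in enumerate(truth.socket_windows):
            ws = work_components(p.values[i0 : i1 + 1], trial.time[i0 : i1 + 1])
            assert -ws.net == pytest.approx(truth.socket_dissipation[k], abs=1e-6)

    def test_asymmetry_shifts_work_monotonically(self):
        from gaitwork.synthetic_gait import SyntheticConfig, generate_point_mass

        pos_i, neg_i, pos_p, neg_p = [], [], [], []
        for asym in (1.0, 1.1, 1.2):
            _, truth = generate_point_mass(
                SyntheticConfig(n_strides=4, load_share_asym=asym)
            )
            pos_i.append(np.mean(truth.work["intact"]["positive"]))
            neg_i.append(np.mean(truth.work["intact"]["negative"]))
            pos_p.append(np.mean(truth.work["prosthetic"]["positive"]))
            neg_p.append(np.mean(truth.work["prosthetic"]["negative"]))
        assert pos_i[0] < pos_i[1] < pos_i[2]
        assert abs(neg_i[0]) < abs(neg_i[1]) < abs(neg_i[2])
        assert pos_p[0] > pos_p[1] > pos_p[2]
        assert abs(neg_p[0]) > abs(neg_p[1]) > abs(neg_p[2])
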