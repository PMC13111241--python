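"""Rigid-body layer: anthropometrics, kinematics, dynamics against
independent closed-form and Lagrangian oracles."""

import numpy as np
import pytest
import sympy as sp

from gaitphys import biomech
from gaitphys.autodiff import Tensor, numerical_grad


class TestAnthropometrics:
    def test_masses_sum_to_total(self, anthro):
        assert sum(anthro.segment_masses.values()) == pytest.approx(68.0, abs=1e-9)

    def test_thigh_length_fraction(self):
        m = biomech.anthropometrics(1.80, 70.0)
        assert m.segment_lengths["thigh_l"] == pytest.approx(0.245 * 1.80)

    def test_mass_homogeneity(self):
        a = biomech.anthropometrics(1.75, 50.0)
        b = biomech.anthropometrics(1.75, 100.0)
        for seg in biomech.SEGMENTS:
            assert b.segment_masses[seg] == pytest.approx(2 * a.segment_masses[seg])
            assert b.segment_inertias[seg] == pytest.approx(2 * a.segment_inertias[seg])

    @pytest.mark.parametrize("h,m", [(1.2, 70.0), (2.3, 70.0), (1.75, 30.0), (1.75, 150.0)])
    def test_rejects_out_of_range(self, h, m):
        with pytest.raises(ValueError):
            biomech.anthropometrics(h, m)


class TestForwardKinematics:
    def test_zero_posture_knee_below_hip(self, anthro):
        fk = biomech.forward_kinematics(np.zeros((1, 6)), anthro)
        knee = fk["knee_l"].data[0]
        assert knee == pytest.approx([0.0, -anthro.segment_lengths["thigh_l"]], abs=1e-12)

    def test_two_link_hand_trigonometry(self, anthro):
        th = np.zeros((1, 6))
        th[0, 0] = np.deg2rad(30.0)  # hip flexion, knee 0
        fk = biomech.forward_kinematics(th, anthro)
        lt = anthro.segment_lengths["thigh_l"]
        ls = anthro.segment_lengths["shank_l"]
        expected = (lt + ls) * np.array([np.sin(np.deg2rad(30)), -np.cos(np.deg2rad(30))])
        assert fk["ankle_l"].data[0] == pytest.approx(expected, abs=1e-12)

    def test_rigid_segment_lengths_random_angles(self, anthro):
        th = np.random.default_rng(1).normal(0, 0.8, (50, 6))
        fk = biomech.forward_kinematics(th, anthro)
        for side in "lr":
            d = np.linalg.norm(fk[f"knee_{side}"].data - fk["hip"].data, axis=-1)
            assert np.allclose(d, anthro.segment_lengths[f"thigh_{side}"], atol=1e-9)
            d = np.linalg.norm(fk[f"ankle_{side}"].data - fk[f"knee_{side}"].data, axis=-1)
            assert np.allclose(d, anthro.segment_lengths[f"shank_{side}"], atol=1e-9)


class TestFiniteDiff:
    def test_exact_for_linear_and_quadratic(self):
        t = np.arange(20) * 0.01
        lin = (2.0 + 3.0 * t)[:, None]
        d1, d2 = biomech.finite_diff(lin, 0.01)
        assert np.allclose(d1.data, 3.0, atol=1e-10)
        assert np.allclose(d2.data, 0.0, atol=1e-9)
        quad = (t**2)[:, None]
        _, dd = biomech.finite_diff(quad, 0.01)
        assert np.allclose(dd.data, 2.0, atol=1e-8)

    def test_second_order_convergence_on_sine(self):
        errs = []
        for dt in (0.01, 0.005):
            t = np.arange(0, 1, dt)
            d1, _ = biomech.finite_diff(np.sin(2 * np.pi * t)[:, None], dt)
            exact = 2 * np.pi * np.cos(2 * np.pi * t)
            errs.append(np.abs(d1.data[1:-1, 0] - exact[1:-1]).max())
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            biomech.finite_diff(np.zeros((2, 1)), 0.01)


class TestComChain:
    def test_weighted_centroid_formula(self, anthro):
        rng = np.random.default_rng(2)
        coms = rng.normal(0, 1, (6, 7, 2))
        p_c, _, _ = biomech.com_chain(coms, anthro, 0.01)
        m = anthro.mass_array
        expected = (coms * m[:, None]).sum(axis=1) / m.sum()
        assert np.allclose(p_c.data, expected, atol=1e-12)

    def test_recovers_constant_acceleration(self, anthro):
        t = (np.arange(30) * 0.01)[:, None]
        g_vec = np.array([0.3, -9.81])
        base = 0.5 * g_vec * t**2
        coms = np.repeat(base[:, None, :], 7, axis=1)
        _, _, a_c = biomech.com_chain(coms, anthro, 0.01)
        assert np.allclose(a_c.data, g_vec, atol=1e-6)


def _lagrangian_leg_oracle(model):
    """Independent 3-link (thigh-shank-foot) torque oracle via sympy."""
    L, C, M, I = (model.segment_lengths, model.com_offsets,
                  model.segment_masses, model.segment_inertias)
    lt, ls, lf = L["thigh_l"], L["shank_l"], L["foot_l"]
    t = sp.symbols("t")
    q = [sp.Function(f"q{i}")(t) for i in range(3)]
    a1, a2 = q[0], q[0] - q[1]
    a3 = a2 + q[2]
    u = lambda a: sp.Matrix([sp.sin(a), -sp.cos(a)])
    w = lambda a: sp.Matrix([sp.cos(a), sp.sin(a)])
    p_t = C["thigh_l"] * lt * u(a1)
    p_s = lt * u(a1) + C["shank_l"] * ls * u(a2)
    p_f = lt * u(a1) + ls * u(a2) + C["foot_l"] * lf * w(a3)
    p_cop = lt * u(a1) + ls * u(a2) + 0.5 * lf * w(a3)
    kin = sum(
        m * (p.diff(t).T * p.diff(t))[0] / 2
        for m, p in ((M["thigh_l"], p_t), (M["shank_l"], p_s), (M["foot_l"], p_f))
    ) + (
        I["thigh_l"] * sp.diff(a1, t) ** 2
        + I["shank_l"] * sp.diff(a2, t) ** 2
        + I["foot_l"] * sp.diff(a3, t) ** 2
    ) / 2
    pot = biomech.GRAVITY * (
        M["thigh_l"] * p_t[1] + M["shank_l"] * p_s[1] + M["foot_l"] * p_f[1]
    )
    lag = kin - pot
    fx, fy = sp.symbols("Fx Fy")
    force = sp.Matrix([fx, fy])
    syms = sp.symbols("x1 x2 x3 v1 v2 v3 a1a a2a a3a")
    subs = {}
    for i, qi in enumerate(q):
        subs[sp.diff(qi, t, 2)] = syms[6 + i]
        subs[sp.diff(qi, t)] = syms[3 + i]
        subs[qi] = syms[i]
    fns = []
    for qi in q:
        qe = sp.diff(sp.diff(lag, sp.diff(qi, t)), t) - sp.diff(lag, qi)
        qext = (p_cop.jacobian([qi]).T * force)[0]
        fns.append(sp.lambdify(syms + (fx, fy), (qe - qext).subs(subs), "numpy"))
    return fns


class TestInverseDynamics:
    def test_static_foot_offset_moments(self, anthro):
        # upright static posture, no GRF: each joint must support the moment of
        # the foot's weight, whose COM sits half a foot-length anterior
        tau = biomech.inverse_dynamics(
            np.zeros((1, 6)), np.zeros((1, 6)), np.zeros((1, 6)), anthro
        ).data[0]
        arm = 0.5 * anthro.segment_lengths["foot_l"]
        expected = arm * anthro.segment_masses["foot_l"] * biomech.GRAVITY
        for j in range(6):
            assert tau[j] == pytest.approx(expected, rel=1e-12)

    def test_matches_lagrangian_oracle(self, anthro):
        fns = _lagrangian_leg_oracle(anthro)
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(20):
            x = rng.normal(0, 0.6, 3)
            v = rng.normal(0, 1.5, 3)
            a = rng.normal(0, 3.0, 3)
            f = rng.normal(0, 200.0, 2)
            th = np.zeros((1, 6))
            th[0, :3] = x
            thd = np.zeros((1, 6))
            thd[0, :3] = v
            thdd = np.zeros((1, 6))
            thdd[0, :3] = a
            tau = biomech.inverse_dynamics(
                th, thd, thdd, anthro, grf_left=f.reshape(1, 2)
            ).data[0, :3]
            oracle = np.array(
                [fns[0](*x, *v, *a, *f), -fns[1](*x, *v, *a, *f), fns[2](*x, *v, *a, *f)]
            )
            worst = max(worst, np.abs(tau - oracle).max() / (np.abs(oracle).max() + 1e-9))
        assert worst < 1e-5

    def test_analytic_acceleration_matches_fd_of_positions(self, anthro):
        dt = 1e-4
        t = np.arange(200) * dt
        th = np.stack([0.3 * np.sin(2 * np.pi * t + i) for i in range(6)], axis=-1)
        thd = np.stack([0.3 * 2 * np.pi * np.cos(2 * np.pi * t + i) for i in range(6)], axis=-1)
        thdd = np.stack(
            [-0.3 * (2 * np.pi) ** 2 * np.sin(2 * np.pi * t + i) for i in range(6)], axis=-1
        )
        kin = biomech.segment_kinematics(th, thd, thdd, anthro)
        fk = biomech.forward_kinematics(th, anthro)
        num_acc = np.gradient(np.gradient(fk["com_shank_l"].data, dt, axis=0), dt, axis=0)
        assert np.allclose(kin["shank_l"]["acc"].data[5:-5], num_acc[5:-5], atol=1e-3)


class TestEnergy:
    def test_rest_at_height(self, anthro):
        e = biomech.total_energy(
            np.zeros((5, 2)), np.zeros((5, 7)), np.full(5, 1.2), anthro
        )
        assert np.allclose(e.data, 68.0 * biomech.GRAVITY * 1.2)

    def test_pure_translation(self, anthro):
        v = np.zeros((5, 2))
        v[:, 0] = 1.5
        e = biomech.total_energy(v, np.zeros((5, 7)), np.zeros(5), anthro)
        assert np.allclose(e.data, 0.5 * 68.0 * 1.5**2)

    def test_reference_height_shift_is_linear(self, anthro):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, (5, 2))
        om = rng.normal(0, 1, (5, 7))
        h = rng.normal(0, 1, 5)
        e0 = biomech.total_energy(v, om, h, anthro).data
        e1 = biomech.total_energy(v, om, h + 0.5, anthro).data
        assert np.allclose(e1 - e0, 68.0 * biomech.GRAVITY * 0.5)

    def test_rigid_pendulum_energy_conserved(self):
        # The COM + segment-rotation energy decomposition is exact for one
        # rigid body, so a frictionless physical pendulum (simulated by an
        # independent RK4 integrator) must conserve the reported E(t).
        mass, i_com, d = 68.0, 1.2, 0.4
        eps = 1e-12
        segs = biomech.SEGMENTS
        model = biomech.AnthropometricModel(
            height=1.75, total_mass=mass,
            segment_lengths={s: 1.0 for s in segs},
            segment_masses={s: (mass - 6 * eps if s == "pelvis_trunk" else eps) for s in segs},
            segment_inertias={s: (i_com if s == "pelvis_trunk" else eps) for s in segs},
            com_offsets={s: 0.5 for s in segs},
        )
        i_pivot = i_com + mass * d**2
        dt = 1e-3
        y = np.array([0.5, 0.0])  # angle from vertical-down, angular rate

        def f(state):
            return np.array(
                [state[1], -mass * biomech.GRAVITY * d * np.sin(state[0]) / i_pivot]
            )

        th, om = [], []
        for _ in range(1500):
            th.append(y[0])
            om.append(y[1])
            k1, k2 = f(y), f(y + dt / 2 * f(y))
            k3 = f(y + dt / 2 * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        th, om = np.array(th), np.array(om)
        v_c = np.stack([d * om * np.cos(th), d * om * np.sin(th)], axis=-1)
        h_c = -d * np.cos(th)
        omega = np.zeros((len(th), 7))
        omega[:, 0] = om
        e = biomech.total_energy(v_c, omega, h_c, model).data
        swing = mass * biomech.GRAVITY * d * (1 - np.cos(0.5))
        assert np.ptp(e) < 1e-6 * swing


class TestChainGradients:
    def test_autodiff_matches_finite_difference(self, anthro):
        rng = np.random.default_rng(3)

        def scalar(x):
            st = biomech.biomech_state(x, 0.01, anthro)
            return ((st.a_c**2).sum() + (st.energy**2).sum() * 1e-4).item()

        x = rng.normal(0, 0.3, (7, 6))
        t = Tensor(x.copy(), requires_grad=True)
        st = biomech.biomech_state(t, 0.01, anthro)
        ((st.a_c**2).sum() + (st.energy**2).sum() * 1e-4).backward()
        num = numerical_grad(lambda a: scalar(a), x.copy())
        rel = np.abs(t.grad - num) / (np.abs(num) + 1e-6)
        assert rel.max() < 1e-4
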