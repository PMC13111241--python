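"""The four constraint losses: zero on feasible fixtures, printed-formula
agreement with loop oracles, gradient correctness, parameter recovery."""

import math

import numpy as np
import pytest

from gaitphys.autodiff import AdamW, Tensor, numerical_grad
from gaitphys.constraints import (
    ConstraintConfig,
    constraint_bundle,
    dynamic_loss,
    energy_loss,
    kinematic_loss,
    symmetry_loss,
    trapezoid_impulse,
)

CFG = ConstraintConfig()


class TestKinematic:
    def test_zero_on_linear_within_limits(self):
        t = np.linspace(-0.2, 0.3, 50)
        theta = np.tile(t[:, None], (1, 6)) * np.array([1, 0.5, 0.8, 1, 0.5, 0.8])
        theta[:, [1, 4]] += 0.25  # keep the knee inside its one-sided range
        assert kinematic_loss(theta, CFG).item() == pytest.approx(0.0, abs=1e-12)

    def test_single_violation_squared(self):
        cfg = ConstraintConfig(smoothness_kappa=0.0)
        theta = np.zeros((10, 6))
        theta[:, 1] = 0.2  # knee comfortably inside range
        theta[4, 0] = np.deg2rad(35.0) + 0.1  # hip limit exceeded by 0.1 rad
        assert kinematic_loss(theta, cfg).item() == pytest.approx(0.01, rel=1e-9)

    def test_smoothness_matches_loop_oracle(self):
        t = np.linspace(0, 1, 40)
        theta = 0.3 * np.sin(2 * np.pi * t)[:, None] * np.ones((1, 6))
        theta[:, [1, 4]] = 0.3 + 0.2 * np.sin(2 * np.pi * t)[:, None]
        loss = kinematic_loss(theta, CFG).item()
        oracle = 0.0
        for j in range(6):
            for k in range(1, 39):
                oracle += (theta[k + 1, j] - 2 * theta[k, j] + theta[k - 1, j]) ** 2
        assert loss == pytest.approx(CFG.smoothness_kappa * oracle, rel=1e-9)


class TestDynamic:
    def test_ballistic_flight_is_feasible(self):
        t_len = 30
        f_pred = np.zeros((t_len, 2))
        a_c = np.tile([0.0, -9.81], (t_len, 1))
        loss = dynamic_loss(f_pred, None, a_c, 70.0, np.zeros(t_len), 1.0,
                           np.zeros(t_len), CFG)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_constant_force_offset(self):
        t_len = 25
        delta = np.array([3.0, -2.0])
        f_meas = np.random.default_rng(0).normal(0, 50, (t_len, 2))
        f_pred = f_meas + delta
        # make the other two terms exactly consistent
        a_c = (f_pred + np.array([0.0, -9.81 * 70.0])) / 70.0
        loss = dynamic_loss(f_pred, f_meas, a_c, 70.0, np.zeros(t_len), 1.0,
                           np.zeros(t_len), CFG)
        assert loss.item() == pytest.approx(t_len * np.sum(delta**2), rel=1e-9)

    def test_kappa1_linearity(self):
        rng = np.random.default_rng(1)
        f_pred = rng.normal(0, 10, (15, 2))
        a_c = rng.normal(0, 1, (15, 2))
        base = dynamic_loss(f_pred, None, a_c, 70.0, np.zeros(15), 1.0, np.zeros(15),
                            ConstraintConfig(kappa1=0.5, kappa2=0.0)).item()
        doubled = dynamic_loss(f_pred, None, a_c, 70.0, np.zeros(15), 1.0, np.zeros(15),
                               ConstraintConfig(kappa1=1.0, kappa2=0.0)).item()
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dynamic_loss(np.zeros((10, 2)), None, np.zeros((9, 2)), 70.0,
                         np.zeros(10), 1.0, np.zeros(10), CFG)


class TestSymmetry:
    def test_perfect_antiphase_is_zero(self):
        rng = np.random.default_rng(2)
        xl = rng.normal(1.0, 0.3, (101, 4))
        xr = np.roll(xl, -50, axis=0)  # right = left advanced by half a cycle
        assert symmetry_loss(xl, xr, 0, CFG).item() == pytest.approx(0.0, abs=1e-12)

    def test_fatigue_decay_factor(self):
        rng = np.random.default_rng(3)
        xl = rng.normal(1.0, 0.3, (101, 3))
        xr = rng.normal(1.2, 0.3, (101, 3))
        l0 = symmetry_loss(xl, xr, 0, CFG).item()
        l4 = symmetry_loss(xl, xr, 4, CFG).item()
        assert l4 / l0 == pytest.approx(math.exp(-0.6), rel=1e-9)

    def test_zero_base_weights(self):
        cfg = ConstraintConfig(sym_base_weights=np.zeros(3))
        xl = np.random.default_rng(4).normal(1, 0.2, (101, 3))
        assert symmetry_loss(xl, xl * 2, 1, cfg).item() == 0.0

    def test_nonincreasing_in_fatigue_level(self):
        rng = np.random.default_rng(5)
        xl = rng.normal(1.0, 0.2, (101, 2))
        xr = rng.normal(1.1, 0.2, (101, 2))
        losses = [symmetry_loss(xl, xr, y, CFG).item() for y in range(5)]
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_denominator_guard_skips_degenerate_samples(self):
        xl = np.ones((101, 1))
        xr = -np.ones((101, 1))  # xl + shifted xr == 0 everywhere
        assert symmetry_loss(xl, xr, 0, CFG).item() == 0.0


class TestEnergy:
    def test_conservative_cycle_zero(self):
        e = np.concatenate([np.linspace(10, 14, 50), np.linspace(14, 10, 51)])
        f = np.zeros((101, 2))
        assert energy_loss(e, f, 0.01, Tensor(0.0)).item() == pytest.approx(0.0, abs=1e-12)

    def test_constructed_dissipation_fixture(self):
        rng = np.random.default_rng(6)
        c_true = 0.05
        f = np.abs(rng.normal(300, 50, (101, 2)))
        imp = trapezoid_impulse(np.linalg.norm(f, axis=-1), 0.01).item()
        e = np.linspace(100.0, 100.0 - c_true * imp, 101)
        assert energy_loss(e, f, 0.01, Tensor(c_true)).item() == pytest.approx(0.0, abs=1e-9)
        at_zero = energy_loss(e, f, 0.01, Tensor(0.0)).item()
        assert at_zero == pytest.approx((c_true * imp) ** 2, rel=1e-9)

    def test_trapezoid_constant_force(self):
        f = np.full(101, 100.0)
        assert trapezoid_impulse(f, 0.01).item() == pytest.approx(100.0, abs=1e-9)

    def test_short_cycle_raises(self):
        with pytest.raises(ValueError):
            energy_loss(np.array([1.0]), np.zeros((1, 2)), 0.01, Tensor(0.0))


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_losses_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)

        def check(make_loss, x, tol=1e-4):
            t = Tensor(x.copy(), requires_grad=True)
            make_loss(t).backward()
            num = numerical_grad(lambda a: make_loss(Tensor(a)).item(), x.copy())
            denom = np.abs(num) + 1e-6
            assert (np.abs(t.grad - num) / denom).max() < tol

        theta = rng.normal(0, 0.8, (12, 6))
        check(lambda t: kinematic_loss(t, CFG), theta)
        # unit mass keeps the loss O(1) so finite differences stay accurate
        f = rng.normal(0, 5, (10, 2))
        a = rng.normal(0, 1, (10, 2))
        check(
            lambda t: dynamic_loss(t, Tensor(f * 0.9), Tensor(a), 1.0,
                                   np.zeros(10), 1.0, np.zeros(10), CFG),
            f,
        )
        xl = rng.normal(1.0, 0.3, (101, 2))
        xr = rng.normal(1.1, 0.3, (101, 2))
        check(lambda t: symmetry_loss(t, Tensor(xr), 1, CFG), xl)
        e = rng.normal(50, 5, 101)
        fg = np.abs(rng.normal(200, 30, (101, 2)))
        check(lambda t: energy_loss(t, Tensor(fg), 0.01, Tensor(0.05)), e)

    def test_energy_loss_gradient_wrt_c(self):
        rng = np.random.default_rng(9)
        e = rng.normal(50, 5, 101)
        fg = np.abs(rng.normal(200, 30, (101, 2)))
        c = Tensor(0.03, requires_grad=True)
        energy_loss(e, fg, 0.01, c).backward()
        num = numerical_grad(
            lambda a: energy_loss(e, fg, 0.01, Tensor(a)).item(), np.array(0.03)
        )
        assert abs(c.grad - num) / (abs(num) + 1e-9) < 1e-6


def test_dissipation_coefficient_recovery():
    """Training only c against cycles generated with known dissipation."""
    rng = np.random.default_rng(12)
    c_true = 0.05
    cycles = []
    for _ in range(20):
        f = np.abs(rng.normal(400, 80, (101, 2)))
        imp = trapezoid_impulse(np.linalg.norm(f, axis=-1), 0.01).item()
        e0 = rng.uniform(80, 120)
        e = np.linspace(e0, e0 - c_true * imp, 101)
        e += rng.normal(0, 0.02, 101)  # small measurement noise
        cycles.append((e, f))
    c = Tensor(0.02, requires_grad=True)
    opt = AdamW([c], lr=5e-3)
    for step in range(500):
        e, f = cycles[step % len(cycles)]
        opt.zero_grad()
        energy_loss(e, f, 0.01, c).backward()
        opt.step()
    assert abs(c.item() - c_true) / c_true < 0.2


def test_bundle_collects_all_terms_and_diagnostics():
    theta = np.zeros((10, 6))
    theta[:, 1] = 0.2
    theta[3, 0] = 0.8  # above the hip limit
    b = constraint_bundle(theta, CFG)
    vals = b.values()
    assert set(vals) == {"l_kin", "l_dyn", "l_sym", "l_eng"}
    assert vals["l_kin"] > 0 and vals["l_dyn"] == 0
    assert b.diagnostics["kin_max_violation"] > 0
    assert 0 < b.diagnostics["kin_violating_fraction"] < 1
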