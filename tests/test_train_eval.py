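"""Objective assembly, metric definitions against hand oracles, training
behaviour, checkpointing, robustness harness."""

import numpy as np
import pytest

from gaitphys import autodiff, biomech, train_eval as te
from gaitphys.autodiff import Tensor
from gaitphys.constraints import ConstraintConfig
from gaitphys.model import GaitFatigueNet, ModelConfig


def _craft_outputs(b=4, t=101, probs=None, asym=None, logvar=None):
    """Minimal forward-output dict with feasible physics."""
    theta = Tensor(np.zeros((b, t, 6)) + np.array([0.1, 0.3, 0.0, 0.1, 0.3, 0.0]))
    out = {
        "theta": theta,
        "f_g": Tensor(np.zeros((b, t, 3))),
        "v_c": Tensor(np.zeros((b, t, 3))),
        "e_aux": Tensor(np.zeros((b, t))),
        "class_probs": Tensor(np.full((b, 5), 0.2) if probs is None else probs),
        "asym": Tensor(np.zeros((b, 6)) if asym is None else asym),
        "logvar": Tensor(np.zeros((b, 6)) if logvar is None else logvar),
    }
    return out


@pytest.fixture(scope="module")
def anthro_mean():
    return biomech.anthropometrics(1.724, 68.0)


class TestTotalLoss:
    def test_uniform_probs_give_log5(self, anthro_mean):
        model = GaitFatigueNet(ModelConfig.tiny(), seed=0)
        out = _craft_outputs()
        y_f = np.array([0, 1, 2, 3])
        total, bd = te.total_loss(
            out, y_f, np.zeros((4, 6)), np.zeros((4, 101, 2)), 68.0, 1.0,
            np.zeros(4), 0.0, model, ConstraintConfig(), anthro_mean,
        )
        assert bd.l_c == pytest.approx(np.log(5.0), rel=1e-6)

    def test_gaussian_nll_closed_form(self, anthro_mean):
        # exact prediction with unit variance: 0.5 * log(2 pi) per dimension
        model = GaitFatigueNet(ModelConfig.tiny(), seed=0)
        out = _craft_outputs()
        _, bd = te.total_loss(
            out, np.zeros(4, int), np.zeros((4, 6)), np.zeros((4, 101, 2)), 68.0, 1.0,
            np.zeros(4), 0.0, model, ConstraintConfig(), anthro_mean,
        )
        assert bd.l_u == pytest.approx(0.5 * np.log(2 * np.pi), rel=1e-6)
        assert bd.l_r == pytest.approx(0.0, abs=1e-12)

    def test_perfect_onehot_zero_ce(self, anthro_mean):
        model = GaitFatigueNet(ModelConfig.tiny(), seed=0)
        probs = np.full((4, 5), 1e-12)
        probs[np.arange(4), [0, 1, 2, 3]] = 1.0
        out = _craft_outputs(probs=probs)
        _, bd = te.total_loss(
            out, np.array([0, 1, 2, 3]), np.zeros((4, 6)), np.zeros((4, 101, 2)),
            68.0, 1.0, np.zeros(4), 0.0, model, ConstraintConfig(), anthro_mean,
        )
        assert bd.l_c == pytest.approx(0.0, abs=1e-9)

    def test_breakdown_sums_to_total(self, anthro_mean):
        model = GaitFatigueNet(ModelConfig.tiny(), seed=0)
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(5), 4)
        out = _craft_outputs(probs=probs, asym=rng.normal(0, 1, (4, 6)))
        lam = np.array([0.1, 0.15, 0.08, 0.12])
        total, bd = te.total_loss(
            out, np.array([0, 1, 2, 3]), np.zeros((4, 6)),
            np.abs(rng.normal(300, 50, (4, 101, 2))), 68.0, 1.0,
            lam, 1e-5, model, ConstraintConfig(), anthro_mean,
        )
        reassembled = bd.l_c + bd.l_r + bd.l_u + bd.l2 + float(np.dot(lam, bd.l_p))
        assert total.item() == pytest.approx(reassembled, rel=1e-6)


def _confusion_kappa_f1(y_true, y_pred, n_classes):
    """Independent confusion-matrix computation of kappa and macro-F1."""
    cm = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = (cm.sum(axis=1) * cm.sum(axis=0)).sum() / n**2
    kappa = (p_o - p_e) / (1 - p_e)
    f1s = []
    for k in range(n_classes):
        tp = cm[k, k]
        prec = tp / cm[:, k].sum() if cm[:, k].sum() else 0.0
        rec = tp / cm[k, :].sum() if cm[k, :].sum() else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return kappa, np.mean(f1s)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        m = te.evaluate(y, y, np.ones((20, 2)), np.ones((20, 2)))
        assert m["accuracy"] == 1.0 and m["kappa"] == 1.0
        assert m["mae"] == 0.0 and m["r2"] == 1.0

    def test_kappa_matches_textbook_confusion_matrix(self):
        # hand-built 2-class confusion matrix [[40, 10], [20, 30]]
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = np.array([0] * 40 + [1] * 10 + [0] * 20 + [1] * 30)
        m = te.evaluate(y_true, y_pred)
        p_o = 0.70
        p_e = 0.5 * 0.6 + 0.5 * 0.4
        assert m["kappa"] == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_kappa_and_f1_match_oracle_on_random_labels(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        m = te.evaluate(y_true, y_pred)
        kappa, f1 = _confusion_kappa_f1(y_true, y_pred, 5)
        assert m["kappa"] == pytest.approx(kappa, abs=1e-12)
        assert m["macro_f1"] == pytest.approx(f1, abs=1e-12)

    def test_constant_regression_gives_zero_r2(self):
        y = np.arange(10.0)
        m = te.evaluate(np.zeros(10, int), np.zeros(10, int), y, np.full(10, y.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_class_warns(self):
        with pytest.warns(UserWarning):
            te.evaluate(np.array([0, 0, 1]), np.array([0, 2, 1]))


class TestTargets:
    def test_symmetric_angles_give_zero_targets(self):
        th = np.random.default_rng(0).normal(0, 0.3, (3, 101, 3))
        theta = np.concatenate([th, th], axis=-1)
        assert np.allclose(te.asymmetry_targets(theta), 0.0)

    def test_rom_deficit_appears_in_target(self):
        t = np.linspace(0, 2 * np.pi, 101)
        theta = np.zeros((101, 6))
        theta[:, 0] = np.sin(t)
        theta[:, 3] = 0.8 * np.sin(t)  # 20% ROM deficit right hip
        y = te.asymmetry_targets(theta)
        assert y[0] == pytest.approx(abs(1 - 0.8) / 0.9, rel=1e-6)


class TestTraining:
    def test_loss_decreases_over_first_epochs(self, trained):
        totals = [h["total"] for h in trained.history[:5]]
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_constraints_fall_below_initial_values(self, trained):
        first, last = trained.history[0], trained.history[-1]
        for k in ("l_kin", "l_sym", "l_dyn"):
            assert last[k] < first[k]

    def test_reaches_target_accuracy(self, trained):
        assert trained.val_metrics["val_accuracy"] >= 0.8

    def test_split_is_subject_disjoint(self, trained, easy_dataset):
        tr = set(easy_dataset.subject[trained.train_idx])
        va = set(easy_dataset.subject[trained.val_idx])
        assert not tr & va

    def test_checkpoint_roundtrip(self, trained, easy_dataset, tmp_path):
        path = tmp_path / "ck.npz"
        te.save_checkpoint(path, trained, ModelConfig.tiny())
        model, norm, meta = te.load_checkpoint(path)
        xn = norm.apply(easy_dataset.x[:4]).astype(np.float32)
        a = trained.model.forward(xn)["class_probs"].data
        b = model.forward(xn)["class_probs"].data
        assert np.allclose(a, b, atol=1e-6)
        assert meta["model_config"]["temporal_dim"] == 32


class TestRobustness:
    def test_injected_snr_within_half_db(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.7, (50, 101, 8, 9))
        noisy = te.add_noise_at_snr(x, 20.0, np.random.default_rng(1))
        noise = noisy - x
        snr = 10 * np.log10(x.var(axis=(0, 1)) / noise.var(axis=(0, 1)))
        assert np.abs(snr - 20.0).max() < 0.5

    def test_constant_channels_left_untouched(self):
        x = np.zeros((10, 101, 8, 9))
        noisy = te.add_noise_at_snr(x, 10.0, np.random.default_rng(2))
        np.testing.assert_array_equal(noisy, x)

    def test_degradation_table_shape_and_baseline(self, trained, easy_dataset):
        rows = te.robustness_suite(
            trained.model, trained.norm, easy_dataset, trained.val_idx, seed=0
        )
        assert rows[0]["scenario"] == "clean"
        assert rows[0]["delta_acc"] == 0.0
        scen = {r["scenario"] for r in rows}
        assert {"snr_20dB", "snr_10dB", "missing_head",
                "missing_shank_foot_one_side"} <= scen
        for r in rows:
            assert 0.0 <= r["accuracy"] <= 1.0
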