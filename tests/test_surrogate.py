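"""Tests of the MLP surrogate ensemble: loss, error metrics, weighting,
training determinism, and prediction contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from contusim.params import BOUNDS, PARAM_NAMES
from contusim.space import mc_sample, sobol_design
from contusim.standin import METRIC_NAMES
from contusim.surrogate import (
    TrainingConfig,
    build_ensemble,
    ensemble_weights,
    error_report,
    huber_loss,
    sample_size_study,
    train_member,
)
from contusim.surrogate._mlp import MLP


def linear_simulator(frame: pd.DataFrame) -> pd.DataFrame:
    """Easy (linear) input-output map with the four metric columns."""
    lo = np.array([BOUNDS[n][0] for n in PARAM_NAMES])
    hi = np.array([BOUNDS[n][1] for n in PARAM_NAMES])
    X = (frame[list(PARAM_NAMES)].to_numpy() - lo) / (hi - lo)
    w = np.array(
        [
            [0.1, 0.05, 0.3, 0.5, 0.0, 0.0, 0.0],
            [0.05, 0.1, 0.5, 0.3, 0.0, 0.0, 0.0],
            [0.1, 0.1, 0.4, 0.4, 0.0, 0.0, 0.0],
            [0.2, 0.05, 0.25, 0.45, 0.0, 0.0, 0.0],
        ]
    )
    return pd.DataFrame(X @ w.T + 0.1, columns=list(METRIC_NAMES), index=frame.index)


class TestHuberLoss:
    def test_zero_residual(self):
        assert huber_loss([0.0], 0.1) == 0.0

    def test_branch_boundary_continuity(self):
        # both branches give d^2/2 at |e| = d
        assert huber_loss([0.1], 0.1) == pytest.approx(0.005)
        assert huber_loss([0.1 - 1e-12], 0.1) == pytest.approx(0.005, rel=1e-6)

    def test_linear_branch_hand_value(self):
        # 0.5*0.1^2 + 0.1*(0.3-0.1) = 0.025
        assert huber_loss([0.3], 0.1) == pytest.approx(0.025)

    def test_mean_over_residuals(self):
        assert huber_loss([0.0, 0.3], 0.1) == pytest.approx(0.0125)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            huber_loss([0.1], 0.0)


class TestErrorReport:
    def test_identity_predictions(self):
        obs = linear_simulator(sobol_design(20))
        rep = error_report(obs.copy(), obs)
        assert rep.max_error() == 0.0

    def test_constant_shift_on_unit_range_output(self):
        obs = pd.DataFrame({"m": np.linspace(0.0, 1.0, 21)})
        rep = error_report(obs + 0.03, obs)
        assert rep.nmae["m"] == pytest.approx(0.03)
        assert rep.nrmse["m"] == pytest.approx(0.03)
        assert rep.ae95["m"] == pytest.approx(0.03)

    def test_ae95_percentile_convention(self):
        # 20 absolute errors 0.01..0.20 on an output spanning [0, 1]
        obs = pd.DataFrame({"m": np.concatenate([[0.0, 1.0], np.full(18, 0.5)])})
        errors = 0.01 * np.arange(1, 21)
        pred = obs["m"] + errors
        rep = error_report(pred.to_frame(), obs)
        # linear-interpolation percentile of the error sample
        assert rep.ae95["m"] == pytest.approx(np.percentile(errors, 95))
        assert rep.ae95["m"] == pytest.approx(0.1905)

    def test_nmae_never_exceeds_nrmse(self):
        rng = np.random.default_rng(0)
        obs = pd.DataFrame({"m": rng.random(50)})
        pred = obs + rng.normal(0, 0.05, size=(50, 1))
        rep = error_report(pred, obs)
        assert rep.nmae["m"] <= rep.nrmse["m"]

    def test_zero_range_rejected(self):
        obs = pd.DataFrame({"m": np.ones(5)})
        with pytest.raises(ValueError, match="m"):
            error_report(obs.copy(), obs)


class TestTrainMember:
    def test_linear_target_fits_below_one_percent(self):
        design = sobol_design(80)
        y = linear_simulator(design)
        cfg = TrainingConfig(max_epochs=4000, patience=4000)
        member = train_member(design[:72], y[:72], design[72:], y[72:], cfg, seed=7)
        rep = error_report(member.predict(design[72:]), y[72:])
        assert max(rep.nrmse.values()) < 0.01

    def test_seed_determinism(self):
        design = sobol_design(30)
        y = linear_simulator(design)
        cfg = TrainingConfig(max_epochs=150, patience=150)
        reports = []
        for _ in range(2):
            m = train_member(design[:27], y[:27], design[27:], y[27:], cfg, seed=3)
            reports.append(error_report(m.predict(design[27:]), y[27:]))
        assert reports[0] == reports[1]

    def test_empty_validation_rejected(self):
        design = sobol_design(20)
        y = linear_simulator(design)
        with pytest.raises(ValueError):
            train_member(design, y, design[:0], y[:0], TrainingConfig(), seed=0)

    def test_constant_output_rejected(self):
        design = sobol_design(20)
        y = linear_simulator(design)
        y["mpsr"] = 1.0
        with pytest.raises(ValueError, match="mpsr"):
            train_member(design[:18], y[:18], design[18:], y[18:],
                         TrainingConfig(max_epochs=10), seed=0)


class TestEnsembleWeights:
    @staticmethod
    def _members(n_points=40, seeds=(1, 2, 3), epochs=120):
        design = sobol_design(n_points)
        y = linear_simulator(design)
        split = int(0.9 * n_points)
        cfg = TrainingConfig(max_epochs=epochs, patience=epochs)
        members = [
            train_member(design[:split], y[:split], design[split:], y[split:], cfg, s)
            for s in seeds
        ]
        return members, design[split:], y[split:]

    def test_single_member_gets_weight_one(self):
        members, vx, vy = self._members(seeds=(1,))
        assert ensemble_weights(members, vx, vy).tolist() == [1.0]

    def test_identical_members_tie_break_uniform(self):
        members, vx, vy = self._members(seeds=(5,))
        w = ensemble_weights([members[0], members[0]], vx, vy)
        assert w == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_matches_brute_force_simplex_grid(self):
        members, vx, vy = self._members(seeds=(1, 2, 3))
        w = ensemble_weights(members, vx, vy)
        m0 = members[0]
        Yv = (vy.to_numpy() - m0.out_min) / m0.out_range
        P = np.stack([m.predict_normalized(vx) for m in members])

        def mse(weights):
            return float(np.mean((np.tensordot(weights, P, axes=1) - Yv) ** 2))

        # exhaustive 0.01-resolution grid over the 3-simplex
        grid_best = min(
            mse(np.array([i, j, 100 - i - j]) / 100.0)
            for i, j in itertools.product(range(101), repeat=2)
            if i + j <= 100
        )
        assert mse(w) <= grid_best + 1e-10

    def test_ensemble_dominates_every_member(self):
        members, vx, vy = self._members(seeds=(1, 2, 3))
        w = ensemble_weights(members, vx, vy)
        m0 = members[0]
        Yv = (vy.to_numpy() - m0.out_min) / m0.out_range
        P = np.stack([m.predict_normalized(vx) for m in members])
        ens_mse = np.mean((np.tensordot(w, P, axes=1) - Yv) ** 2)
        member_mses = [np.mean((P[i] - Yv) ** 2) for i in range(len(members))]
        assert ens_mse <= min(member_mses) + 1e-10


class TestBuildEnsemble:
    def test_split_arithmetic_and_reproducibility(self, standin_model,
                                                  small_training_config):
        design = sobol_design(80)
        ens, rep = build_ensemble(design, standin_model.predict, small_training_config)
        assert len(ens.members) == 2
        assert len(design) - len(design) // 10 == 72  # 72 train / 8 validation
        ens2, rep2 = build_ensemble(design, standin_model.predict, small_training_config)
        assert rep == rep2

    def test_predictions_non_negative_fuzz(self, standin_model, small_training_config):
        design = sobol_design(40)
        ens, _ = build_ensemble(design, standin_model.predict, small_training_config)
        points = mc_sample(2000, seed=9)
        assert (ens.predict(points).to_numpy() >= 0).all()

    def test_batch_order_invariance(self, standin_model, small_training_config):
        design = sobol_design(40)
        ens, _ = build_ensemble(design, standin_model.predict, small_training_config)
        points = mc_sample(50, seed=11)
        direct = ens.predict(points)
        permuted = ens.predict(points.iloc[::-1]).iloc[::-1]
        assert np.allclose(direct.to_numpy(), permuted.to_numpy())

    def test_extrapolation_warns_not_fails(self, standin_model, small_training_config):
        design = sobol_design(40)
        ens, _ = build_ensemble(design, standin_model.predict, small_training_config)
        points = mc_sample(5, seed=1)
        points.loc[points.index[0], "d_ind"] = 13.5
        with pytest.warns(UserWarning, match="extrapolating"):
            ens.predict(points)

    def test_too_small_design_rejected(self, standin_model):
        with pytest.raises(ValueError):
            build_ensemble(sobol_design(5), standin_model.predict)

    def test_save_load_round_trip(self, standin_model, small_training_config, tmp_path):
        design = sobol_design(40)
        ens, _ = build_ensemble(design, standin_model.predict, small_training_config)
        ens.save(tmp_path / "ens")
        from contusim.surrogate import SurrogateEnsemble

        loaded = SurrogateEnsemble.load(tmp_path / "ens")
        points = mc_sample(20, seed=5)
        assert np.allclose(
            ens.predict(points).to_numpy(), loaded.predict(points).to_numpy()
        )


class TestSampleSizeStudy:
    def test_structure_and_selection_set(self, standin_model):
        cfg = TrainingConfig(n_members=1, max_epochs=120, patience=120)
        table, selected = sample_size_study(
            standin_model.predict, cfg, sizes=(10, 20), folds=5
        )
        assert set(table["size"]) == {10, 20}
        assert set(table["fold"]) == set(range(5))
        assert set(table["role"]) == {"train", "heldout"}
        # 2 sizes x 5 folds x 2 roles x 4 outputs
        assert len(table) == 80
        assert selected in (10, 20, None)
        assert table["size"].value_counts()[20] == 40

    def test_size_smaller_than_folds_rejected(self, standin_model):
        with pytest.raises(ValueError):
            sample_size_study(standin_model.predict, sizes=(3,), folds=5)


class TestMLPInternals:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        mlp = MLP((3, 8, 2), seed=1)
        X = rng.random((6, 3))
        Y = rng.random((6, 2))
        _, gW, _ = mlp._gradients(X, Y, d=0.1, l2=1e-4)
        eps = 1e-6
        for (i, j) in [(0, 0), (1, 3)]:
            w0 = mlp.W[0][i, j]
            mlp.W[0][i, j] = w0 + eps
            up = mlp._loss(X, Y, 0.1, 1e-4)
            mlp.W[0][i, j] = w0 - eps
            dn = mlp._loss(X, Y, 0.1, 1e-4)
            mlp.W[0][i, j] = w0
            assert gW[0][i, j] == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-8)
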