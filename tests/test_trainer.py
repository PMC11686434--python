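"""Training machinery: splits, masking, early stopping, optimization."""

import dataclasses

import numpy as np
import pytest

from phenocae import model, trainer
from phenocae.model import LatentLayout, NetworkSpec
from phenocae.trainer import (
    TrainConfig,
    TrainConfigError,
    early_stop_epoch,
    mask_input,
    split_groups,
    sweep,
    train_cae,
    train_vanilla,
)


@pytest.fixture(scope="module")
def toy_problem():
    """Small smooth-spectra groups a tiny CAE can fit quickly."""
    rng = np.random.default_rng(0)
    W, G = 24, 12
    grid = np.linspace(0, 1, W)
    bases = np.stack([np.exp(-((grid - c) ** 2) / 0.02) for c in (0.25, 0.5, 0.75)])
    x = []
    for g in range(G):
        a = rng.normal(size=3)
        group = []
        for p in range(4):
            bump = rng.normal(scale=0.3, size=3)
            group.append(1 / (1 + np.exp(-((a + bump) @ bases))))
        x.append(group)
    return np.asarray(x)


class TestSplit:
    def test_floor_convention_on_study_size(self):
        train, val = split_groups(list(range(578)), 0.85, seed=0)
        assert len(train) == 491 and len(val) == 87

    def test_two_groups_half(self):
        train, val = split_groups([0, 1], 0.5, seed=3)
        assert len(train) == 1 and len(val) == 1
        assert set(train) | set(val) == {0, 1}

    def test_deterministic_and_disjoint(self):
        a = split_groups(list(range(40)), 0.85, seed=9)
        b = split_groups(list(range(40)), 0.85, seed=9)
        assert a == b
        assert not set(a[0]) & set(a[1])
        assert sorted(a[0] + a[1]) == list(range(40))

    def test_empty_side_rejected(self):
        with pytest.raises(TrainConfigError):
            split_groups([0, 1, 2], 0.1, seed=0)


class TestMasking:
    def test_zero_fraction_is_identity(self):
        x = np.random.default_rng(0).random((4, 10))
        masked, mask = mask_input(x, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(masked, x)
        assert not mask.any()

    def test_masked_share_within_binomial_bounds(self):
        x = np.ones((4, 2151))
        _, mask = mask_input(x, 0.2, np.random.default_rng(2))
        n = x.size
        sigma = np.sqrt(0.2 * 0.8 / n)
        assert abs(mask.mean() - 0.2) < 3 * sigma

    def test_masked_entries_are_zero_rest_untouched(self):
        x = np.random.default_rng(3).uniform(0.5, 1.0, (6, 50))
        masked, mask = mask_input(x, 0.4, np.random.default_rng(4))
        assert np.all(masked[mask] == 0.0)
        np.testing.assert_array_equal(masked[~mask], x[~mask])

    def test_fresh_mask_each_call(self):
        x = np.ones((10, 100))
        rng = np.random.default_rng(5)
        _, m1 = mask_input(x, 0.3, rng)
        _, m2 = mask_input(x, 0.3, rng)
        assert (m1 != m2).any()

    def test_invalid_fraction(self):
        with pytest.raises(TrainConfigError):
            mask_input(np.ones((2, 2)), 1.0, np.random.default_rng(0))


class TestEarlyStopping:
    def test_flat_trace_stops_at_best_plus_patience(self):
        trace = [1.0] + [1.0] * 30
        assert early_stop_epoch(trace, patience=15) == 15  # best at 0

    def test_improving_trace_never_stops(self):
        trace = list(np.linspace(1.0, 0.1, 50))
        assert early_stop_epoch(trace, patience=15) is None

    def test_late_improvement_resets_patience(self):
        trace = [1.0] * 10 + [0.5] + [0.6] * 30
        assert early_stop_epoch(trace, patience=15) == 10 + 15

    @pytest.mark.parametrize("patience", [1, 5, 15])
    def test_contract_on_random_traces(self, patience):
        rng = np.random.default_rng(42)
        for _ in range(20):
            trace = rng.random(60).tolist()
            stop = early_stop_epoch(trace, patience)
            if stop is None:
                continue
            best = np.inf
            best_i = 0
            for i in range(stop):
                if trace[i] < best:
                    best, best_i = trace[i], i
            assert stop - best_i == patience
            # no earlier epoch satisfied the condition
            running_best_i = 0
            running_best = np.inf
            for i in range(stop):
                if trace[i] < running_best:
                    running_best, running_best_i = trace[i], i
                assert i - running_best_i < patience


class TestTrainingLoops:
    def test_cae_training_reduces_mse(self, toy_problem):
        layout = LatentLayout(3, 2, 2)
        spec = NetworkSpec(input_dim=24, hidden_dims=(16,))
        cfg = TrainConfig(seed=0, max_epochs=8, weight=1e-4, lbfgs_max_inner=40,
                          mask_fraction=0.2, patience=15)
        res = train_cae(toy_problem, spec, layout, cfg)
        h = res.history_dataframe()
        assert h.train_mse.iloc[-1] < h.train_mse.iloc[0]
        assert res.best_val_loss == pytest.approx(h.val_mse.min())
        assert res.stopped_epoch <= cfg.max_epochs - 1

    def test_same_seed_reproducible(self, toy_problem):
        layout = LatentLayout(3, 2, 2)
        spec = NetworkSpec(input_dim=24, hidden_dims=(16,))
        cfg = TrainConfig(seed=7, max_epochs=4, weight=1e-4, lbfgs_max_inner=20)
        r1 = train_cae(toy_problem, spec, layout, cfg)
        r2 = train_cae(toy_problem, spec, layout, cfg)
        np.testing.assert_allclose(r1.checkpoint.theta, r2.checkpoint.theta, rtol=1e-12)
        h1, h2 = r1.history_dataframe(), r2.history_dataframe()
        np.testing.assert_allclose(h1.val_total, h2.val_total, rtol=1e-10)

    def test_checkpoint_restore_reproduces_val_loss(self, toy_problem, tmp_path):
        layout = LatentLayout(3, 2, 2)
        spec = NetworkSpec(input_dim=24, hidden_dims=(16,))
        cfg = TrainConfig(seed=1, max_epochs=5, weight=1e-4, lbfgs_max_inner=20,
                          restore_best=True)
        res = train_cae(toy_problem, spec, layout, cfg)
        res.checkpoint.save(tmp_path / "ck")
        loaded = model.Checkpoint.load(tmp_path / "ck")
        _, val_idx = split_groups(list(range(len(toy_problem))), cfg.split_fraction, cfg.seed)
        lb = trainer.validation_loss(loaded, toy_problem[val_idx])
        assert lb.reconstruction == pytest.approx(res.best_val_loss, rel=1e-6)

    def test_vanilla_rejects_positive_weight(self, toy_problem):
        spec = NetworkSpec(input_dim=24, hidden_dims=(16,))
        with pytest.raises(TrainConfigError, match="reconstruction-only"):
            train_vanilla(toy_problem.reshape(-1, 24), spec, 7, TrainConfig(weight=0.5))

    def test_degenerate_groups_match_vanilla_epoch_by_epoch(self, toy_problem):
        """E=N=1 groups with identity fusion and no penalty reduce the CAE
        to the vanilla autoencoder exactly."""
        x = toy_problem.reshape(-1, 24)
        layout = LatentLayout(3, 2, 2, E=1, N=1)
        spec = NetworkSpec(input_dim=24, hidden_dims=(16,))
        cfg = TrainConfig(seed=3, max_epochs=4, weight=0.0, mask_fraction=0.0,
                          lbfgs_max_inner=15, identity_fusion=True)
        r_cae = train_cae(x[:, None, :], spec, layout, cfg)
        r_van = train_vanilla(x, spec, layout.d, cfg)
        hc, hv = r_cae.history_dataframe(), r_van.history_dataframe()
        # identical math; rtol absorbs the optimizer's accumulation-order drift
        # over the padded parameter vector
        np.testing.assert_allclose(hc.train_mse, hv.train_mse, rtol=1e-7)
        np.testing.assert_allclose(hc.val_mse, hv.val_mse, rtol=1e-7)

    def test_identity_fusion_requires_degenerate_layout(self, toy_problem):
        layout = LatentLayout(3, 2, 2, E=2, N=2)
        spec = NetworkSpec(input_dim=24, hidden_dims=(16,))
        cfg = TrainConfig(identity_fusion=True)
        with pytest.raises(TrainConfigError):
            train_cae(toy_problem, spec, layout, cfg)


class TestGradients:
    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_cae_objective_gradient_matches_finite_differences(self, weight):
        rng = np.random.default_rng(0)
        layout = LatentLayout(2, 1, 1, E=2, N=2)
        spec = NetworkSpec(input_dim=10, hidden_dims=(6,))
        shapes = model.param_shapes(spec, layout)
        theta = model.init_params(shapes, 0)
        x = rng.uniform(0.2, 0.8, (5, 4, 10))
        loss, grad = trainer._cae_loss_and_grad(theta, x, x, spec, layout, weight)
        eps = 1e-6
        for i in rng.choice(theta.size, 25, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            lp, _ = trainer._cae_loss_and_grad(tp, x, x, spec, layout, weight)
            lm, _ = trainer._cae_loss_and_grad(tm, x, x, spec, layout, weight)
            num = (lp - lm) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_vanilla_objective_gradient(self):
        rng = np.random.default_rng(1)
        spec = NetworkSpec(input_dim=8, hidden_dims=(5,))
        shapes = model.param_shapes(spec, None, d=3)
        theta = model.init_params(shapes, 1)
        x = rng.uniform(0.2, 0.8, (7, 8))
        loss, grad = trainer._vanilla_loss_and_grad(theta, x, x, spec, 3)
        eps = 1e-6
        for i in rng.choice(theta.size, 20, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            lp, _ = trainer._vanilla_loss_and_grad(tp, x, x, spec, 3)
            lm, _ = trainer._vanilla_loss_and_grad(tm, x, x, spec, 3)
            assert grad[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-10)


class TestSweep:
    def test_mask_sweep_shape(self, toy_problem):
        layout = LatentLayout(3, 2, 2)
        spec = NetworkSpec(input_dim=24, hidden_dims=(12,))
        cfg = TrainConfig(seed=0, max_epochs=2, weight=1e-4, lbfgs_max_inner=5)
        table = sweep("mask_fraction", [0.0, 0.2, 0.5, 0.7], toy_problem, spec, layout, cfg)
        assert len(table) == 4
        assert set(table.columns) >= {"axis", "value", "val_loss"}

    def test_layout_sweep_and_downstream_callback(self, toy_problem):
        layout = LatentLayout(3, 2, 2)
        spec = NetworkSpec(input_dim=24, hidden_dims=(12,))
        cfg = TrainConfig(seed=0, max_epochs=2, weight=1e-4, lbfgs_max_inner=5)
        table = sweep(
            "latent_layout", [(3, 2, 2), (6, 2, 2)], toy_problem, spec, layout, cfg,
            downstream_eval=lambda ck: float(ck.layout.d),
        )
        assert table.downstream_r2.tolist() == [7.0, 10.0]

    def test_empty_values_rejected(self, toy_problem):
        with pytest.raises(TrainConfigError):
            sweep("mask_fraction", [], toy_problem, None, None, TrainConfig())


def test_config_validation():
    with pytest.raises(TrainConfigError):
        TrainConfig(split_fraction=1.0)
    with pytest.raises(TrainConfigError):
        TrainConfig(patience=0)
    with pytest.raises(TrainConfigError):
        TrainConfig(mask_fraction=1.0)
    with pytest.raises(TrainConfigError):
        TrainConfig(optimizer="lamb")
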