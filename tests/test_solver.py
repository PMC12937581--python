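"""Coupled HALS solver: initialization, updates, full fits."""

import numpy as np
import pytest

from conftest import random_model, random_pair
from reference_hals import single_tensor_cp_fit, single_tensor_hals_update
from ctca import (
    Alphas,
    FactorModel,
    FitConfig,
    ParameterError,
    SimSpec,
    coupled_objective,
    coupled_pair,
    factor_match_score,
    fit_ctca,
    impute_working_copy,
    initialize,
    reconstruct,
    update_private_mode,
    update_shared_mode,
    validate_coupled_pair,
)
from test_tensors import corrupt_masked_entries, make_tensor, pair_from_model


class TestFitConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rank": 0},
            {"rank": 2, "tol": 0.0},
            {"rank": 2, "max_iter": 0},
            {"rank": 2, "epsilon": 0.0},
            {"rank": 2, "init": "zeros"},
            {"rank": 2, "n_restarts": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            FitConfig(**kwargs)


class TestInitialize:
    def test_seeded_determinism(self, small_pair):
        cfg = FitConfig(rank=3, seed=11)
        m1 = initialize(small_pair, cfg)
        m2 = initialize(small_pair, cfg)
        for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
            assert np.array_equal(getattr(m1, name), getattr(m2, name))

    @pytest.mark.parametrize("init", ["random", "svd"])
    def test_entries_at_least_epsilon(self, small_pair, init):
        cfg = FitConfig(rank=3, seed=0, init=init, epsilon=1e-10)
        model = initialize(small_pair, cfg)
        for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
            assert np.all(getattr(model, name) >= 1e-10)

    def test_rank_may_exceed_all_mode_lengths(self, small_pair):
        model = initialize(small_pair, FitConfig(rank=50, seed=0))
        assert model.contexts.shape[1] == 50

    def test_svd_recovers_rank_one_directions(self):
        rng = np.random.default_rng(3)
        vecs = {
            "contexts": np.abs(rng.standard_normal((5, 1))),
            "lr_a": np.abs(rng.standard_normal((6, 1))),
            "lr_b": np.abs(rng.standard_normal((4, 1))),
            "senders": np.abs(rng.standard_normal((3, 1))),
            "receivers": np.abs(rng.standard_normal((3, 1))),
        }
        truth = FactorModel(rank=1, **vecs)
        pair = pair_from_model(truth)
        model = initialize(pair, FitConfig(rank=1, init="svd"))
        for name, vec in vecs.items():
            got = getattr(model, name)[:, 0]
            cosine = got @ vec[:, 0] / (np.linalg.norm(got) * np.linalg.norm(vec))
            assert cosine >= 0.99


class TestImputation:
    def test_full_mask_returns_original(self, rng, small_pair):
        model = random_model(rng)
        wa, wb = impute_working_copy(small_pair, model)
        assert np.array_equal(wa, small_pair.tensor_a.values)
        assert np.array_equal(wb, small_pair.tensor_b.values)

    def test_all_masked_returns_reconstruction(self, rng):
        model = random_model(rng, shapes=(2, 2, 2, 2, 2), rank=2)
        zero_mask = np.zeros((2, 2, 2, 2))
        pair = validate_coupled_pair(
            make_tensor(np.ones((2, 2, 2, 2)), mask=zero_mask, prefix="lrA"),
            make_tensor(np.ones((2, 2, 2, 2)), mask=zero_mask, prefix="lrB"),
        )
        wa, wb = impute_working_copy(pair, model)
        assert np.allclose(wa, reconstruct(model, "a"))
        assert np.allclose(wb, reconstruct(model, "b"))

    def test_mixed_mask_elementwise_oracle(self, rng):
        model = random_model(rng, shapes=(2, 2, 2, 2, 2), rank=2)
        pair = random_pair(rng, shapes=(2, 2, 2, 2, 2), mask_fraction=0.4)
        wa, _ = impute_working_copy(pair, model)
        m, x = pair.tensor_a.mask, pair.tensor_a.values
        expected = m * x + (1 - m) * reconstruct(model, "a")
        assert np.abs(wa - expected).max() <= 1e-12


class TestSharedUpdate:
    @pytest.mark.parametrize("mode,axis", [("context", 0), ("sender", 2), ("receiver", 3)])
    def test_alpha_one_zero_matches_single_tensor_hals(self, rng, small_pair, mode, axis):
        model = random_model(rng)
        updated = update_shared_mode(
            model, small_pair.tensor_a.values, small_pair.tensor_b.values,
            mode, Alphas(1.0, 0.0),
        )
        expected = single_tensor_hals_update(
            small_pair.tensor_a.values, model.factors("a"), axis
        )
        attr = {"context": "contexts", "sender": "senders", "receiver": "receivers"}[mode]
        assert np.abs(getattr(updated, attr) - expected).max() <= 1e-12

    def test_fixed_point_at_planted_solution(self, rng):
        truth = random_model(rng, shapes=(3, 4, 5, 3, 3), rank=2)
        pair = pair_from_model(truth)
        updated = update_shared_mode(
            truth, pair.tensor_a.values, pair.tensor_b.values, "context"
        )
        assert np.abs(updated.contexts - truth.contexts).max() < 1e-10

    def test_entries_floored_at_epsilon(self, rng, small_pair):
        model = random_model(rng)
        updated = update_shared_mode(
            model, small_pair.tensor_a.values, small_pair.tensor_b.values,
            "sender", epsilon=1e-12,
        )
        assert np.all(updated.senders >= 1e-12)

    def test_objective_does_not_increase(self, rng, small_pair):
        model = random_model(rng)
        before = coupled_objective(model, small_pair)
        for mode in ("context", "sender", "receiver"):
            model = update_shared_mode(
                model, small_pair.tensor_a.values, small_pair.tensor_b.values, mode
            )
            after = coupled_objective(model, small_pair)
            assert after <= before + 1e-9
            before = after


class TestPrivateUpdate:
    def test_other_modality_untouched(self, rng, small_pair):
        model = random_model(rng)
        updated = update_private_mode(model, small_pair.tensor_a.values, "a")
        assert updated.lr_b is not model.lr_b
        assert np.array_equal(updated.lr_b, model.lr_b)
        assert not np.array_equal(updated.lr_a, model.lr_a)

    def test_matches_single_tensor_oracle(self, rng, small_pair):
        model = random_model(rng)
        updated = update_private_mode(model, small_pair.tensor_b.values, "b")
        expected = single_tensor_hals_update(
            small_pair.tensor_b.values, model.factors("b"), 1
        )
        assert np.abs(updated.lr_b - expected).max() <= 1e-12

    def test_fixed_point_at_planted_solution(self, rng):
        truth = random_model(rng, shapes=(3, 4, 5, 3, 3), rank=2)
        pair = pair_from_model(truth)
        updated = update_private_mode(truth, pair.tensor_a.values, "a")
        assert np.abs(updated.lr_a - truth.lr_a).max() < 1e-10


class TestFit:
    def test_planted_recovery_noiseless(self):
        spec = SimSpec(
            shapes=(5, 8, 6, 4, 4), rank=2, seed=5, sparsity=0.0,
            noise_level=0.0, missing_fraction=0.0,
        )
        pair, truth = coupled_pair(spec)
        result = fit_ctca(pair, FitConfig(rank=2, n_restarts=5, seed=1, tol=1e-12))
        assert result.relative_errors[0] <= 1e-5
        assert result.relative_errors[1] <= 1e-5
        assert factor_match_score(result.model, truth) >= 0.99

    def test_rank_one_all_ones_pair(self):
        pair = validate_coupled_pair(
            make_tensor(np.ones((2, 3, 2, 2)), prefix="lrA"),
            make_tensor(np.ones((2, 4, 2, 2)), prefix="lrB"),
        )
        result = fit_ctca(pair, FitConfig(rank=1, seed=0, tol=1e-14, max_iter=200))
        assert np.abs(reconstruct(result.model, "a") - 1.0).max() <= 1e-8
        assert np.abs(reconstruct(result.model, "b") - 1.0).max() <= 1e-8

    def test_decoupled_fit_matches_single_tensor_cp(self, small_pair):
        n_sweeps = 30
        config = FitConfig(
            rank=2, alphas=Alphas(1.0, 0.0), seed=9, tol=1e-300, max_iter=n_sweeps
        )
        result = fit_ctca(small_pair, config)
        assert result.n_iter == n_sweeps
        init = initialize(small_pair, config)
        factors = single_tensor_cp_fit(
            small_pair.tensor_a.values,
            small_pair.tensor_a.mask,
            [init.contexts, init.lr_a, init.senders, init.receivers],
            n_sweeps,
        )
        for got, want in zip(
            [result.model.contexts, result.model.lr_a,
             result.model.senders, result.model.receivers],
            factors,
        ):
            assert np.abs(got - want).max() <= 1e-10

    def test_trajectory_non_increasing_full_mask(self, small_pair):
        result = fit_ctca(small_pair, FitConfig(rank=3, seed=2, max_iter=100))
        diffs = np.diff(result.objective_trajectory)
        assert np.all(diffs <= 1e-9)

    def test_masked_objective_non_increasing(self, rng):
        pair = random_pair(rng, shapes=(4, 5, 4, 3, 3), mask_fraction=0.3)
        result = fit_ctca(pair, FitConfig(rank=2, seed=3, max_iter=100))
        diffs = np.diff(result.objective_trajectory)
        assert np.all(diffs <= 1e-9)

    def test_mask_invariance_bit_identical(self, rng):
        pair = random_pair(rng, shapes=(3, 4, 5, 3, 3), mask_fraction=0.3)
        corrupted = corrupt_masked_entries(pair, rng)
        cfg = FitConfig(rank=2, seed=4, max_iter=50)
        r1 = fit_ctca(pair, cfg)
        r2 = fit_ctca(corrupted, cfg)
        for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
            assert np.array_equal(getattr(r1.model, name), getattr(r2.model, name))

    def test_reproducibility(self, small_pair):
        cfg = FitConfig(rank=2, seed=8, max_iter=60, n_restarts=2)
        r1 = fit_ctca(small_pair, cfg)
        r2 = fit_ctca(small_pair, cfg)
        assert r1.seed_used == r2.seed_used
        assert r1.objective_trajectory == r2.objective_trajectory
        for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
            assert np.array_equal(getattr(r1.model, name), getattr(r2.model, name))

    def test_restarts_pick_lowest_objective(self, small_pair):
        singles = [
            fit_ctca(small_pair, FitConfig(rank=2, seed=10 + s, max_iter=40))
            for s in range(3)
        ]
        multi = fit_ctca(small_pair, FitConfig(rank=2, seed=10, max_iter=40, n_restarts=3))
        best = min(singles, key=lambda r: r.objective_trajectory[-1])
        assert multi.seed_used == best.seed_used
        assert multi.objective_trajectory[-1] == best.objective_trajectory[-1]

    def test_swap_symmetry_on_planted_data(self, noiseless_pair):
        pair, truth = noiseless_pair
        swapped = validate_coupled_pair(pair.tensor_b, pair.tensor_a)
        cfg = FitConfig(rank=2, n_restarts=5, seed=2, tol=1e-12)
        forward = fit_ctca(pair, cfg)
        backward = fit_ctca(swapped, cfg)
        unswapped = FactorModel(
            rank=backward.model.rank,
            contexts=backward.model.contexts,
            lr_a=backward.model.lr_b,
            lr_b=backward.model.lr_a,
            senders=backward.model.senders,
            receivers=backward.model.receivers,
        )
        assert factor_match_score(forward.model, unswapped) >= 0.999

    def test_all_loadings_non_negative(self, small_pair):
        result = fit_ctca(small_pair, FitConfig(rank=3, seed=1, max_iter=50))
        for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
            assert np.all(getattr(result.model, name) >= 0)

    def test_returned_model_unnormalized_weights(self, small_pair):
        result = fit_ctca(small_pair, FitConfig(rank=2, seed=0, max_iter=20))
        assert np.array_equal(result.model.weights_a, np.ones(2))
        assert np.array_equal(result.model.weights_b, np.ones(2))
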