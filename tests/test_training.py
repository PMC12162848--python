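"""Loss, analytic gradients, optimization and architecture sweeps."""

import numpy as np
import pytest

from dpsf import (
    BitDepthPolicy,
    DiffractiveProcessor,
    Dispersion,
    ProcessorGeometry,
    TrainConfig,
    TransformMatrix,
    bit_depth_eval,
    evaluate_loss,
    impulse_matrix,
    loss_and_gradient,
    optimal_scale,
    random_uniform_target,
    snap_to_quantized,
    sweep,
    train,
    transformation_error,
)


class TestTransformationError:
    def test_double_loop_oracle(self):
        """Loss and sigma_A recomputed with explicit loops (Frobenius sums)."""
        rng = np.random.default_rng(20)
        a = rng.uniform(size=(5, 7))
        ap = rng.uniform(size=(5, 7))
        num = den_ap = den_a = 0.0
        for p in range(5):
            for q in range(7):
                num += a[p, q] * ap[p, q]
                den_ap += ap[p, q] ** 2
                den_a += a[p, q] ** 2
        sigma = num / den_ap
        expect = sum(
            (a[p, q] - sigma * ap[p, q]) ** 2 for p in range(5) for q in range(7)
        ) / den_a
        assert transformation_error(a, ap) == pytest.approx(expect, abs=1e-12)
        assert optimal_scale(a, ap) == pytest.approx(sigma, abs=1e-12)

    def test_perfect_realization_up_to_scale_is_zero(self):
        rng = np.random.default_rng(21)
        a = rng.uniform(size=(6, 6))
        assert transformation_error(a, 0.01 * a) < 1e-12
        assert transformation_error(a, 100.0 * a) < 1e-12

    def test_orthogonal_realization_is_one(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        ap = np.array([[0.0, 0.0], [0.0, 3.0]])
        assert transformation_error(a, ap) == pytest.approx(1.0)
        # all-zero realization also scores 1 (sigma_A = 0)
        assert transformation_error(a, np.zeros((2, 2))) == pytest.approx(1.0)

    def test_scale_invariance_in_realized(self):
        rng = np.random.default_rng(22)
        a, ap = rng.uniform(size=(4, 4)), rng.uniform(size=(4, 4))
        assert transformation_error(a, ap) == pytest.approx(
            transformation_error(a, 7.3 * ap), abs=1e-12
        )

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            transformation_error(np.zeros((2, 2)), np.ones((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transformation_error(np.ones((2, 2)), np.ones((3, 2)))


class TestLossAndGradient:
    def test_matches_evaluate_loss(self, tiny_processor):
        target = random_uniform_target(4, 4, seed=1)
        loss, grads, per_lam = loss_and_gradient(tiny_processor, target)
        assert loss == pytest.approx(evaluate_loss(tiny_processor, target), abs=1e-12)
        assert len(grads) == 2 and len(per_lam) == 1
        assert per_lam[0] == pytest.approx(loss, abs=1e-12)

    def test_gradient_against_finite_differences(self, tiny_processor):
        """Central finite differences on individual latents agree with the
        analytic adjoint gradient to much better than 1e-4 relative."""
        target = random_uniform_target(4, 4, seed=2)
        _, grads, _ = loss_and_gradient(tiny_processor, target)
        rng = np.random.default_rng(0)
        eps = 1e-6
        checked = 0
        for k in (0, 1):
            for _ in range(3):
                i, j = rng.integers(0, 6, size=2)
                surf = tiny_processor.surfaces[k]
                orig = surf.latent[i, j]
                surf.latent[i, j] = orig + eps
                lp = evaluate_loss(tiny_processor, target)
                surf.latent[i, j] = orig - eps
                lm = evaluate_loss(tiny_processor, target)
                surf.latent[i, j] = orig
                fd = (lp - lm) / (2 * eps)
                if abs(fd) > 1e-8:
                    assert grads[k][i, j] == pytest.approx(fd, rel=1e-4)
                    checked += 1
        assert checked >= 4

    def test_self_target_gives_zero_loss(self, tiny_processor):
        """A processor trivially realizes its own impulse matrix."""
        target = impulse_matrix(tiny_processor)
        loss, grads, _ = loss_and_gradient(tiny_processor, target)
        assert loss < 1e-24
        assert max(np.max(np.abs(g)) for g in grads) < 1e-10

    def test_target_count_mismatch_rejected(self, tiny_processor):
        t = random_uniform_target(4, 4, seed=0)
        with pytest.raises(ValueError):
            loss_and_gradient(tiny_processor, [t, t])

    def test_target_shape_mismatch_rejected(self, tiny_processor):
        with pytest.raises(ValueError):
            loss_and_gradient(tiny_processor, random_uniform_target(5, 4, seed=0))


class TestTrain:
    def test_converges_on_random_target(self, trained_small):
        result = trained_small["result"]
        trace = result.loss_trace
        assert trace[-1] < 0.05
        assert trace[-1] < 0.25 * trace[0]
        assert result.final_loss == pytest.approx(trace[-1], rel=0.2)

    def test_trace_is_bit_for_bit_reproducible(self, tiny_processor):
        target = random_uniform_target(4, 4, seed=3)
        config = TrainConfig(iterations=40, seed=5)
        r1 = train(tiny_processor, target, config)
        r2 = train(tiny_processor, target, config)
        assert np.array_equal(r1.loss_trace, r2.loss_trace)
        for s1, s2 in zip(r1.processor.surfaces, r2.processor.surfaces):
            assert np.array_equal(s1.latent, s2.latent)

    def test_input_processor_left_untouched(self, tiny_processor):
        before = [s.latent.copy() for s in tiny_processor.surfaces]
        target = random_uniform_target(4, 4, seed=3)
        train(tiny_processor, target, TrainConfig(iterations=10))
        for b, s in zip(before, tiny_processor.surfaces):
            assert np.array_equal(b, s.latent)

    def test_one_bit_training_is_worse_than_unbounded(self, tiny_geometry, material):
        target = random_uniform_target(4, 4, seed=6)
        losses = {}
        for b in (None, 1):
            proc = DiffractiveProcessor.initialize(
                tiny_geometry, material, [1.0], seed=8,
                policy=BitDepthPolicy(b_train=b, b_test=b),
            )
            config = TrainConfig(
                iterations=200, seed=8, policy=BitDepthPolicy(b_train=b, b_test=b)
            )
            losses[b] = train(proc, target, config).final_loss
        assert losses[1] > 2.0 * losses[None]

    def test_plateau_early_stopping(self, tiny_processor):
        target = impulse_matrix(tiny_processor)  # already optimal: stops early
        config = TrainConfig(iterations=500, plateau_patience=10)
        result = train(tiny_processor, target, config)
        assert result.iterations_run < 500

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(iterations=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="lbfgs")


class TestBitDepthGeneralization:
    def test_snapped_design_is_flat_for_finer_test_depths(self, tiny_geometry, material):
        """After training at b_train, the loss is *identical* for every
        b_test >= b_train (the fabricated profile already sits on the coarser,
        nested level grid), and strictly worse for b_test < b_train."""
        b_tr = 3
        target = random_uniform_target(4, 4, seed=9)
        proc = DiffractiveProcessor.initialize(
            tiny_geometry, material, [1.0], seed=10,
            policy=BitDepthPolicy(b_train=b_tr, b_test=b_tr),
        )
        config = TrainConfig(
            iterations=250, seed=10, policy=BitDepthPolicy(b_train=b_tr, b_test=b_tr)
        )
        result = train(proc, target, config)
        ref = result.final_loss
        for b_te in (3, 4, 6, 8, 12, None):
            assert bit_depth_eval(result.processor, target, b_te) == pytest.approx(
                ref, abs=1e-12
            )
        assert bit_depth_eval(result.processor, target, 1) > ref

    def test_snap_is_idempotent(self, tiny_processor):
        snap_to_quantized(tiny_processor, 4)
        lat = [s.latent.copy() for s in tiny_processor.surfaces]
        snap_to_quantized(tiny_processor, 4)
        for before, s in zip(lat, tiny_processor.surfaces):
            assert np.allclose(before, s.latent, atol=1e-12)

    def test_snap_none_is_noop(self, tiny_processor):
        lat = [s.latent.copy() for s in tiny_processor.surfaces]
        snap_to_quantized(tiny_processor, None)
        for before, s in zip(lat, tiny_processor.surfaces):
            assert np.array_equal(before, s.latent)


class TestMultiwavelength:
    def test_per_wavelength_losses_and_weights(self, tiny_geometry):
        mat = Dispersion("poly", table={1.0: 1.65, 1.1: 1.66})
        proc = DiffractiveProcessor.initialize(tiny_geometry, mat, [1.0, 1.1], seed=12)
        assert proc.multiwavelength
        t1 = random_uniform_target(4, 4, seed=13)
        t2 = random_uniform_target(4, 4, seed=14)
        config = TrainConfig(iterations=60, seed=12, loss_weights=[2.0, 1.0])
        result = train(proc, [t1, t2], config)
        assert len(result.per_wavelength_losses) == 2
        l1, l2 = result.per_wavelength_losses
        assert result.final_loss == pytest.approx((2 * l1 + l2) / 3, abs=1e-12)
        # both channels actually improved over the random initialization
        assert l1 < transformation_error(
            t1.entries, impulse_matrix(proc, wavelength=1.0).entries
        )

    def test_multiwavelength_snap_quantizes_thickness(self, tiny_geometry):
        """With several design wavelengths the *thickness* is quantized, so
        snapped thickness values sit exactly on the k*t_max/2**b grid."""
        mat = Dispersion("poly", table={1.0: 1.65, 1.1: 1.66})
        proc = DiffractiveProcessor.initialize(tiny_geometry, mat, [1.0, 1.1], seed=15)
        snap_to_quantized(proc, 3)
        from dpsf import thickness_from_latent

        for s in proc.surfaces:
            t = thickness_from_latent(s.latent, s.t_max)
            steps = t / (s.t_max / 2**3)
            assert np.allclose(steps, np.round(steps), atol=1e-9)


class TestSweep:
    def base_kwargs(self):
        return dict(
            n_features=2 * 36, n_surfaces=2, wavelength=1.0,
            input_shape=(1, 2, 2), output_shape=(1, 2, 2),
        )

    def test_structure_seeds_and_errors(self, material):
        target = random_uniform_target(4, 4, seed=30)
        config = TrainConfig(iterations=30, seed=100)
        # 72 features: 36 per layer at K=2, 9 per layer at K=8 (both square)
        res = sweep(
            "K", [2, 8], self.base_kwargs(), target, material, [1.0], config
        )
        assert res.axis == "K"
        assert res.values == [2, 8]
        assert res.seeds == [1100, 2100]
        assert len(res.errors) == 2 and all(np.isfinite(res.errors))
        assert res.skipped == []
        assert res.as_rows()[0] == (2, res.errors[0], 1100)
        assert res.as_rows()[1][0] == 8

    def test_infeasible_points_are_skipped_with_warning(self, material):
        # N=80 over K=2 gives 40 features per layer: not a perfect square
        target = random_uniform_target(4, 4, seed=31)
        config = TrainConfig(iterations=10, seed=0)
        with pytest.warns(UserWarning, match="skipping"):
            res = sweep(
                "N", [72, 80], self.base_kwargs(), target, material, [1.0], config
            )
        assert res.values == [72]
        assert res.skipped == [80]

    def test_axis_and_order_validation(self, material):
        target = random_uniform_target(4, 4, seed=32)
        config = TrainConfig(iterations=5)
        with pytest.raises(ValueError):
            sweep("Q", [1], self.base_kwargs(), target, material, [1.0], config)
        with pytest.raises(ValueError):
            sweep("K", [3, 2], self.base_kwargs(), target, material, [1.0], config)
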