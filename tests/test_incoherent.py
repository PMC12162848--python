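"""Incoherent forward model: impulse matrix, Monte-Carlo ensemble, scaling."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from dpsf import (
    EmitterVolume,
    PhaseEnsembleSpec,
    TransformMatrix,
    apply_transform,
    ensemble_output,
    impulse_matrix,
    multispectral_output,
    optimal_scale,
    point_psf,
    spectral_crosstalk,
)
from dpsf.wave_optics import propagate_samples


class TestTransformMatrix:
    def test_negative_realized_rejected(self):
        with pytest.raises(ValueError):
            TransformMatrix(np.array([[1.0, -0.1]]), role="realized")

    def test_negative_target_allowed_but_shape_checked(self):
        with pytest.raises(ValueError):
            TransformMatrix(np.ones((4, 4)), input_shape=(1, 2, 3))

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            TransformMatrix(np.ones((2, 2)), role="banana")


class TestImpulseMatrix:
    def test_columns_are_vectorized_point_psfs(self, tiny_processor):
        """Each column of A' equals the vectorized PSF of that input voxel."""
        mat = impulse_matrix(tiny_processor)
        geom = tiny_processor.geometry
        ci, h, w = geom.input_shape
        for q in range(geom.n_input_voxels):
            n, rem = divmod(q, h * w)
            l, m = divmod(rem, w)
            psf = point_psf(tiny_processor, (n, l, m)).vectorized()
            assert np.allclose(mat.entries[:, q], psf, atol=1e-14)

    def test_nonnegative_and_passive(self, tiny_processor):
        mat = impulse_matrix(tiny_processor)
        assert np.all(mat.entries >= 0)
        # each column comes from a unit-power impulse
        assert np.all(mat.entries.sum(axis=0) <= 1.0 + 1e-12)

    def test_cyclic_shift_equivariance(self):
        """Unpadded angular-spectrum propagation is exactly periodic, so a
        cyclic shift of the input field cyclically shifts the output."""
        rng = np.random.default_rng(4)
        u = rng.normal(size=(12, 12)) + 1j * rng.normal(size=(12, 12))
        out = propagate_samples(u, 0.53, 3.0, 1.0, pad_factor=1)
        out_shifted = propagate_samples(
            np.roll(u, (2, 5), axis=(0, 1)), 0.53, 3.0, 1.0, pad_factor=1
        )
        assert np.allclose(np.roll(out, (2, 5), axis=(0, 1)), out_shifted, atol=1e-12)


class TestEnsembleOutput:
    def test_single_emitter_is_exact_at_one_realization(self, tiny_processor):
        """One emitter: the random phase is a global phase, so intensity is
        deterministic and the ensemble equals the impulse response exactly."""
        geom = tiny_processor.geometry
        inten = np.zeros(geom.input_shape)
        inten[0, 1, 0] = 0.7
        vol = EmitterVolume(inten, geom.pitch, geom.d_pp)
        out = ensemble_output(tiny_processor, vol, PhaseEnsembleSpec(n_phase=1, seed=0))
        exact = 0.7 * point_psf(tiny_processor, (0, 1, 0)).intensity
        assert np.allclose(out.intensity, exact, atol=1e-12)

    def test_zero_volume_gives_zero_output(self, tiny_processor):
        geom = tiny_processor.geometry
        vol = EmitterVolume(np.zeros(geom.input_shape), geom.pitch, geom.d_pp)
        out = ensemble_output(tiny_processor, vol, PhaseEnsembleSpec(n_phase=5, seed=0))
        assert np.all(out.intensity == 0)

    def test_planes_add_exactly(self, trained_small):
        """Planes are mutually incoherent and use independent spawned phase
        streams, so a two-plane volume equals the sum of its per-plane parts
        under the same master seed — exactly, not just in expectation."""
        proc = trained_small["result"].processor
        geom = proc.geometry
        rng = np.random.default_rng(9)
        inten = rng.uniform(0.1, 1.0, size=geom.input_shape)
        spec = PhaseEnsembleSpec(n_phase=8, seed=21)
        both = ensemble_output(
            proc, EmitterVolume(inten, geom.pitch, geom.d_pp), spec
        ).intensity
        parts = np.zeros_like(both)
        for n in range(geom.input_shape[0]):
            solo = np.zeros_like(inten)
            solo[n] = inten[n]
            parts += ensemble_output(
                proc, EmitterVolume(solo, geom.pitch, geom.d_pp), spec
            ).intensity
        assert np.allclose(both, parts, atol=1e-12)

    def test_converges_to_matrix_product(self, tiny_processor):
        """Multi-emitter ensemble approaches A' i within a few sigma."""
        geom = tiny_processor.geometry
        inten = np.zeros(geom.input_shape)
        inten[0, 0, 0] = 1.0
        inten[0, 1, 1] = 0.6
        vol = EmitterVolume(inten, geom.pitch, geom.d_pp)
        n_phi = 2000
        out = ensemble_output(
            tiny_processor, vol, PhaseEnsembleSpec(n_phase=n_phi, seed=5)
        )
        mat = impulse_matrix(tiny_processor)
        exact = apply_transform(mat, vol.vectorized())
        err = np.abs(out.vectorized() - exact)
        assert np.max(err) < 5.0 * np.max(exact) / np.sqrt(n_phi)

    def test_monte_carlo_rate(self, tiny_processor):
        """log-log slope of the ensemble error vs N_phi is -1/2 (+- 0.1)."""
        geom = tiny_processor.geometry
        inten = np.zeros(geom.input_shape)
        inten[0, 0, 1] = 1.0
        inten[0, 1, 0] = 0.8
        vol = EmitterVolume(inten, geom.pitch, geom.d_pp)
        exact = apply_transform(impulse_matrix(tiny_processor), vol.vectorized())
        ns = np.array([25, 100, 400, 1600])
        errs = []
        for n_phi in ns:
            e = 0.0
            for seed in (1, 2, 3, 4):
                out = ensemble_output(
                    tiny_processor, vol, PhaseEnsembleSpec(n_phase=int(n_phi), seed=seed)
                )
                e += np.linalg.norm(out.vectorized() - exact)
            errs.append(e / 4)
        slope = np.polyfit(np.log(ns), np.log(errs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_volume_shape_mismatch_rejected(self, tiny_processor):
        vol = EmitterVolume(np.ones((2, 2, 2)), 0.53, 2.67)
        with pytest.raises(ValueError):
            ensemble_output(tiny_processor, vol, PhaseEnsembleSpec(n_phase=1))


class TestApplyTransform:
    def test_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(size=(7, 5))
        i = rng.uniform(size=5)
        mat = TransformMatrix(a)
        out = apply_transform(mat, i)
        expect = np.zeros(7)
        for p in range(7):
            for q in range(5):
                expect[p] += a[p, q] * i[q]
        assert np.allclose(out, expect, atol=1e-14)

    def test_rejects_negative_or_mismatched_input(self):
        mat = TransformMatrix(np.ones((3, 4)))
        with pytest.raises(ValueError):
            apply_transform(mat, np.ones(3))
        with pytest.raises(ValueError):
            apply_transform(mat, np.array([1.0, -1.0, 0.0, 0.0]))


class TestOptimalScale:
    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(size=(9, 6))
        ap = rng.uniform(size=(9, 6))
        sigma = optimal_scale(a, ap)
        res = minimize_scalar(lambda s: np.sum((a - s * ap) ** 2))
        assert abs(sigma - res.x) < 1e-10

    def test_exact_on_scaled_copies(self):
        rng = np.random.default_rng(13)
        ap = rng.uniform(size=(4, 4))
        assert optimal_scale(3.7 * ap, ap) == pytest.approx(3.7, abs=1e-12)

    def test_is_a_stationary_point(self):
        rng = np.random.default_rng(14)
        a, ap = rng.uniform(size=(5, 5)), rng.uniform(size=(5, 5))
        s = optimal_scale(a, ap)
        f = lambda x: np.sum((a - x * ap) ** 2)
        assert f(s) <= f(s + 1e-6) and f(s) <= f(s - 1e-6)

    def test_zero_realized_raises(self):
        with pytest.raises(ZeroDivisionError):
            optimal_scale(np.ones((2, 2)), np.zeros((2, 2)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            optimal_scale(np.ones((2, 2)), np.ones((2, 3)))


class TestMultispectral:
    def test_exact_route_sums_channels(self, tiny_processor):
        """multispectral_output without Monte-Carlo equals A' i summed over
        the processor's wavelengths."""
        geom = tiny_processor.geometry
        rng = np.random.default_rng(15)
        inten = rng.uniform(size=geom.input_shape)
        vol = EmitterVolume(inten, geom.pitch, geom.d_pp)
        out = multispectral_output(tiny_processor, vol)
        expect = np.zeros(geom.n_output_voxels)
        for lam in tiny_processor.wavelengths:
            mat = impulse_matrix(tiny_processor, wavelength=lam)
            expect += apply_transform(mat, vol.vectorized())
        assert np.allclose(out.vectorized(), expect, atol=1e-13)

    def test_spectral_crosstalk_hand_example(self):
        frame = np.array([[4.0, 1.0], [0.0, 5.0]])
        masks = [
            np.array([[True, False], [False, False]]),
            np.array([[False, True], [False, True]]),
        ]
        # channel 0 emitters: energy on channel-1 pixels is 1 + 5 of total 10
        assert spectral_crosstalk(frame, masks, 0) == pytest.approx(0.6)
        # channel 1 emitters: energy on channel-0 pixel is 4 of total 10
        assert spectral_crosstalk(frame, masks, 1) == pytest.approx(0.4)
        assert spectral_crosstalk(np.zeros((2, 2)), masks, 0) == 0.0
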