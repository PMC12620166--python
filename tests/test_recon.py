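"""Unrolled reconstruction: DC steps, denoisers, gradients, training."""

import numpy as np
import pytest

from phimo.forward import (
    CoilSensitivityMaps,
    ExclusionMask,
    expand_mask_keepcenter,
    variable_density_line_mask,
)
from phimo.recon import (
    UnrolledConfig,
    _A,
    _unrolled_forward,
    _unrolled_vjp,
    dc_gradient_step,
    make_denoisers,
    normalize_volume,
    reconstruct_with_masks,
    train_unrolled,
    unrolled_reconstruct,
)
from phimo.relaxometry import DecayStack, fit_monoexp, physics_loss


def _random_instance(rng, n_echo=3, n_coil=2, pe=16, ro=16):
    csm = CoilSensitivityMaps(
        rng.standard_normal((n_coil, 1, pe, ro)) + 1j * rng.standard_normal((n_coil, 1, pe, ro))
    ).csm[:, 0]
    x = rng.standard_normal((n_echo, pe, ro)) + 1j * rng.standard_normal((n_echo, pe, ro))
    return x, csm


class TestNormalizeVolume:
    def test_unit_max_after_normalization(self, tiny_phantom):
        normed, scale = normalize_volume(tiny_phantom.clean_kspace, tiny_phantom.csm)
        images = np.abs(
            np.sum(np.conj(tiny_phantom.csm.csm)[None]
                   * np.fft.ifftshift(np.fft.ifft2(np.fft.fftshift(
                       normed.data, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)),
                   axis=1)
        )
        assert images.max() == pytest.approx(1.0, abs=1e-6)
        assert scale > 0

    def test_round_trip(self, tiny_phantom):
        normed, scale = normalize_volume(tiny_phantom.clean_kspace, tiny_phantom.csm)
        assert np.allclose(normed.data * scale, tiny_phantom.clean_kspace.data, atol=1e-9)

    def test_physics_loss_invariant_under_normalization(self, tiny_phantom):
        mags = np.abs(tiny_phantom.clean_images) + 0.1
        stack = DecayStack(mags, tiny_phantom.te_ms)
        normed, _ = normalize_volume(mags)
        stack_n = DecayStack(normed, tiny_phantom.te_ms)
        bm = tiny_phantom.brain_mask
        assert physics_loss(stack, bm) == pytest.approx(physics_loss(stack_n, bm), abs=1e-10)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            normalize_volume(np.zeros((2, 4, 4)))


class TestDataConsistency:
    def test_consistent_estimate_is_fixed_point(self, rng):
        x, csm = _random_instance(rng)
        y = _A(x, csm)
        plane = np.ones(x.shape[-2:])
        x_next = dc_gradient_step(x, y, plane, csm, eta=1.0)
        assert np.max(np.abs(x_next - x)) < 1e-10

    def test_zero_weights_freeze_the_estimate(self, rng):
        x, csm = _random_instance(rng)
        y = _A(2 * x, csm)
        x_next = dc_gradient_step(x, y, np.zeros(x.shape[-2:]), csm, eta=1.0)
        assert np.array_equal(x_next, x)

    def test_residual_non_increasing_over_iterations(self, rng):
        x, csm = _random_instance(rng)
        y = _A(rng.standard_normal(x.shape) + 1j * rng.standard_normal(x.shape), csm)
        mask = variable_density_line_mask(16, 0.4, seed=1, keepcenter=False)
        plane = expand_mask_keepcenter(mask, 16, keepcenter=False)
        res = []
        est = np.zeros_like(x)
        for _ in range(20):
            est = dc_gradient_step(est, plane * y, plane, csm, eta=1.0)
            res.append(np.linalg.norm(plane * (_A(est, csm) - plane * y)))
        assert all(b <= a + 1e-12 for a, b in zip(res, res[1:]))

    def test_shape_mismatch_rejected(self, rng):
        x, csm = _random_instance(rng)
        with pytest.raises(ValueError, match="mismatch"):
            dc_gradient_step(x, _A(x, csm), np.ones((4, 4)), csm)


class TestUnrolledReconstruct:
    def test_full_mask_identity_denoiser_matches_adjoint(self, tiny_phantom):
        ph = tiny_phantom
        full = ExclusionMask(np.ones(ph.pe_size))
        out = unrolled_reconstruct(ph.clean_kspace.data, full, ph.csm, UnrolledConfig())
        adjoint = np.sum(
            np.conj(ph.csm.csm)[None]
            * np.fft.ifftshift(np.fft.ifft2(np.fft.fftshift(
                ph.clean_kspace.data, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)),
            axis=1,
        )
        assert np.max(np.abs(out - adjoint)) < 1e-6 * np.abs(adjoint).max()

    def test_zero_kspace_gives_zero_output(self, tiny_phantom):
        ph = tiny_phantom
        zeros = np.zeros_like(ph.clean_kspace.data)
        for kind in ("identity", "gaussian_smooth"):
            out = unrolled_reconstruct(
                zeros, ExclusionMask(np.ones(ph.pe_size)), ph.csm,
                UnrolledConfig(denoiser=kind),
            )
            assert not np.any(out)

    def test_output_shape_contract(self, tiny_phantom):
        ph = tiny_phantom
        out = unrolled_reconstruct(
            ph.clean_kspace.data, ExclusionMask(np.ones(ph.pe_size)), ph.csm,
            UnrolledConfig(),
        )
        assert out.shape == ph.clean_images.shape

    def test_cnn_without_weights_rejected(self, tiny_phantom):
        ph = tiny_phantom
        with pytest.raises(ValueError, match="weights"):
            unrolled_reconstruct(
                ph.clean_kspace.data, ExclusionMask(np.ones(ph.pe_size)), ph.csm,
                UnrolledConfig(denoiser="cnn"),
            )


class TestHandWrittenGradients:
    """The reverse-mode machinery against central finite differences."""

    def test_mask_gradient_matches_finite_differences(self, rng):
        E, C, Y, RO = 3, 2, 8, 8
        x, csm = _random_instance(rng, E, C, Y, RO)
        y_raw = _A(x, csm)
        w = rng.uniform(0.2, 1.0, Y)
        dens = make_denoisers(UnrolledConfig(n_iterations=2, denoiser="gaussian_smooth"), E)

        def loss_of(weights):
            plane = expand_mask_keepcenter(ExclusionMask(weights), RO, keepcenter=True)
            y_w = plane * y_raw
            out, _ = _unrolled_forward(y_w, plane, csm, dens, 1.0)
            return float(np.sum(np.abs(out) ** 2))

        plane = expand_mask_keepcenter(ExclusionMask(w), RO, keepcenter=True)
        y_w = plane * y_raw
        out, tape = _unrolled_forward(y_w, plane, csm, dens, 1.0)
        W_bar, _, _ = _unrolled_vjp(2 * out, tape, y_w, y_raw, plane, csm, 1.0)
        W_bar[Y // 2 - 1 : Y // 2 + 1, RO // 2 - 1 : RO // 2 + 1] = 0.0
        grad = W_bar.sum(axis=1)
        h = 1e-6
        for i in range(Y):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd = (loss_of(wp) - loss_of(wm)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_denoiser_parameter_gradients_match_finite_differences(self, rng):
        E, C, Y, RO = 2, 2, 8, 8
        img, csm = _random_instance(rng, E, C, Y, RO)
        cfg = UnrolledConfig(n_iterations=2, denoiser="cnn")
        dens = make_denoisers(cfg, E, seed=0)
        mask = ExclusionMask(rng.integers(0, 2, Y).astype(float))
        plane = expand_mask_keepcenter(mask, RO)
        y_raw = _A(img, csm)
        y_w = plane * y_raw

        def loss():
            out, tape = _unrolled_forward(y_w, plane, csm, dens, 1.0)
            d = out - img
            return float(np.mean(np.abs(d) ** 2)), tape, d

        _, tape, d = loss()
        _, _, pgrads = _unrolled_vjp(
            2 * d / d.size, tape, y_w, y_raw, plane, csm, 1.0,
            need_mask_grad=False, need_param_grads=True,
        )
        h = 1e-6
        for di, den in enumerate(dens):
            for pi, p in enumerate(den.params):
                idx = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
                orig = p[idx]
                p[idx] = orig + h
                lp, _, _ = loss()
                p[idx] = orig - h
                lm, _, _ = loss()
                p[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert pgrads[di][pi][idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTraining:
    def _dataset(self, tiny_phantom):
        ph = tiny_phantom
        return [(ph.clean_images[:, s], ph.csm.csm[:, s]) for s in range(ph.n_slices)]

    def test_keepcenter_training_masks_have_center_block_on(self, tiny_phantom):
        Y = tiny_phantom.pe_size
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = variable_density_line_mask(Y, 0.5, seed=rng, keepcenter=True)
            plane = expand_mask_keepcenter(mask, Y, keepcenter=True)
            assert np.all(plane[Y // 2 - 1 : Y // 2 + 1, Y // 2 - 1 : Y // 2 + 1] == 1)

    def test_overfitting_single_slice_reduces_mse_tenfold(self, tiny_phantom):
        data = self._dataset(tiny_phantom)[:1]
        Y = tiny_phantom.pe_size
        gen = lambda rng: variable_density_line_mask(Y, 0.5, seed=rng)
        _, history = train_unrolled(data, gen, epochs=200, lr=5e-3, seed=0)
        assert history[0] / history[-1] >= 10.0

    def test_seeded_training_is_bit_reproducible(self, tiny_phantom):
        data = self._dataset(tiny_phantom)
        Y = tiny_phantom.pe_size
        gen = lambda rng: variable_density_line_mask(Y, 0.5, seed=rng)
        _, h1 = train_unrolled(data, gen, epochs=10, lr=1e-3, seed=4)
        _, h2 = train_unrolled(data, gen, epochs=10, lr=1e-3, seed=4)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_unrolled([], lambda rng: None, epochs=1)


class TestReconQualityOnPhantom:
    def test_t2star_error_decreases_with_exclusion_rate(self, phantom8):
        ph = phantom8
        maes = []
        for rate in (0.4, 0.2, 0.0):
            mask = variable_density_line_mask(ph.pe_size, rate, seed=6, keepcenter=True)
            out = reconstruct_with_masks(ph.clean_kspace, mask, ph.csm, UnrolledConfig())
            maps, _ = fit_monoexp(DecayStack(np.abs(out), ph.te_ms), ph.brain_mask)
            eval_mask = ph.brain_mask & (ph.sg_map < 100.0)
            maes.append(float(np.mean(np.abs(maps.t2star_ms - ph.t2star_map)[eval_mask])))
        assert maes[0] > maes[1] > maes[2]
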