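import numpy as np
import pytest

from k2image.fourier import fft2c, ifft2c
from k2image.synthetic import (ComplexImage, add_kspace_noise,
                               calibrate_noise_sigma, compose_complex,
                               load_magnitude, make_dataset, make_phase,
                               procedural_magnitude, simulate_radial_kspace)
from k2image.trajectories import TrajectorySpec, build_trajectory


class TestProceduralMagnitude:
    def test_deterministic_and_seed_sensitive(self):
        a = procedural_magnitude(64, 0)
        assert np.array_equal(a, procedural_magnitude(64, 0))
        assert not np.array_equal(a, procedural_magnitude(64, 1))

    def test_exact_minmax_normalization(self):
        img = procedural_magnitude(64, 0)
        assert img.min() == 0.0 and img.max() == 1.0

    def test_rejects_tiny_width(self):
        with pytest.raises(ValueError):
            procedural_magnitude(4, 0)


class TestLoadMagnitude:
    def test_resize_and_normalize(self, tmp_path, rng):
        from skimage.io import imsave
        p = tmp_path / "img.png"
        imsave(p, (rng.random((256, 256)) * 255).astype(np.uint8))
        img = load_magnitude(p, 128)
        assert img.shape == (128, 128)
        assert img.min() == 0.0 and img.max() == 1.0

    def test_constant_input_maps_to_zeros(self, tmp_path):
        from skimage.io import imsave
        p = tmp_path / "white.png"
        imsave(p, np.full((32, 32), 255, dtype=np.uint8),
               check_contrast=False)
        assert np.all(load_magnitude(p, 16) == 0.0)

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises((OSError, ValueError)):
            load_magnitude(tmp_path / "missing.png", 16)


class TestMakePhase:
    def test_range_is_sum_of_component_ranges(self):
        mag = procedural_magnitude(64, 3)
        p = make_phase(mag, 4)
        assert p.min() >= -np.pi - 0.25 and p.max() <= np.pi + 0.25

    def test_constant_magnitude_gives_smooth_field_only(self):
        p = make_phase(np.full((32, 32), 0.5), 4)
        # high-pass of a constant is zero; only the [-pi, pi] field remains
        assert p.min() >= -np.pi and p.max() <= np.pi

    def test_deterministic(self):
        mag = procedural_magnitude(32, 7)
        assert np.array_equal(make_phase(mag, 1), make_phase(mag, 1))


class TestComposeComplex:
    def test_zero_phase_is_real(self):
        M = procedural_magnitude(16, 0)
        out = compose_complex(M, np.zeros_like(M))
        np.testing.assert_array_equal(out.data, M.astype(complex))

    def test_modulus_identity(self):
        M = procedural_magnitude(16, 0)
        P = make_phase(M, 1)
        np.testing.assert_allclose(np.abs(compose_complex(M, P).data), M,
                                   atol=1e-14)

    def test_unit_magnitude_quarter_turn(self):
        out = compose_complex(np.ones((8, 8)), np.full((8, 8), np.pi / 2))
        np.testing.assert_allclose(out.data, 1j * np.ones((8, 8)), atol=1e-15)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compose_complex(np.ones((8, 8)), np.ones((4, 4)))


class TestSimulateRadialKSpace:
    def test_zero_image(self, traj16, spec16):
        out = simulate_radial_kspace(ComplexImage(np.zeros((16, 16), complex)),
                                     traj16)
        assert np.allclose(out.data, 0)
        assert out.normalized

    def test_dc_sample_equals_image_mean(self, traj16, spec16):
        c = 0.7 - 0.2j
        out = simulate_radial_kspace(ComplexImage(np.full((16, 16), c)), traj16)
        m0 = spec16.n_samples // 2 - 1
        np.testing.assert_allclose(out.data[:, m0], c, rtol=1e-4)

    def test_linearity(self, traj16, image16):
        a = simulate_radial_kspace(image16, traj16).data
        scaled = ComplexImage(2.0 * image16.data)
        b = simulate_radial_kspace(scaled, traj16).data
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-10)

    def test_dimension_mismatch(self, traj16):
        with pytest.raises(ValueError):
            simulate_radial_kspace(ComplexImage(np.zeros((8, 8), complex)),
                                   traj16)


class TestKSpaceNoise:
    def test_zero_sigma_is_identity(self, kspace16):
        assert add_kspace_noise(kspace16, 0.0, 1) is kspace16

    def test_negative_sigma_rejected(self, kspace16):
        with pytest.raises(ValueError):
            add_kspace_noise(kspace16, -1.0, 1)

    def test_empirical_std_and_determinism(self):
        spec = TrajectorySpec(w_img=16, n_samples=256, n_spokes=400)
        ksp = simulate_radial_kspace(
            ComplexImage(np.zeros((16, 16), complex)), build_trajectory(spec))
        noisy = add_kspace_noise(ksp, 0.01, 5)
        d = noisy.data - ksp.data
        assert abs(d.real.std() / 0.01 - 1) < 0.02
        assert abs(d.imag.std() / 0.01 - 1) < 0.02
        again = add_kspace_noise(ksp, 0.01, 5)
        assert np.array_equal(noisy.data, again.data)


class TestNoiseCalibration:
    def test_analytic_value_at_50db(self):
        # sigma_image = 10^(-50/20) ~ 3.162e-3, divided by w_img
        np.testing.assert_allclose(calibrate_noise_sigma(128, 50.0),
                                   10 ** (-2.5) / 128)

    def test_monotone_in_target(self):
        sig = [calibrate_noise_sigma(64, p) for p in (30, 50, 70, 90)]
        assert all(a > b for a, b in zip(sig, sig[1:]))

    def test_round_trip_psnr_within_half_db(self, rng):
        w, target = 64, 50.0
        mag = procedural_magnitude(w, 9)      # unit peak by construction
        img = compose_complex(mag, make_phase(mag, 10)).data
        sigma = calibrate_noise_sigma(w, target)
        # fully sampled Cartesian k-space on the normalized scale
        kn = fft2c(img) / w
        noise = rng.normal(scale=sigma, size=(w, w)) \
            + 1j * rng.normal(scale=sigma, size=(w, w))
        recon = ifft2c((kn + noise) * w)
        resid = recon - img
        sigma_img = np.sqrt(0.5 * (resid.real.var() + resid.imag.var()))
        psnr = 20 * np.log10(1.0 / sigma_img)
        assert abs(psnr - target) < 0.5


class TestMakeDataset:
    def test_deterministic_and_diverse(self, spec16):
        a = make_dataset(2, spec16, seed=1)
        b = make_dataset(2, spec16, seed=1)
        for s, t in zip(a, b):
            assert np.array_equal(s.image.data, t.image.data)
            assert np.array_equal(s.kspace.data, t.kspace.data)
        assert not np.array_equal(a[0].image.data, a[1].image.data)

    def test_kspace_is_forward_model_of_image(self, spec16, traj16):
        (s,) = make_dataset(1, spec16, seed=2)
        expected = simulate_radial_kspace(s.image, traj16)
        np.testing.assert_array_equal(s.kspace.data, expected.data)

    def test_rejects_empty(self, spec16):
        with pytest.raises(ValueError):
            make_dataset(0, spec16, seed=0)
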