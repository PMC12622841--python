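import numpy as np
import pytest

from k2image.fourier import ifft2c
from k2image.model import (K2IModel, K2IResults, KSpaceToImage,
                           closed_form_fit, design_matrices, forward,
                           infer_magnitude, infer_multicoil, load_model,
                           parameter_count, save_model)
from k2image.synthetic import (ComplexImage, RadialKSpace, Sample,
                               make_dataset)
from k2image.trajectories import TrajectorySpec


@pytest.fixture(scope="module")
def small_model(spec16, rng):
    A = rng.standard_normal((spec16.w_img**2, spec16.n_points))
    return K2IModel(A=A, spec=spec16)


class TestParameterCount:
    @pytest.mark.parametrize("n_spokes,expected", [
        (101, 423_624_704),    # R = 2
        (21, 88_080_384),      # R = 10
        (51, 213_909_504),     # 51-spoke configuration
    ])
    def test_published_configurations(self, n_spokes, expected):
        spec = TrajectorySpec(w_img=128, n_samples=256, n_spokes=n_spokes)
        assert parameter_count(spec) == expected
        A = np.zeros((spec.w_img**2, spec.n_points), dtype=np.float32)
        assert K2IModel(A=A, spec=spec).n_parameters == expected


class TestForward:
    def test_zero_weights_give_zero_image(self, spec16, kspace16):
        model = K2IModel(A=np.zeros((256, spec16.n_points)), spec=spec16)
        assert np.all(forward(model, kspace16).data == 0)

    def test_linear_in_real_scaling(self, small_model, kspace16):
        base = forward(small_model, kspace16).data
        scaled = RadialKSpace(data=3.0 * kspace16.data, spec=kspace16.spec)
        np.testing.assert_allclose(forward(small_model, scaled).data,
                                   3.0 * base, rtol=1e-12)

    def test_commutes_with_multiplication_by_i(self, small_model, kspace16):
        # weight sharing between real/imag channels => complex linearity
        base = forward(small_model, kspace16).data
        rot = RadialKSpace(data=1j * kspace16.data, spec=kspace16.spec)
        np.testing.assert_allclose(forward(small_model, rot).data, 1j * base,
                                   rtol=1e-12)

    def test_shape_mismatch(self, small_model):
        bad_spec = TrajectorySpec(w_img=16, n_samples=16, n_spokes=3)
        bad = RadialKSpace(data=np.zeros((3, 16), complex), spec=bad_spec)
        with pytest.raises(ValueError):
            forward(small_model, bad)


class TestInference:
    def test_magnitude_nonnegative_and_phase_invariant(self, small_model,
                                                       kspace16):
        mag = infer_magnitude(small_model, kspace16)
        assert np.all(mag >= 0)
        rot = RadialKSpace(data=np.exp(0.7j) * kspace16.data,
                           spec=kspace16.spec)
        np.testing.assert_allclose(infer_magnitude(small_model, rot), mag,
                                   rtol=1e-10, atol=1e-14)

    def test_multicoil_rss(self, small_model, kspace16):
        single = infer_magnitude(small_model, kspace16)
        np.testing.assert_array_equal(
            infer_multicoil(small_model, [kspace16]), single)
        two = infer_multicoil(small_model, [kspace16, kspace16])
        np.testing.assert_allclose(two, np.sqrt(2) * single, rtol=1e-12)

    def test_multicoil_order_invariant(self, small_model, kspace16):
        other = RadialKSpace(data=2.0 * kspace16.data, spec=kspace16.spec)
        a = infer_multicoil(small_model, [kspace16, other])
        b = infer_multicoil(small_model, [other, kspace16])
        np.testing.assert_array_equal(a, b)

    def test_empty_coil_list(self, small_model):
        with pytest.raises(ValueError):
            infer_multicoil(small_model, [])


def _samples_from_design(A_star, spec, n, rng):
    """Samples whose targets are exactly X @ A*^T (full-rank random inputs)."""
    w = spec.w_img
    out = []
    for i in range(n):
        x = rng.standard_normal(spec.n_points) \
            + 1j * rng.standard_normal(spec.n_points)
        k_cart = (A_star @ x).reshape(w, w)
        out.append(Sample(
            image=ComplexImage(ifft2c(k_cart)),
            kspace=RadialKSpace(data=x.reshape(spec.n_spokes, spec.n_samples),
                                spec=spec),
            seed=i))
    return out


class TestClosedFormFit:
    def test_recovers_known_weights(self, rng):
        spec = TrajectorySpec(w_img=8, n_samples=10, n_spokes=3)
        A_star = rng.standard_normal((64, spec.n_points))
        samples = _samples_from_design(A_star, spec, 80, rng)
        fit = closed_form_fit(samples, spec, ridge=0.0)
        err = np.abs(fit.A - A_star).max() / np.abs(A_star).max()
        assert err < 1e-6

    def test_huge_ridge_shrinks_weights_to_zero(self, rng):
        spec = TrajectorySpec(w_img=8, n_samples=10, n_spokes=3)
        A_star = rng.standard_normal((64, spec.n_points))
        samples = _samples_from_design(A_star, spec, 80, rng)
        fit = closed_form_fit(samples, spec, ridge=1e12)
        assert np.abs(fit.A).max() < 1e-6

    def test_radial_operator_is_singular_without_ridge(self, spec16):
        # all spokes share the DC sample and line projections of a 16-wide
        # image carry < n_samples dof, so the normal equations are singular
        samples = make_dataset(150, spec16, seed=3)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            closed_form_fit(samples, spec16, ridge=0.0)
        fit = closed_form_fit(samples, spec16, ridge="auto")
        assert fit.training_meta["ridge"] > 0

    def test_global_optimality_on_training_objective(self, spec16, rng):
        samples = make_dataset(150, spec16, seed=3)
        fit = closed_form_fit(samples, spec16, ridge=1e-8)
        X, Y = design_matrices(samples)
        obj_opt = np.mean((X @ fit.A.T - Y) ** 2)
        perturbed = fit.A + 1e-3 * rng.standard_normal(fit.A.shape)
        assert obj_opt <= np.mean((X @ perturbed.T - Y) ** 2)


class TestPersistence:
    def test_round_trip_bit_identical(self, small_model, kspace16, tmp_path):
        p = tmp_path / "model.h5"
        save_model(small_model, p)
        loaded = load_model(p)
        assert np.array_equal(loaded.A, small_model.A)
        assert loaded.spec == small_model.spec
        np.testing.assert_array_equal(forward(loaded, kspace16).data,
                                      forward(small_model, kspace16).data)

    def test_truncated_file_raises_clear_error(self, tmp_path):
        p = tmp_path / "junk.h5"
        p.write_bytes(b"\x89HDF\r\n\x1a\nthis is not a model")
        with pytest.raises(ValueError):
            load_model(p)


class TestModelResultsInterface:
    def test_closed_form_fit_via_estimator(self, spec16):
        samples = make_dataset(150, spec16, seed=5)
        res = KSpaceToImage(samples, spec=spec16).fit(method="closed_form",
                                                      ridge="auto")
        assert isinstance(res, K2IResults)
        s = res.summary()
        assert "parameters" in s and f"{res.model.n_parameters:,}" in s
        np.testing.assert_array_equal(
            res.predict(samples[0].kspace).data,
            forward(res.model, samples[0].kspace).data)

    def test_rejects_mixed_specs(self, spec16):
        samples = make_dataset(2, spec16, seed=5)
        other_spec = TrajectorySpec(w_img=16, n_samples=32, n_spokes=9)
        other = make_dataset(2, other_spec, seed=5)
        with pytest.raises(ValueError):
            KSpaceToImage(samples + other)

    def test_unknown_method(self, spec16):
        samples = make_dataset(2, spec16, seed=5)
        with pytest.raises(ValueError):
            KSpaceToImage(samples).fit(method="sgd")
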