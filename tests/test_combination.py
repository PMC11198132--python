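import json

import numpy as np
import pytest
from scipy.integrate import quad

from combireg import (
    CombinationParams,
    CombinedModel,
    LabelledDataset,
    calibrate,
    combine,
    combined_deviance,
    estimate_pi_sigma,
    fit_combined,
    fit_variant_models,
    predict_combined,
    predict_glm,
)
from combireg.simulation import SimulationSpec, simulate_dataset


def gaussian_cdf_by_quadrature(x, mu, sigma2):
    """Numerical-integration oracle for the calibration transform."""
    sd = np.sqrt(sigma2)

    def density(t):
        return np.exp(-((t - mu) ** 2) / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)

    val, _ = quad(density, mu - 12 * sd, x)
    return val if x > mu - 12 * sd else 0.0


def brute_force_grid_argmin(z, zhat, yhat, c, pi_grid, sigma_grid, clip=1e-5):
    """Independent exhaustive evaluation of the combined deviance grid."""
    from scipy.stats import norm

    best = (np.inf, None, None)
    for pi in pi_grid:
        for sigma in sigma_grid:
            phi = norm.cdf((yhat - c) / sigma)
            p = np.clip((1 - pi) * zhat + pi * phi, clip, 1 - clip)
            loss = -2 * np.sum(z * np.log(p) + (1 - z) * np.log(1 - p))
            if loss < best[0] - 1e-12:
                best = (loss, pi, sigma)
    return best


class TestCalibrate:
    def test_half_at_threshold(self):
        for sigma2 in (0.01, 1.0, 50.0):
            assert calibrate(np.array([3.0]), 3.0, sigma2)[0] == 0.5

    def test_one_sd_above_threshold(self):
        got = calibrate(np.array([1.0 + 2.0]), 1.0, 4.0)[0]  # c + sigma
        oracle = gaussian_cdf_by_quadrature(3.0, 1.0, 4.0)
        assert abs(got - oracle) < 1e-9
        assert abs(got - 0.841345) < 1e-6

    def test_large_variance_limit(self):
        got = calibrate(np.array([-1.0]), 0.0, 1e8)[0]
        assert abs(got - 0.5) < 1e-3

    def test_matches_quadrature_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            c = rng.normal()
            sigma2 = float(rng.uniform(0.1, 5.0))
            yhat = c + rng.normal()
            got = calibrate(np.array([yhat]), c, sigma2)[0]
            assert abs(got - gaussian_cdf_by_quadrature(yhat, c, sigma2)) < 1e-8

    def test_monotone_and_symmetric(self, rng):
        c = 0.7
        yhat = np.sort(rng.normal(size=50))
        out = calibrate(yhat, c, 2.0)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out > 0) & (out < 1))
        mirrored = calibrate(2 * c - yhat, c, 2.0)
        np.testing.assert_allclose(mirrored, 1 - out, atol=1e-12)

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError):
            calibrate(np.array([0.0]), 0.0, 0.0)
        with pytest.raises(ValueError):
            calibrate(np.array([0.0]), 0.0, -1.0)


class TestCombine:
    def test_endpoints(self, rng):
        zhat = rng.uniform(size=10)
        phi = rng.uniform(size=10)
        np.testing.assert_array_equal(combine(zhat, phi, 0.0), zhat)
        np.testing.assert_array_equal(combine(zhat, phi, 1.0), phi)

    def test_midpoint(self):
        assert combine(np.array([0.2]), np.array([0.6]), 0.5)[0] == pytest.approx(0.4)

    def test_output_between_sources(self, rng):
        zhat = rng.uniform(size=100)
        phi = rng.uniform(size=100)
        for pi in rng.uniform(size=5):
            out = combine(zhat, phi, pi)
            assert np.all(out >= np.minimum(zhat, phi) - 1e-12)
            assert np.all(out <= np.maximum(zhat, phi) + 1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine(np.zeros(3), np.zeros(4), 0.5)


class TestCombinedDeviance:
    def test_near_perfect_prediction_near_zero(self):
        eps = 1e-5
        z = np.array([1.0, 0.0])
        phat = np.array([1 - eps, eps])
        dev = combined_deviance(z, phat, clip_epsilon=eps)
        assert 0 <= dev <= 4 * abs(np.log(1 - eps)) + 1e-15

    def test_uninformative_half(self):
        assert combined_deviance(np.array([1.0]), np.array([0.5])) == pytest.approx(
            2 * np.log(2)
        )
        n = 10
        z = np.array([0, 1] * 5, dtype=float)
        assert combined_deviance(z, np.full(n, 0.5)) == pytest.approx(2 * n * np.log(2))

    def test_closed_form_quarter(self):
        dev = combined_deviance(np.array([1.0]), np.array([0.25]))
        assert dev == pytest.approx(-2 * np.log(0.25))
        assert dev == pytest.approx(2.772589, abs=1e-6)

    def test_mean_form_is_sum_over_n(self, rng):
        z = (rng.uniform(size=13) > 0.5).astype(float)
        p = rng.uniform(size=13)
        total = combined_deviance(z, p)
        mean = combined_deviance(z, p, mean=True)
        assert mean == pytest.approx(total / 13)


class TestEstimatePiSigma:
    def test_perfect_logistic_noise_linear_gives_pi_zero(self, rng):
        z = (rng.uniform(size=80) > 0.5).astype(float)
        zhat = np.clip(z, 0.02, 0.98)  # nearly perfect probabilities
        yhat = rng.normal(0.0, 0.01, size=80)  # pure noise around c
        params, surface = estimate_pi_sigma(z, zhat, yhat, c=0.0)
        assert params.pi == 0.0
        loss, pi, sigma = brute_force_grid_argmin(
            z, zhat, yhat, 0.0, surface.pi_grid, surface.sigma_grid
        )
        assert pi == 0.0
        assert surface.loss.min() == pytest.approx(loss)

    def test_perfect_linear_uninformative_logistic_gives_pi_one(self, rng):
        # margin small enough that the smallest grid sigma is not saturated
        # by clipping, making the sigma argmin unique
        y = np.concatenate([rng.uniform(-2, -0.1, 40), rng.uniform(0.1, 2, 40)])
        z = (y > 0).astype(float)
        zhat = np.full(80, 0.5)
        params, surface = estimate_pi_sigma(z, zhat, y, c=0.0)
        assert params.pi == 1.0
        assert params.sigma2 == pytest.approx(surface.sigma_grid[0] ** 2)
        loss, pi, sigma = brute_force_grid_argmin(
            z, zhat, y, 0.0, surface.pi_grid, surface.sigma_grid
        )
        assert (pi, sigma) == (1.0, surface.sigma_grid[0])

    def test_achieved_loss_dominates_endpoints(self, rng):
        z = (rng.uniform(size=60) > 0.4).astype(float)
        zhat = np.clip(z + rng.normal(0, 0.3, 60), 0.01, 0.99)
        yhat = rng.normal(size=60)
        params, surface = estimate_pi_sigma(z, zhat, yhat, c=0.0)
        achieved = surface.loss.min()
        pi0 = surface.loss[surface.pi_grid == 0.0, :].min()
        pi1 = surface.loss[surface.pi_grid == 1.0, :].min()
        assert achieved <= pi0 and achieved <= pi1

    def test_argmin_recorded_on_surface(self, rng):
        z = (rng.uniform(size=40) > 0.5).astype(float)
        params, surface = estimate_pi_sigma(
            z, rng.uniform(size=40), rng.normal(size=40), c=0.0
        )
        a = np.flatnonzero(surface.pi_grid == surface.argmin[0])[0]
        s = np.flatnonzero(surface.sigma_grid == surface.argmin[1])[0]
        assert surface.loss[a, s] == surface.loss.min()
        assert params.sigma2 == pytest.approx(surface.argmin[1] ** 2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            estimate_pi_sigma(
                np.ones(10), rng.uniform(size=10), rng.normal(size=10), c=0.0
            )


def _small_sim(seed, example="standard", n1=400):
    data = simulate_dataset(
        SimulationSpec(example=example, n0=80, n1=n1, p=60, sparsity=0.1, seed=seed)
    )
    return data.train, data.test


class TestFitCombined:
    def test_combined_beats_logistic_out_of_sample_mostly(self):
        wins = 0
        reps = 10
        for seed in range(reps):
            train, test = _small_sim(seed)
            models = fit_variant_models(train, alpha=1.0, k=5, seed=seed)
            dev = {
                name: combined_deviance(test.z, model.predict(test.X), mean=True)
                for name, model in models.items()
            }
            if dev["combined"] <= dev["logistic"] + 1e-12:
                wins += 1
        assert wins >= 7

    def test_latent_binary_contract(self):
        train, test = _small_sim(3, example="latent_binary", n1=50)
        model = fit_combined(train, alpha=1.0, k=5, seed=0)
        phat = model.predict(test.X)
        assert np.all((phat > 0) & (phat < 1))

    def test_deterministic_given_seed(self):
        train, _ = _small_sim(1, n1=10)
        m1 = fit_combined(train, alpha=1.0, k=5, seed=7)
        m2 = fit_combined(train, alpha=1.0, k=5, seed=7)
        assert json.dumps(m1.to_dict()) == json.dumps(m2.to_dict())

    def test_needs_enough_samples(self, toy_dataset):
        with pytest.raises(ValueError):
            fit_combined(toy_dataset, k=40)

    def test_variant_pi_values(self):
        train, _ = _small_sim(2, n1=10)
        models = fit_variant_models(train, alpha=1.0, k=5, seed=0)
        assert models["logistic"].params.pi == 0.0
        assert models["calibrated_linear"].params.pi == 1.0
        assert 0.0 <= models["combined"].params.pi <= 1.0


class TestPredictCombined:
    def test_pi_zero_reduces_to_logistic(self):
        train, test = _small_sim(4, n1=30)
        model = fit_combined(train, alpha=1.0, k=5, seed=1, pi=0.0)
        zhat = predict_glm(model.logistic_fit, test.X, model.standardisation)
        expected = np.clip(zhat, model.clip_epsilon, 1 - model.clip_epsilon)
        np.testing.assert_array_equal(model.predict(test.X), expected)

    def test_pi_one_reduces_to_calibrated_linear(self):
        train, test = _small_sim(5, n1=30)
        model = fit_combined(train, alpha=1.0, k=5, seed=1, pi=1.0)
        yhat = predict_glm(model.linear_fit, test.X, model.standardisation)
        phi = calibrate(yhat, model.params.c, model.params.sigma2)
        expected = np.clip(phi, model.clip_epsilon, 1 - model.clip_epsilon)
        np.testing.assert_array_equal(model.predict(test.X), expected)

    def test_single_row_matches_batch(self):
        train, test = _small_sim(6, n1=20)
        model = fit_combined(train, alpha=1.0, k=5, seed=2)
        batch = model.predict(test.X)
        single = model.predict(test.X[3])
        assert single.shape == (1,)
        assert single[0] == batch[3]

    def test_output_clipped(self):
        train, test = _small_sim(7, example="latent_binary", n1=200)
        model = fit_combined(train, alpha=1.0, k=5, seed=0)
        phat = predict_combined(model, test.X)
        eps = model.clip_epsilon
        assert phat.min() >= eps and phat.max() <= 1 - eps

    def test_column_mismatch_raises(self):
        train, _ = _small_sim(8, n1=10)
        model = fit_combined(train, alpha=1.0, k=5, seed=0)
        with pytest.raises(ValueError):
            model.predict(np.ones((2, train.p + 1)))


class TestSerialisation:
    def test_round_trip_bit_identical_predictions(self, tmp_path):
        train, test = _small_sim(9, n1=40)
        model = fit_combined(train, alpha=1.0, k=5, seed=3)
        path = tmp_path / "model.json"
        model.save(str(path))
        loaded = CombinedModel.load(str(path))
        np.testing.assert_array_equal(loaded.predict(test.X), model.predict(test.X))
        parts_a = model.predict_parts(test.X)
        parts_b = loaded.predict_parts(test.X)
        for col in ("zhat", "yhat", "phi", "phat"):
            np.testing.assert_array_equal(parts_a[col], parts_b[col])

    def test_document_fields(self, tmp_path):
        train, _ = _small_sim(10, n1=10)
        model = fit_combined(train, alpha=1.0, k=5, seed=0)
        doc = model.to_dict()
        for key in ("pi", "sigma2", "c", "alpha", "direction", "clip_epsilon",
                    "logistic", "linear", "standardisation", "version"):
            assert key in doc
        assert doc["logistic"]["lambda"] == model.logistic_fit.lambda_selected

    def test_save_load_save_stable(self, tmp_path):
        train, _ = _small_sim(11, n1=10)
        model = fit_combined(train, alpha=1.0, k=5, seed=0)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        model.save(str(p1))
        CombinedModel.load(str(p1)).save(str(p2))
        assert p1.read_bytes() == p2.read_bytes()


class TestDirectionLe:
    def test_le_direction_flips_calibration(self, rng):
        # positive class is y <= c: larger yhat must mean smaller phat at pi=1
        X = rng.standard_normal((80, 10))
        y = X[:, 0] * 2.0 + rng.standard_normal(80) * 0.5 + 25.0
        ds = LabelledDataset(X=X, y=y, c=25.0, direction="le")
        model = fit_combined(ds, alpha=1.0, k=5, seed=0, pi=1.0)
        grid = np.zeros((2, 10))
        grid[0, 0] = -2.0  # low yhat -> likely y <= c -> high probability
        grid[1, 0] = 2.0
        phat = model.predict(grid)
        assert phat[0] > phat[1]
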