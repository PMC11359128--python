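import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilhazard.geostat import (
    FAMILIES,
    EmpiricalVariogram,
    VariogramModel,
    classify_spd,
    empirical_semivariogram,
    fit_variogram,
    krige,
    krige_grid,
    loo_cross_validate,
    model_semivariance,
    select_best_model,
)
from soilhazard.io import ValidationError
from soilhazard.synthetic import generate_gaussian_field

from conftest import make_samples


def _random_samples(rng, n=12, extent=20.0, metal="Cu"):
    coords = rng.uniform(0, extent, (n, 2))
    vals = rng.uniform(1, 100, n)
    return make_samples(coords, **{metal: vals})


def _dense_ok_oracle(coords, values, model, target):
    """Full-matrix ordinary-kriging solve, no neighborhood truncation."""
    from scipy.spatial.distance import cdist

    n = len(coords)
    cov = model.sill - model.semivariance(cdist(coords, coords))
    np.fill_diagonal(cov, model.sill)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = cov
    lhs[n, :n] = lhs[:n, n] = 1.0
    d0 = np.linalg.norm(coords - target, axis=1)
    rhs = np.append(model.sill - model.semivariance(d0), 1.0)
    sol = np.linalg.inv(lhs) @ rhs
    return float(sol[:n] @ values)


class TestModelSemivariance:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_zero_lag_is_zero(self, family):
        m = VariogramModel(family, 0.3, 0.5, 5.0)
        assert m.semivariance(0.0) == 0.0

    @pytest.mark.parametrize("family", ["spherical", "circular"])
    def test_sill_attained_at_range(self, family):
        # Cu semivariogram: nugget 0.7, partial sill 0.27 -> sill 0.97
        m = VariogramModel(family, 0.7, 0.27, 10.0)
        assert m.semivariance(10.0) == pytest.approx(0.97, abs=1e-12)
        assert m.semivariance(25.0) == pytest.approx(0.97, abs=1e-12)

    def test_exponential_approaches_sill(self):
        # Cr semivariogram: nugget 0.41, partial sill 0.64 -> sill 1.05
        m = VariogramModel("exponential", 0.41, 0.64, 10.0)
        assert m.semivariance(1000 * 10.0) == pytest.approx(1.05, abs=1e-6)

    @pytest.mark.parametrize("shape,family", [(1.0, "exponential"), (2.0, "gaussian")])
    def test_stable_reduces_to_classical_families(self, shape, family):
        h = np.linspace(0, 30, 101)
        stable = VariogramModel("stable", 0.2, 0.8, 5.0, shape)
        classic = VariogramModel(family, 0.2, 0.8, 5.0)
        np.testing.assert_allclose(stable.semivariance(h), classic.semivariance(h),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        family=st.sampled_from(FAMILIES),
        nugget=st.floats(0, 2),
        psill=st.floats(0, 5),
        rng_a=st.floats(0.1, 50),
        shape=st.floats(0.1, 2.0),
        h=st.tuples(st.floats(0, 100), st.floats(0, 100)),
    )
    def test_nondecreasing_in_lag(self, family, nugget, psill, rng_a, shape, h):
        m = VariogramModel(family, nugget, psill, rng_a, shape)
        h1, h2 = sorted(h)
        assert m.semivariance(h1) <= m.semivariance(h2) + 1e-12

    def test_negative_lag_rejected(self):
        m = VariogramModel("exponential", 0.1, 0.9, 5.0)
        with pytest.raises(ValidationError):
            m.semivariance(-1.0)

    @pytest.mark.parametrize("kwargs", [
        dict(family="triangular", nugget=0, partial_sill=1, range_=1),
        dict(family="exponential", nugget=-0.1, partial_sill=1, range_=1),
        dict(family="exponential", nugget=0, partial_sill=1, range_=0),
        dict(family="stable", nugget=0, partial_sill=1, range_=1, shape=2.5),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            VariogramModel(**kwargs)


class TestEmpiricalSemivariogram:
    def test_two_sample_hand_computation(self):
        # values 0 and 2 at distance 5: gamma = (2-0)^2 / (2*1) = 2
        s = make_samples([[0, 0], [3, 4]], Cu=[0.0, 2.0])
        emp = empirical_semivariogram(s, "Cu", lag_width=10.0, max_lag=10.0)
        assert emp.semivariance[emp.populated].tolist() == [2.0]
        assert emp.pair_counts[emp.populated].tolist() == [1]

    def test_constant_field_has_zero_semivariance(self, rng):
        coords = rng.uniform(0, 10, (30, 2))
        s = make_samples(coords, Cu=np.full(30, 7.0))
        emp = empirical_semivariogram(s, "Cu")
        assert np.all(emp.semivariance[emp.populated] == 0.0)

    def test_white_noise_flat_at_unit_variance(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 50, (1000, 2))
        noise = rng.standard_normal(1000)
        noise = (noise - noise.mean()) / noise.std()  # variance exactly 1
        s = make_samples(coords, nonnegative=False, M=noise)
        emp = empirical_semivariogram(s, "M")
        g = emp.semivariance[emp.populated]
        assert np.all(np.abs(g - 1.0) < 0.1)

    def test_no_pairs_within_max_lag_rejected(self):
        s = make_samples([[0, 0], [100, 100]], Cu=[1.0, 2.0])
        with pytest.raises(ValidationError, match="no pairs"):
            empirical_semivariogram(s, "Cu", lag_width=1.0, max_lag=1.0)


class TestFitVariogram:
    def _emp_from_model(self, model, n_bins=12, max_lag=30.0, counts=50):
        centers = (np.arange(n_bins) + 0.5) * (max_lag / n_bins)
        return EmpiricalVariogram(
            centers, model.semivariance(centers),
            np.full(n_bins, counts), max_lag, max_lag / n_bins,
        )

    def test_noise_free_spherical_recovered(self):
        true = VariogramModel("spherical", 0.25, 0.75, 12.0)
        fit, obj = fit_variogram(self._emp_from_model(true), "spherical")
        assert fit.nugget == pytest.approx(true.nugget, rel=1e-3, abs=1e-6)
        assert fit.partial_sill == pytest.approx(true.partial_sill, rel=1e-3)
        assert fit.range_ == pytest.approx(true.range_, rel=1e-3)
        assert obj < 1e-10

    def test_flat_variogram_resolves_to_pure_nugget(self):
        emp = EmpiricalVariogram(
            np.array([2.0, 6.0, 10.0, 14.0]), np.full(4, 0.8),
            np.array([30, 60, 80, 40]), 16.0, 4.0,
        )
        fit, _ = fit_variogram(emp, "exponential")
        assert fit.nugget == pytest.approx(0.8, abs=1e-6)
        assert fit.partial_sill == pytest.approx(0.0, abs=1e-6)

    def test_exponential_sill_from_published_parameters(self):
        # V semivariogram row: nugget 0.38, partial sill 0.63 -> sill 1.01
        true = VariogramModel("exponential", 0.38, 0.63, 9.0)
        fit, _ = fit_variogram(self._emp_from_model(true), "exponential")
        assert fit.sill == pytest.approx(1.01, abs=0.01)

    def test_stable_shape_recovered(self):
        true = VariogramModel("stable", 0.1, 0.9, 8.0, 1.6)
        fit, _ = fit_variogram(self._emp_from_model(true), "stable")
        assert fit.shape == pytest.approx(1.6, abs=0.05)

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0]), np.array([0.5, 0.6]),
                                 np.array([3, 4]), 3.0, 1.0)
        with pytest.raises(ValidationError, match="3 populated"):
            fit_variogram(emp, "exponential")


class TestKrige:
    MODEL = VariogramModel("exponential", 0.1, 0.9, 5.0)

    def test_single_sample_predicts_its_value_everywhere(self):
        s = make_samples([[1.0, 1.0]], Cu=[3.5])
        preds, _ = krige(s, "Cu", self.MODEL, [[0, 0], [8, 3], [100, 100]])
        np.testing.assert_allclose(preds, 3.5)

    def test_equidistant_samples_weighted_equally(self):
        s = make_samples([[0, 0], [2, 0]], Cu=[1.0, 5.0])
        preds, _ = krige(s, "Cu", self.MODEL, [[1.0, 0.0]])
        assert preds[0] == pytest.approx(3.0, abs=1e-10)

    def test_matches_dense_linear_solve_oracle(self, rng):
        s = _random_samples(rng, n=5)
        targets = rng.uniform(0, 20, (7, 2))
        preds, _ = krige(s, "Cu", self.MODEL, targets)
        expected = [
            _dense_ok_oracle(s.coords, s.values("Cu"), self.MODEL, t)
            for t in targets
        ]
        np.testing.assert_allclose(preds, expected, atol=1e-8)

    def test_neighborhood_equals_dense_solve_when_k_covers_all(self, rng):
        s = _random_samples(rng, n=12)
        targets = rng.uniform(0, 20, (5, 2))
        p_full, _ = krige(s, "Cu", self.MODEL, targets, k=12)
        expected = [
            _dense_ok_oracle(s.coords, s.values("Cu"), self.MODEL, t)
            for t in targets
        ]
        np.testing.assert_allclose(p_full, expected, atol=1e-8)

    def test_weights_sum_to_one_via_shift_invariance(self, rng):
        # adding a constant to every sample value must shift every
        # prediction by exactly that constant (unbiasedness constraint)
        s = _random_samples(rng, n=20)
        targets = rng.uniform(0, 20, (6, 2))
        p1, _ = krige(s, "Cu", self.MODEL, targets)
        shifted = make_samples(s.coords, Cu=s.values("Cu") + 1000.0)
        p2, _ = krige(shifted, "Cu", self.MODEL, targets)
        np.testing.assert_allclose(p2 - p1, 1000.0, atol=1e-8)

    def test_exact_interpolation_with_zero_nugget(self, rng):
        s = _random_samples(rng, n=10)
        model = VariogramModel("exponential", 0.0, 1.0, 5.0)
        preds, variances = krige(s, "Cu", model, s.coords)
        np.testing.assert_allclose(preds, s.values("Cu"), atol=1e-6)
        np.testing.assert_allclose(variances, 0.0, atol=1e-8)

    def test_duplicate_locations_averaged_with_warning(self):
        s = make_samples([[0, 0], [0, 0], [4, 0]], Cu=[2.0, 6.0, 10.0])
        with pytest.warns(UserWarning, match="duplicate"):
            preds, _ = krige(s, "Cu", self.MODEL, [[0.0, 0.0]])
        model0 = VariogramModel("exponential", 0.0, 1.0, 5.0)
        with pytest.warns(UserWarning, match="duplicate"):
            exact, _ = krige(s, "Cu", model0, [[0.0, 0.0]])
        assert exact[0] == pytest.approx(4.0, abs=1e-6)  # mean of 2 and 6

    def test_zero_sill_model_rejected(self):
        s = make_samples([[0, 0], [1, 1]], Cu=[1.0, 2.0])
        bad = VariogramModel("exponential", 0.0, 0.0, 5.0)
        with pytest.raises(ValidationError, match="positive sill"):
            krige(s, "Cu", bad, [[0.5, 0.5]])


class TestKrigeGrid:
    MODEL = VariogramModel("spherical", 0.2, 0.8, 6.0)

    def test_constant_samples_give_constant_raster(self, rng):
        coords = rng.uniform(0, 10, (8, 2))
        s = make_samples(coords, Cu=np.full(8, 42.0))
        raster = krige_grid(s, "Cu", self.MODEL, (0, 0, 10, 10), 2.0)
        np.testing.assert_allclose(raster.prediction, 42.0, atol=1e-8)

    def test_grid_covers_bbox_without_gaps(self, rng):
        s = _random_samples(rng, n=10, extent=10)
        raster = krige_grid(s, "Cu", self.MODEL, (0, 0, 10.0, 7.0), 1.0)
        assert (raster.n_rows, raster.n_cols) == (7, 10)
        assert np.all(np.isfinite(raster.prediction))
        assert np.all(raster.variance >= 0)
        xs, ys = raster.cell_centers()
        assert xs[0] == 0.5 and xs[-1] == 9.5 and ys[-1] == 6.5

    def test_cell_on_sample_reproduces_value_with_zero_nugget(self):
        # sample placed exactly on a cell center of the 1-km grid
        s = make_samples([[2.5, 3.5], [7.0, 8.0]], Cu=[11.0, 55.0])
        model = VariogramModel("exponential", 0.0, 1.0, 5.0)
        raster = krige_grid(s, "Cu", model, (0, 0, 10, 10), 1.0)
        assert raster.prediction[3, 2] == pytest.approx(11.0, abs=1e-6)

    def test_nonpositive_cell_size_rejected(self, rng):
        s = _random_samples(rng)
        with pytest.raises(ValidationError, match="cell_size"):
            krige_grid(s, "Cu", self.MODEL, (0, 0, 10, 10), 0.0)


class TestLooCrossValidation:
    MODEL = VariogramModel("exponential", 0.3, 0.7, 8.0)

    def test_sample_order_invariance(self, rng):
        s = _random_samples(rng, n=15)
        cv1 = loo_cross_validate(s, "Cu", self.MODEL)
        perm = rng.permutation(15)
        shuffled = make_samples(s.coords[perm], Cu=s.values("Cu")[perm])
        cv2 = loo_cross_validate(shuffled, "Cu", self.MODEL)
        assert cv1.mse == pytest.approx(cv2.mse, abs=1e-10)
        assert cv1.rmsse == pytest.approx(cv2.rmsse, abs=1e-10)

    def test_overstated_sill_deflates_rmsse(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 40, (60, 2))
        true = VariogramModel("exponential", 0.5, 0.5, 8.0)
        f = generate_gaussian_field(coords, true, 21)
        s = make_samples(coords, nonnegative=False, M=f)
        inflated = VariogramModel("exponential", 50.0, 50.0, 8.0)
        cv = loo_cross_validate(s, "M", inflated)
        assert cv.rmsse < 0.5

    def test_too_few_samples_rejected(self):
        s = make_samples([[0, 0], [1, 1]], Cu=[1.0, 2.0])
        with pytest.raises(ValidationError, match="at least 3"):
            loo_cross_validate(s, "Cu", self.MODEL)

    def test_nugget_sill_ratio_reported(self, rng):
        s = _random_samples(rng, n=10)
        cv = loo_cross_validate(s, "Cu", self.MODEL)
        assert cv.nugget_sill_ratio == pytest.approx(0.3)
        assert cv.spd == "moderate"


class TestClassifySpd:
    @pytest.mark.parametrize("nugget,psill,ratio,label", [
        (0.5, 0.4, 0.56, "moderate"),    # As row (printed sill 0.90)
        (0.41, 0.64, 0.39, "moderate"),  # Cr row
        (0.01, 0.95, 0.01, "strong"),    # Fe row
        (0.0, 0.7, 0.0, "strong"),
        (0.25, 0.75, 0.25, "moderate"),  # boundary -> moderate
        (0.75, 0.25, 0.75, "moderate"),  # boundary -> moderate
        (0.9, 0.1, 0.9, "weak"),
    ])
    def test_ratio_and_label(self, nugget, psill, ratio, label):
        got_label, got_ratio = classify_spd(
            VariogramModel("exponential", nugget, psill, 5.0)
        )
        assert round(got_ratio, 2) == ratio
        assert got_label == label

    def test_zero_sill_rejected(self):
        m = VariogramModel("exponential", 0.0, 0.0, 5.0)
        with pytest.raises(ValidationError, match="sill"):
            classify_spd(m)


class TestSelectBestModel:
    def _structured_samples(self, n=40, seed=2):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 30, (n, 2))
        true = VariogramModel("exponential", 0.2, 0.8, 6.0)
        f = generate_gaussian_field(coords, true, seed)
        return make_samples(coords, nonnegative=False, M=f)

    def test_single_candidate_returned_unconditionally(self):
        s = self._structured_samples()
        best, table = select_best_model(s, "M", families=("gaussian",))
        assert best.family == "gaussian"
        assert len(table) == 1

    def test_tied_duplicate_family_first_wins(self):
        s = self._structured_samples()
        best, table = select_best_model(s, "M", families=("spherical", "spherical"))
        assert best.family == "spherical"
        assert table[0]["order"] == 0  # exact tie resolved by input order

    def test_ranked_table_sorted_by_score(self):
        s = self._structured_samples()
        _, table = select_best_model(
            s, "M", families=("exponential", "gaussian", "spherical")
        )
        scores = [row["score"] for row in table]
        assert scores == sorted(scores)
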