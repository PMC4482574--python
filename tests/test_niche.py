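import numpy as np
import pytest
import scipy.spatial.distance

import nichecentroid as nc


@pytest.fixture
def model4():
    """A fitted 4-D model from seeded correlated samples."""
    rng = np.random.default_rng(3)
    cov = np.array([[2.0, 0.5, 0.2, 0.0],
                    [0.5, 1.0, 0.3, 0.1],
                    [0.2, 0.3, 1.5, 0.4],
                    [0.0, 0.1, 0.4, 0.8]])
    data = rng.multivariate_normal(np.array([1.0, -2.0, 0.5, 3.0]), cov,
                                   size=100)
    return nc.fit_niche(data), data


class TestFitNiche:
    def test_centroid_is_arithmetic_mean(self):
        model = nc.fit_niche(np.array([[0, 0], [2, 0], [1, 3.0]]))
        np.testing.assert_allclose(model.centroid, [1.0, 1.0])

    def test_standardized_data_gives_identity_precision(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(60, 3)) @ np.array(
            [[1, 0.4, 0], [0, 1, 0.2], [0, 0, 1.0]])
        # whiten so the sample covariance is exactly the identity
        centered = raw - raw.mean(axis=0)
        cov = np.cov(centered, rowvar=False)
        white = centered @ np.linalg.inv(np.linalg.cholesky(cov)).T
        model = nc.fit_niche(white)
        np.testing.assert_allclose(model.precision, np.eye(3), atol=1e-8)
        assert not model.regularization_used

    def test_duplicated_variable_triggers_regularization(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(30, 2))
        data = np.column_stack([base, base[:, 0]])  # layer 3 = layer 1
        model = nc.fit_niche(data)
        assert model.regularization_used
        d = nc.mahalanobis(model, np.array([1.0, 2.0, 3.0]))
        assert np.isfinite(d)

    def test_zero_variance_variable_regularized(self):
        rng = np.random.default_rng(2)
        data = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        model = nc.fit_niche(data)
        assert model.regularization_used
        assert np.isfinite(nc.mahalanobis(model, np.array([0.0, 7.0])))

    def test_too_few_points(self):
        with pytest.raises(nc.InsufficientDataError):
            nc.fit_niche(np.array([[1.0, 2.0]]))

    def test_json_round_trip(self, tmp_path, model4):
        model, _ = model4
        nc.envelope_radius(model, np.array([model.centroid + 1.0]))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = nc.NicheModel.from_json(path)
        np.testing.assert_allclose(back.centroid, model.centroid)
        np.testing.assert_allclose(back.precision, model.precision, atol=1e-12)
        assert back.d_max == pytest.approx(model.d_max)


class TestMahalanobis:
    def test_zero_at_centroid(self, model4):
        model, _ = model4
        assert nc.mahalanobis(model, model.centroid) == pytest.approx(0.0)

    def test_identity_precision_reduces_to_euclidean(self):
        model = nc.NicheModel(
            variable_names=["a", "b"], centroid=np.zeros(2),
            covariance=np.eye(2), precision=np.eye(2), n_occurrences=10)
        assert nc.mahalanobis(model, np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_matches_explicit_quadratic_form_and_scipy(self, model4):
        model, data = model4
        rng = np.random.default_rng(9)
        for v in rng.normal(size=(10, 4), scale=3):
            diff = v - model.centroid
            loop = 0.0
            for i in range(4):
                for j in range(4):
                    loop += diff[i] * model.precision[i, j] * diff[j]
            expected = np.sqrt(loop)
            assert nc.mahalanobis(model, v) == pytest.approx(expected, rel=1e-12)
            independent = scipy.spatial.distance.mahalanobis(
                v, model.centroid, model.precision)
            assert nc.mahalanobis(model, v) == pytest.approx(independent,
                                                             rel=1e-10)

    def test_dimension_mismatch(self, model4):
        model, _ = model4
        with pytest.raises(nc.ContractError):
            nc.mahalanobis(model, np.zeros(3))

    def test_squared_option(self, model4):
        model, _ = model4
        v = model.centroid + np.array([1.0, 0.0, -1.0, 2.0])
        root = nc.mahalanobis(model, v)
        model.squared = True
        assert nc.mahalanobis(model, v) == pytest.approx(root**2)
        model.squared = False


class TestDistanceSurface:
    def test_constant_stack_at_centroid_is_zero(self, constant_stack):
        model = nc.fit_niche(np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0],
                                       [5.1, 4.9]]),
                             variable_names=["a", "b"])
        model.centroid = np.array([5.0, 5.0])
        surf = nc.distance_surface(model, constant_stack)
        np.testing.assert_allclose(surf.values[surf.valid_mask], 0.0,
                                   atol=1e-8)

    def test_matches_per_pixel_loop(self, random_stack):
        rng = np.random.default_rng(5)
        occ = rng.normal(size=(50, 3))
        model = nc.fit_niche(occ, variable_names=["a", "b", "c"])
        surf = nc.distance_surface(model, random_stack)
        for r in range(20):
            for c in range(20):
                if not random_stack.valid_mask[r, c]:
                    assert np.isnan(surf.values[r, c])
                    continue
                v = random_stack.values[:, r, c]
                assert surf.values[r, c] == pytest.approx(
                    nc.mahalanobis(model, v), rel=1e-10)

    def test_affine_invariance(self, random_stack):
        """Distance is unchanged by any invertible recombination of layers."""
        rng = np.random.default_rng(6)
        occ = rng.normal(size=(50, 3))
        model = nc.fit_niche(occ, variable_names=["a", "b", "c"])
        surf = nc.distance_surface(model, random_stack)

        A = np.array([[2.0, 0.5, 0.0], [0.1, 1.0, -0.3], [0.0, 0.2, 1.5]])
        shift = np.array([1.0, -2.0, 0.5])
        occ_t = occ @ A.T + shift
        vals = np.einsum("ij,jrc->irc", A, random_stack.values) + shift[:, None, None]
        stack_t = nc.EnvStack(spec=random_stack.spec,
                              layer_names=["a", "b", "c"], values=vals,
                              valid_mask=random_stack.valid_mask)
        model_t = nc.fit_niche(occ_t, variable_names=["a", "b", "c"])
        surf_t = nc.distance_surface(model_t, stack_t)
        m = random_stack.valid_mask
        np.testing.assert_allclose(surf_t.values[m], surf.values[m],
                                   rtol=1e-8)

    def test_layer_name_mismatch(self, random_stack):
        model = nc.fit_niche(np.zeros((5, 3)) + np.eye(5, 3),
                             variable_names=["x", "y", "z"])
        with pytest.raises(nc.ContractError):
            nc.distance_surface(model, random_stack)


class TestEnvelope:
    def test_single_occurrence_at_centroid(self, model4):
        model, _ = model4
        nc.envelope_radius(model, model.centroid[None, :])
        assert model.d_max == pytest.approx(0.0)

    def test_dmax_is_max_of_constructed_distances(self):
        model = nc.NicheModel(
            variable_names=["a", "b"], centroid=np.zeros(2),
            covariance=np.eye(2), precision=np.eye(2), n_occurrences=3)
        occ = np.array([[1.0, 0.0], [0.0, 2.5], [0.3, 0.0]])
        nc.envelope_radius(model, occ)
        assert model.d_max == pytest.approx(2.5)

    def test_dmax_attained_by_some_occurrence(self, model4):
        model, data = model4
        nc.envelope_radius(model, data)
        dists = np.array([nc.mahalanobis(model, row) for row in data])
        assert np.max(dists) == pytest.approx(model.d_max, rel=1e-12)

    def test_empty_matrix_rejected(self, model4):
        model, _ = model4
        with pytest.raises(nc.InsufficientDataError):
            nc.envelope_radius(model, np.empty((0, 4)))


class TestPotentialDistribution:
    def test_inclusive_threshold_and_brute_force_count(self, random_stack):
        rng = np.random.default_rng(8)
        occ = rng.normal(size=(40, 3))
        model = nc.fit_niche(occ, variable_names=["a", "b", "c"])
        surf = nc.distance_surface(model, random_stack)
        d_max = float(np.nanmedian(surf.values))
        mask = nc.potential_distribution(surf, d_max)
        expected = 0
        for r in range(20):
            for c in range(20):
                if surf.valid_mask[r, c] and surf.values[r, c] <= d_max:
                    expected += 1
        assert mask.n_inside == expected
        assert not np.any(mask.values & ~surf.valid_mask)

    def test_dmax_zero_selects_only_zero_cells(self, constant_stack):
        model = nc.fit_niche(np.array([[5.0, 5.0]] * 3 + [[6.0, 6.0]]),
                             variable_names=["a", "b"])
        model.centroid = np.array([5.0, 5.0])
        surf = nc.distance_surface(model, constant_stack)
        surf.values[0, 0] = 1.0  # every cell zero except this one
        mask = nc.potential_distribution(surf, 0.0)
        assert mask.n_inside == 99
        assert not mask.values[0, 0]

    def test_infinite_dmax_equals_valid_mask(self, random_stack):
        rng = np.random.default_rng(8)
        model = nc.fit_niche(rng.normal(size=(40, 3)),
                             variable_names=["a", "b", "c"])
        surf = nc.distance_surface(model, random_stack)
        mask = nc.potential_distribution(surf, np.inf)
        np.testing.assert_array_equal(mask.values, surf.valid_mask)

    def test_monotone_in_dmax(self, random_stack):
        rng = np.random.default_rng(8)
        model = nc.fit_niche(rng.normal(size=(40, 3)),
                             variable_names=["a", "b", "c"])
        surf = nc.distance_surface(model, random_stack)
        qs = np.nanquantile(surf.values, [0.2, 0.5, 0.8])
        masks = [nc.potential_distribution(surf, q).values for q in qs]
        assert np.all(masks[0] <= masks[1])
        assert np.all(masks[1] <= masks[2])

    def test_fitting_occurrences_always_inside(self, small_bundle):
        env, _ = nc.extract_values(small_bundle.stack, small_bundle.occurrences)
        model = nc.fit_niche(env, variable_names=small_bundle.stack.layer_names)
        nc.envelope_radius(model, env)
        surf = nc.distance_surface(model, small_bundle.stack)
        mask = nc.potential_distribution(surf, model.d_max)
        from nichecentroid.io_geo import point_to_cell
        for x, y in small_bundle.occurrences.xy:
            cell = point_to_cell(small_bundle.stack.spec, x, y)
            assert mask.values[cell]


class TestSlopeFilter:
    @pytest.fixture
    def mask_and_slope(self, random_stack):
        rng = np.random.default_rng(10)
        model = nc.fit_niche(rng.normal(size=(40, 3)),
                             variable_names=["a", "b", "c"])
        surf = nc.distance_surface(model, random_stack)
        mask = nc.potential_distribution(surf, float(np.nanmedian(surf.values)))
        slope = rng.uniform(0.5, 30.0, size=(20, 20))
        return mask, slope

    def test_huge_cutoff_no_change(self, mask_and_slope):
        mask, slope = mask_and_slope
        out = nc.apply_slope_filter(mask, slope, cutoff=1e6)
        np.testing.assert_array_equal(out.values, mask.values)

    def test_tiny_cutoff_empties_mask(self, mask_and_slope):
        mask, slope = mask_and_slope
        out = nc.apply_slope_filter(mask, slope, cutoff=1e-9)
        assert out.n_inside == 0

    def test_removed_count_matches_brute_force(self, mask_and_slope):
        mask, slope = mask_and_slope
        cutoff = 15.0
        out = nc.apply_slope_filter(mask, slope, cutoff)
        removed = int(np.sum(mask.values & (slope > cutoff)))
        assert mask.n_inside - out.n_inside == removed

    def test_geometry_mismatch(self, mask_and_slope):
        mask, _ = mask_and_slope
        with pytest.raises(nc.ContractError):
            nc.apply_slope_filter(mask, np.zeros((5, 5)), 1.0)
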