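"""Inverse fit: error terms, centroid-vector updates and the two-step loop."""

import numpy as np
import pytest

from sdhspike import (BivariateNormal, FitConfig, PatternLabel,
                      error_terms, fit, fit_with_sigma_search, proportions,
                      region_geometry, update_centre)
from sdhspike.fit import _MapIntegrator, optimize_rho
from sdhspike.patternmap import RegionGeometry


class TestErrorTerms:
    def test_zero_when_equal(self):
        t = np.array([0.2, 0.1, 0.3, 0.35, 0.05])
        e, m = error_terms(t, t)
        assert np.all(e == 0) and m == 0.0

    def test_disjoint_one_hot(self):
        e, m = error_terms(np.array([1, 0, 0, 0, 0.0]),
                           np.array([0, 1, 0, 0, 0.0]))
        assert m == 1.0
        assert e[0] == 1.0 and e[1] == -1.0

    def test_maxerror_uses_absolute_values(self):
        e, m = error_terms(np.array([0.0, 0, 0, 0, 0.2]),
                           np.array([0.5, 0, 0, 0, 0.0]))
        assert m == 0.5  # the largest |E_i| is the negative one


def _geometry(centroids: dict) -> RegionGeometry:
    full = {lab: centroids.get(lab) for lab in PatternLabel}
    return RegionGeometry(
        points={lab: np.empty((0, 2)) for lab in PatternLabel},
        centroids={k: (np.asarray(v, dtype=float) if v is not None else None)
                   for k, v in full.items()},
        counts={lab: 0 for lab in PatternLabel})


class TestUpdateCentre:
    def test_no_error_no_move(self):
        geom = _geometry({PatternLabel.TONIC: (1.0, 1.0)})
        new = update_centre((5.0, 5.0), np.zeros(5), geom)
        assert new == pytest.approx([5.0, 5.0])

    def test_unit_vector_scaling(self):
        """A single error of 0.1 with a centroid 5 units along +x moves the
        centre exactly 0.1 along +x."""
        geom = _geometry({PatternLabel.RELUCTANT: (10.0, 5.0)})
        e = np.array([0.1, 0, 0, 0, 0.0])
        new = update_centre((5.0, 5.0), e, geom)
        assert new == pytest.approx([5.1, 5.0])

    def test_opposite_errors_cancel(self):
        geom = _geometry({PatternLabel.RELUCTANT: (10.0, 5.0),
                          PatternLabel.TONIC: (0.0, 5.0)})
        e = np.array([0.1, 0, 0, 0, 0.1])
        new = update_centre((5.0, 5.0), e, geom)
        assert new == pytest.approx([5.0, 5.0])

    def test_negative_error_pushes_away(self):
        geom = _geometry({PatternLabel.GAP: (10.0, 5.0)})
        e = np.array([0, 0, 0, -0.2, 0.0])
        new = update_centre((5.0, 5.0), e, geom)
        assert new == pytest.approx([4.8, 5.0])

    def test_empty_region_with_error_is_skipped_with_warning(self):
        geom = _geometry({PatternLabel.GAP: (10.0, 5.0)})
        e = np.array([0.3, 0, 0, 0.1, 0.0])  # reluctant centroid missing
        with pytest.warns(UserWarning):
            new = update_centre((5.0, 5.0), e, geom)
        assert new == pytest.approx([5.1, 5.0])


class TestOptimizeRho:
    @pytest.mark.parametrize("true_rho", [0.6, 0.0, -0.4])
    def test_recovers_generating_rho_at_true_centre(self, coarse_map, true_rho):
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, true_rho)
        target = proportions(d, coarse_map)
        integ = _MapIntegrator(coarse_map)
        scan = optimize_rho((3.0, 4.0), (1.0, 1.0), target, integ)
        assert scan.rho == pytest.approx(true_rho, abs=1e-9)
        assert scan.stop  # exact self-consistency terminates the fit

    def test_tie_breaks_toward_incumbent_then_smaller_rho(self):
        from sdhspike.fit import _best_rho, _rho_grid
        rhos = _rho_grid(-0.9, 0.9, 0.1)
        flat = np.full(len(rhos), 0.42)
        # fully tied scan keeps the incumbent
        assert rhos[_best_rho(rhos, flat, incumbent=0.3)] == pytest.approx(0.3)
        # equidistant candidates resolve to the smaller |rho|
        assert rhos[_best_rho(rhos, flat, incumbent=0.25)] == pytest.approx(0.2)
        # a genuine minimum always wins over the incumbent
        dipped = flat.copy()
        dipped[2] = 0.1
        assert rhos[_best_rho(rhos, dipped, incumbent=0.3)] == pytest.approx(rhos[2])


class TestFit:
    def test_fixed_point_converges_immediately(self, coarse_map):
        """A target computed from the initial distribution itself stops in
        the first iteration with MaxError below delta."""
        g = coarse_map.grid
        centre = ((g.g_lt_min + g.g_lt_max) / 2, (g.g_A_min + g.g_A_max) / 2)
        d = BivariateNormal(centre[0], centre[1], 1.0, 1.0, 0.0)
        target = proportions(d, coarse_map)
        res = fit(target, coarse_map)
        assert res.status == "converged_error"
        assert res.iterations == 1
        assert res.mu_Klt == pytest.approx(centre[0])
        assert res.max_error < 0.001

    def test_deterministic(self, coarse_map):
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, 0.6)
        target = proportions(d, coarse_map)
        r1 = fit(target, coarse_map)
        r2 = fit(target, coarse_map)
        assert (r1.mu_Klt, r1.mu_KA, r1.rho, r1.max_error) == \
               (r2.mu_Klt, r2.mu_KA, r2.rho, r2.max_error)

    def test_fitted_proportions_reproduce_max_error(self, coarse_map):
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, 0.6)
        target = proportions(d, coarse_map)
        res = fit(target, coarse_map)
        recomputed = proportions(res.distribution(), coarse_map)
        _, me = error_terms(target, recomputed)
        assert me == pytest.approx(res.max_error, abs=1e-9)

    def test_history_records_every_iteration(self, coarse_map):
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, 0.0)
        target = proportions(d, coarse_map)
        res = fit(target, coarse_map)
        assert len(res.history) == res.iterations
        assert res.history[-1]["max_error"] == res.max_error

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FitConfig(delta=0.01, epsilon=0.003)


class TestSigmaSearch:
    def test_collapsed_grid_equals_plain_fit(self, coarse_map):
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, 0.6)
        target = proportions(d, coarse_map)
        cfg = FitConfig(sigma_grid=(1.0, 1.0, 0.05), sigma=(1.0, 1.0))
        searched = fit_with_sigma_search(target, coarse_map, cfg)
        plain = fit(target, coarse_map, cfg)
        assert searched.sigma_Klt == 1.0 and searched.sigma_KA == 1.0
        assert searched.mu_Klt == pytest.approx(plain.mu_Klt)
        assert searched.rho == pytest.approx(plain.rho)
        assert searched.max_error == pytest.approx(plain.max_error)

    def test_error_surface_shape_and_best(self, coarse_map):
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, 0.0)
        target = proportions(d, coarse_map)
        cfg = FitConfig(sigma_grid=(0.8, 1.2, 0.2))
        res = fit_with_sigma_search(target, coarse_map, cfg)
        assert res.sigma_error_surface.shape == (3, 3)
        assert res.max_error == pytest.approx(res.sigma_error_surface.min(),
                                              abs=1e-12)

    def test_matched_sigma_beats_badly_mismatched_sigma(self, full_map):
        """Fixing sigma at half/1.5x the generating value leaves a larger
        final MaxError than fitting with the true sigma."""
        d = BivariateNormal(3.0, 4.0, 1.0, 1.0, 0.0)
        target = proportions(d, full_map)
        matched = fit(target, full_map, FitConfig(sigma=(1.0, 1.0)))
        low = fit(target, full_map, FitConfig(sigma=(0.5, 0.5)))
        high = fit(target, full_map, FitConfig(sigma=(1.5, 1.5)))
        assert matched.max_error < low.max_error
        assert matched.max_error < high.max_error
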