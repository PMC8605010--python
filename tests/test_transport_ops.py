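"""Elementary transport operations against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from nervelight.media import NerveModel, OpticalMedium
from nervelight.transport import (
    BoundaryExit,
    attenuated_intensity,
    boundary_intersect,
    deposit_segment,
    hg_cdf_cos,
    hg_pdf,
    new_direction,
    reflect_or_transmit,
    sample_path_length,
    sample_scatter_cos,
    sample_scatter_theta,
    weighted_theta_table,
    VoxelGrid,
)

MU_EFF = 3.0655342111938655  # sqrt(3*0.35*(0.35+43*0.2))


class TestPathLength:
    def test_always_positive(self, rng, white_matter):
        draws = [sample_path_length(rng, white_matter) for _ in range(1000)]
        assert min(draws) > 0

    def test_mean_is_inverse_mu_s(self, rng, white_matter):
        n = 1_000_000
        u = rng.random_sample(n)
        draws = -np.log(1.0 - u) / white_matter.mu_s
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - 1.0 / 43.0) < 3 * se

    def test_doubling_mu_s_halves_draws(self, white_matter):
        m2 = OpticalMedium(mu_s=86.0, mu_a=0.35, g=0.8)
        a = [sample_path_length(np.random.RandomState(7), white_matter)
             for _ in range(1)]
        b = [sample_path_length(np.random.RandomState(7), m2)
             for _ in range(1)]
        assert a[0] == pytest.approx(2.0 * b[0])

    def test_literal_convention_mean_is_mu_s(self, rng, white_matter):
        draws = np.array([
            sample_path_length(rng, white_matter, "mu-s-literal")
            for _ in range(20000)
        ])
        assert draws.mean() == pytest.approx(43.0, rel=0.05)

    def test_per_cm_convention_mean(self, rng, white_matter):
        draws = np.array([
            sample_path_length(rng, white_matter, "mu-s-per-cm")
            for _ in range(20000)
        ])
        assert draws.mean() == pytest.approx(10.0 / 43.0, rel=0.05)


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 3.5809),
        (math.pi, 0.0049124),
    ])
    def test_pdf_values_g08(self, theta, expected):
        assert hg_pdf(theta, 0.8) == pytest.approx(expected, rel=1e-4)

    def test_pdf_isotropic_limit(self):
        thetas = np.linspace(0, math.pi, 17)
        np.testing.assert_allclose(hg_pdf(thetas, 0.0),
                                   1.0 / (4 * math.pi))

    def test_sampler_mean_cos_equals_g(self, rng):
        n = 1_000_000
        u = rng.random_sample(n)
        g = 0.8
        tmp = (1 - g * g) / (1 - g + 2 * g * u)
        mu = (1 + g * g - tmp * tmp) / (2 * g)
        se = mu.std() / math.sqrt(n)
        assert abs(mu.mean() - g) < 3 * se

    def test_sampler_isotropic_cos_uniform(self, rng):
        samples = np.array([sample_scatter_cos(rng, 0.0)
                            for _ in range(20000)])
        p = stats.kstest(samples, stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 0.01

    def test_sampler_matches_closed_form_cdf(self, rng):
        g = 0.8
        samples = np.array([sample_scatter_cos(rng, g)
                            for _ in range(50000)])
        p = stats.kstest(samples, lambda m: hg_cdf_cos(m, g)).pvalue
        assert p > 0.01

    def test_weighted_list_matches_inverse_cdf(self, rng):
        g = 0.8
        table = weighted_theta_table(g, 10_000)
        a = np.array([sample_scatter_cos(rng, g, "weighted-list", table)
                      for _ in range(100000)])
        b = np.array([sample_scatter_cos(rng, g) for _ in range(100000)])
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_theta_range(self, rng):
        thetas = [sample_scatter_theta(rng, 0.8) for _ in range(1000)]
        assert all(0.0 <= t <= math.pi for t in thetas)


class TestNewDirection:
    def test_no_deflection_preserves_direction(self, rng):
        prev = np.array([0.0, 0.6, 0.8])
        new = new_direction(prev, 0.0, rng)
        np.testing.assert_allclose(new, prev, atol=1e-12)

    def test_right_angle_deflection(self, rng):
        prev = np.array([1.0, 0.0, 0.0])
        new = new_direction(prev, math.pi / 2, rng)
        assert abs(prev @ new) < 1e-12

    @pytest.mark.parametrize("theta", [0.3, 1.1, 2.5])
    def test_dot_product_equals_cos_theta(self, rng, theta):
        prev = np.array([0.48, -0.6, 0.64])
        prev /= np.linalg.norm(prev)
        for _ in range(20):
            new = new_direction(prev, theta, rng)
            assert prev @ new == pytest.approx(math.cos(theta), abs=1e-12)
            assert np.linalg.norm(new) == pytest.approx(1.0, abs=1e-12)

    def test_azimuth_uniform_about_prev(self, rng):
        """The scatter azimuth around the previous direction is uniform."""
        prev = np.array([0.0, 0.0, 1.0])
        theta = 0.7
        phis = []
        for _ in range(20000):
            new = new_direction(prev, theta, rng)
            phis.append(math.atan2(new[1], new[0]) % (2 * math.pi))
        p = stats.kstest(np.array(phis),
                         stats.uniform(scale=2 * math.pi).cdf).pvalue
        assert p > 0.01

    def test_paper_literal_realises_complement_deflection(self, rng):
        """The orthogonal-vector construction deflects by pi/2 - theta."""
        prev = np.array([0.2, -0.4, 0.6])
        prev /= np.linalg.norm(prev)
        theta = 0.5
        for _ in range(20):
            new = new_direction(prev, theta, rng, "paper-literal",
                                path_length=0.1)
            deflection = math.acos(np.clip(prev @ new, -1, 1))
            assert deflection == pytest.approx(math.pi / 2 - theta,
                                               abs=1e-9)


class TestAttenuation:
    def test_zero_path_returns_initial(self, white_matter):
        assert attenuated_intensity(0.7, 0.0, white_matter) == 0.7

    def test_mu_eff_value(self, white_matter):
        assert white_matter.mu_eff == pytest.approx(3.06554, abs=1e-5)

    def test_decay_at_one_mm(self, white_matter):
        assert attenuated_intensity(1.0, 1.0, white_matter) == pytest.approx(
            0.04659, rel=1e-3
        )

    def test_never_exceeds_initial(self, white_matter, rng):
        ts = rng.random_sample(100) * 5
        vals = [attenuated_intensity(1.0, t, white_matter) for t in ts]
        assert all(0 < v <= 1.0 for v in vals)


class TestBoundaryIntersect:
    def test_radial_travel_hits_normal_incidence(self, nerve):
        rec = boundary_intersect((0, 0, 1.0), (1.0, 0, 1.0), nerve)
        assert rec.kind == "side"
        assert rec.incidence_angle == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rec.exit_point, [0.5, 0, 1.0],
                                   atol=1e-12)

    def test_axial_travel_never_exits_side_wall(self, nerve):
        rec = boundary_intersect((0.2, 0.1, 0.5), (0.2, 0.1, 1.5), nerve)
        assert rec is None
        rec = boundary_intersect((0.2, 0.1, 0.5), (0.2, 0.1, 2.5), nerve)
        assert rec.kind == "cap"

    def test_interior_segment_has_no_crossing(self, nerve):
        assert boundary_intersect((0, 0, 1), (0.1, 0.1, 1.1), nerve) is None

    def test_start_outside_is_contract_violation(self, nerve):
        with pytest.raises(ValueError):
            boundary_intersect((0.9, 0, 1), (0, 0, 1), nerve)

    def test_crossing_matches_bisection_oracle(self, nerve, rng):
        """Quadratic-solve crossing vs an independent bisection root-finder."""
        def radial2(p):
            return p[0] ** 2 + p[1] ** 2

        for _ in range(200):
            start = np.array([0.0, 0.0, 1.0])
            start[:2] = rng.random_sample(2) * 0.3 - 0.15
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            end = start + d * 2.0
            rec = boundary_intersect(start, end, nerve)
            if rec is None or rec.kind != "side":
                continue
            assert radial2(rec.exit_point) == pytest.approx(0.25, abs=1e-9)
            lo, hi = 0.0, 2.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if radial2(start + mid * d) < 0.25:
                    lo = mid
                else:
                    hi = mid
            assert rec.distance == pytest.approx(0.5 * (lo + hi), abs=1e-9)


class TestReflectOrTransmit:
    def test_critical_angle_value(self):
        assert math.degrees(math.asin(1.0 / 1.32)) == pytest.approx(
            49.25, abs=0.01
        )

    def _exit(self, angle):
        return BoundaryExit(np.array([0.5, 0.0, 1.0]), 0.1, angle, "side")

    def test_normal_incidence_transmits(self):
        assert reflect_or_transmit(self._exit(0.0), 1.32, 1.0) is None

    def test_above_critical_reflects(self):
        assert reflect_or_transmit(self._exit(math.radians(60)), 1.32,
                                   1.0) == "reflect"

    def test_just_below_critical_transmits(self):
        crit = math.asin(1.0 / 1.32)
        assert reflect_or_transmit(self._exit(crit - 1e-6), 1.32, 1.0) is None
        assert reflect_or_transmit(self._exit(crit + 1e-6), 1.32,
                                   1.0) == "reflect"

    def test_no_tir_when_external_index_higher(self):
        assert reflect_or_transmit(self._exit(math.radians(80)), 1.32,
                                   1.4) is None


class TestDepositSegment:
    def test_zero_length_changes_nothing(self, nerve, white_matter):
        grid = VoxelGrid.for_nerve(nerve, 0.01)
        n = deposit_segment(grid, (0, 0, 1), (0, 0, 1), 0.0, 1.0,
                            white_matter, 1e-3)
        assert n == 0 and grid.total == 0.0

    def test_geometric_series_oracle(self, nerve, white_matter):
        """Straight 0.1 mm segment at 1 um steps: the grid total equals the
        closed-form geometric sum of the decaying sample intensities."""
        grid = VoxelGrid.for_nerve(nerve, 0.01)
        deposit_segment(grid, (0.4, 0, 1.0), (0.3, 0, 1.0), 0.0, 1.0,
                        white_matter, 1e-3)
        expected = sum(math.exp(-MU_EFF * k * 1e-3) for k in range(100))
        assert grid.total == pytest.approx(expected, rel=1e-12)

    def test_deposit_bounded_by_initial_intensity(self, nerve, white_matter,
                                                  rng):
        grid = VoxelGrid.for_nerve(nerve, 0.01)
        deposit_segment(grid, (0.1, -0.2, 0.8), (-0.3, 0.1, 1.2), 0.0, 1.0,
                        white_matter, 1e-3)
        # any single voxel holds at most (samples in it) * I0; a diagonal
        # crossing fits at most sqrt(3)*voxel/step samples
        assert grid.values.max() <= math.sqrt(3) * 0.01 / 1e-3 + 1.0

    def test_out_of_grid_samples_counted(self, white_matter):
        grid = VoxelGrid((0, 0, 0), 0.01, (10, 10, 10))
        nerve_pt0 = (0.05, 0.05, 0.05)
        deposit_segment(grid, nerve_pt0, (0.05, 0.05, 0.3), 0.0, 1.0,
                        white_matter, 1e-3)
        assert grid.skipped_samples > 0
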