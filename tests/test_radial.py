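import math

import numpy as np
import pytest
from scipy.integrate import quad

from divlayers.locio import CellFrame, LocalizationTable, render_image
from divlayers.radial import (
    RadialProjectionModel,
    axis_displacements,
    detect_clusters,
    disk_moments,
    fit_gaussian_projection,
    fit_uniform_disk,
    projected_disk_density,
)
from divlayers.simulate import (
    RadialSimParams,
    sample_rejected_gaussian_radius,
    simulate_radial_clusters,
)


class TestClusterDetection:
    def _cluster_table(self, centers, spread=30.0, n_each=400, seed=0):
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for cx, cy in centers:
            xs.append(rng.normal(cx, spread, n_each))
            ys.append(rng.normal(cy, spread, n_each))
        return LocalizationTable.from_arrays(
            x=np.concatenate(xs), y=np.concatenate(ys)
        )

    def test_single_cluster_extent(self):
        # a tight cluster spanning ~100 nm: second-moment major axis
        # of a Gaussian blob ~ 4 sigma
        table = self._cluster_table([(0.0, 0.0)], spread=25.0)
        image = render_image(table, pixel_size=15.0, smoothing_sd=15.0)
        clusters = detect_clusters(image, threshold_frac=0.2)
        assert len(clusters) == 1
        assert clusters[0].major_axis == pytest.approx(100.0, rel=0.35)

    def test_two_separated_clusters(self):
        table = self._cluster_table([(0.0, 0.0), (500.0, 0.0)])
        image = render_image(table, pixel_size=15.0, smoothing_sd=15.0)
        assert len(detect_clusters(image, threshold_frac=0.2)) == 2

    def test_threshold_above_max_empty(self):
        table = self._cluster_table([(0.0, 0.0)])
        image = render_image(table, pixel_size=15.0)
        assert detect_clusters(image, threshold_frac=1.01) == []

    def test_axis_displacements_absolute(self):
        table = self._cluster_table([(200.0, 100.0)], spread=20.0, seed=1)
        image = render_image(table, pixel_size=15.0, smoothing_sd=15.0)
        clusters = detect_clusters(image, threshold_frac=0.2)
        frame = CellFrame(center=(0.0, 0.0), axis_angle=0.0, length=3000.0)
        disp = axis_displacements(clusters, frame)[0]
        assert disp.long_axis == pytest.approx(200.0, abs=10.0)
        assert disp.short_axis == pytest.approx(100.0, abs=10.0)
        assert disp.cell_length == 3000.0


class TestDiskClosedForms:
    @pytest.mark.parametrize("r_max", [100.0, 419.0, 700.0])
    def test_density_normalizes_to_one(self, r_max):
        integral, _ = quad(lambda r: projected_disk_density(r, r_max), 0, r_max)
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_moments_closed_form(self):
        mean, sd = disk_moments(3.0)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(3.0 / math.sqrt(18.0), abs=1e-12)
        assert sd == pytest.approx(0.7071, abs=1e-4)

    def test_moments_match_monte_carlo(self):
        df = simulate_radial_clusters(
            RadialSimParams(mode="disk", r_max=419.0, n_clusters=1_000_000), seed=0
        )
        mean, sd = disk_moments(419.0)
        mc_err = df.r_nm.std() / math.sqrt(len(df))
        assert abs(df.r_nm.mean() - mean) < 3 * mc_err
        assert df.r_nm.std() == pytest.approx(sd, rel=0.01)


class TestProjectionIdentity:
    @pytest.mark.parametrize(
        "sampler",
        [
            lambda rng, n: np.full(n, 280.0),
            lambda rng, n: rng.uniform(0.0, 500.0, n),
            lambda rng, n: sample_rejected_gaussian_radius(280.0, 120.0, n, rng),
        ],
        ids=["constant", "uniform", "gaussian-rejected"],
    )
    def test_mean_projection_two_over_pi(self, sampler):
        # E|r cos phi| = (2 / pi) E[r] for any nonnegative radius distribution
        rng = np.random.default_rng(1)
        r = sampler(rng, 200_000)
        phi = rng.uniform(0, 2 * math.pi, len(r))
        lhs = np.mean(np.abs(r * np.cos(phi)))
        assert lhs == pytest.approx((2 / math.pi) * np.mean(r), rel=0.01)


class TestGaussianProjectionFit:
    GRID_MU = np.arange(200.0, 381.0, 20.0)
    GRID_SIGMA = np.arange(40.0, 221.0, 20.0)

    def test_recovery_at_study_parameters(self):
        df = simulate_radial_clusters(
            RadialSimParams(mu_r=280.0, sigma_r=120.0, n_clusters=613), seed=5
        )
        fit = fit_gaussian_projection(
            df.r_prime_nm.to_numpy(),
            mu_grid=self.GRID_MU,
            sigma_grid=self.GRID_SIGMA,
            n_sim=4000,
            seed=7,
        )
        assert fit.mu_r == pytest.approx(280.0, abs=20.0)
        assert fit.sigma_r == pytest.approx(120.0, abs=20.0)

    def test_recovery_at_alternate_parameters(self):
        df = simulate_radial_clusters(
            RadialSimParams(mu_r=150.0, sigma_r=100.0, n_clusters=1000), seed=6
        )
        fit = fit_gaussian_projection(
            df.r_prime_nm.to_numpy(),
            mu_grid=np.arange(90.0, 251.0, 20.0),
            sigma_grid=np.arange(40.0, 181.0, 20.0),
            n_sim=4000,
            seed=7,
        )
        assert fit.mu_r == pytest.approx(150.0, abs=20.0)
        assert fit.sigma_r == pytest.approx(100.0, abs=20.0)

    def test_degenerate_sigma_pulls_to_grid_minimum(self):
        rng = np.random.default_rng(7)
        phi = rng.uniform(0, 2 * math.pi, 1000)
        r_prime = np.abs(280.0 * np.cos(phi))  # sigma -> 0 limit
        fit = fit_gaussian_projection(
            r_prime,
            mu_grid=np.arange(240.0, 321.0, 20.0),
            sigma_grid=np.arange(20.0, 141.0, 20.0),
            n_sim=4000,
            seed=7,
        )
        assert fit.sigma_r == 20.0

    def test_objective_deterministic_given_seed(self):
        df = simulate_radial_clusters(RadialSimParams(n_clusters=500), seed=8)
        kwargs = dict(
            mu_grid=np.arange(240.0, 321.0, 40.0),
            sigma_grid=np.arange(80.0, 161.0, 40.0),
            n_sim=500,
            seed=3,
        )
        a = fit_gaussian_projection(df.r_prime_nm.to_numpy(), **kwargs)
        b = fit_gaussian_projection(df.r_prime_nm.to_numpy(), **kwargs)
        assert (a.mu_r, a.sigma_r, a.sse) == (b.mu_r, b.sigma_r, b.sse)


class TestUniformDiskFit:
    def test_recovery_at_study_r_max(self):
        df = simulate_radial_clusters(
            RadialSimParams(mode="disk", r_max=419.0, n_clusters=20_000), seed=9
        )
        fit = fit_uniform_disk(df.r_prime_nm.to_numpy())
        assert fit.r_max == pytest.approx(419.0, rel=0.05)
        assert fit.mean_r == pytest.approx(2 * fit.r_max / 3, abs=1e-9)

    def test_boundary_warning_when_grid_too_small(self):
        df = simulate_radial_clusters(
            RadialSimParams(mode="disk", r_max=419.0, n_clusters=1000), seed=10
        )
        with pytest.warns(Warning):
            fit_uniform_disk(
                df.r_prime_nm.to_numpy(), r_max_grid=np.arange(100.0, 200.0, 10.0)
            )

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            RadialProjectionModel(np.abs(np.random.default_rng(0).normal(200, 50, 20)))
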