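import math

import numpy as np
import pytest
from scipy import stats

from divlayers.simulate import (
    FWHM_FACTOR,
    FrapSimParams,
    RadialSimParams,
    RingSimParams,
    TwoColorSimParams,
    simulate_beads,
    simulate_frap,
    simulate_ipalm_layers,
    simulate_radial_clusters,
    simulate_ring_band,
    simulate_two_color,
)


class TestRingBand:
    def test_noiseless_points_lie_on_shell(self):
        p = RingSimParams(diameter=600.0, n_molecules=200, loc_precision=0.0,
                          z_precision=0.0)
        table = simulate_ring_band(p, dims=3, seed=0)
        radii = np.hypot(table.y, table.z)
        np.testing.assert_allclose(radii, 300.0, atol=1e-9)

    def test_long_axis_fwhm_matches_parameter(self):
        # FWHM/sd identity: sd of the long-axis coordinate = w / 2.355
        p = RingSimParams(band_width=115.0, n_molecules=10_000, loc_precision=0.0)
        table = simulate_ring_band(p, seed=1)
        assert np.std(table.x) == pytest.approx(115.0 / FWHM_FACTOR, rel=0.02)

    def test_record_count_without_background(self):
        p = RingSimParams(n_molecules=500, background_density=0.0)
        assert len(simulate_ring_band(p, seed=2)) == 500

    def test_background_adds_records_over_field(self):
        p = RingSimParams(n_molecules=100, background_density=50.0,
                          field=(2000.0, 2000.0))
        table = simulate_ring_band(p, seed=3)
        assert len(table) > 100

    def test_deterministic_given_seed(self):
        p = RingSimParams()
        a = simulate_ring_band(p, seed=9)
        b = simulate_ring_band(p, seed=9)
        np.testing.assert_array_equal(a.x, b.x)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RingSimParams(diameter=-1.0)
        with pytest.raises(ValueError):
            RingSimParams(n_molecules=0)


class TestTwoColor:
    def test_pure_shift_gives_exact_pairwise_offset(self):
        p = TwoColorSimParams(
            base=RingSimParams(n_molecules=200, loc_precision=0.0),
            shift_y=97.0,
            registration_sd=0.0,
        )
        table = simulate_two_color(p, seed=0)
        ch1 = table.select_channel("ch1")
        ch2 = table.select_channel("ch2")
        np.testing.assert_allclose(ch2.y - ch1.y, 97.0, atol=1e-9)
        np.testing.assert_allclose(ch2.x, ch1.x, atol=1e-9)

    def test_no_shift_no_noise_channels_coincide(self):
        p = TwoColorSimParams(
            base=RingSimParams(n_molecules=100, loc_precision=0.0),
            shift_y=0.0,
            registration_sd=0.0,
        )
        table = simulate_two_color(p, seed=1)
        np.testing.assert_allclose(
            table.select_channel("ch2").y, table.select_channel("ch1").y, atol=1e-9
        )

    def test_detection_efficiency_binomial(self):
        p = TwoColorSimParams(
            base=RingSimParams(n_molecules=1000), detection_efficiency=0.5
        )
        table = simulate_two_color(p, seed=2)
        n2 = len(table.select_channel("ch2"))
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= n2 <= hi


class TestRadialClusters:
    def test_gaussian_radii_nonnegative(self):
        p = RadialSimParams(mu_r=100.0, sigma_r=200.0, n_clusters=20_000)
        df = simulate_radial_clusters(p, seed=0)
        assert df.r_nm.min() >= 0

    def test_gaussian_projection_mean_two_over_pi(self):
        # E|cos phi| = 2/pi for a uniform angle
        p = RadialSimParams(mu_r=280.0, sigma_r=120.0, n_clusters=100_000)
        df = simulate_radial_clusters(p, seed=1)
        expected = (2.0 / math.pi) * df.r_nm.mean()
        assert df.r_prime_nm.mean() == pytest.approx(expected, rel=0.02)

    def test_disk_mean_radius_closed_form(self):
        p = RadialSimParams(mode="disk", r_max=419.0, n_clusters=100_000)
        df = simulate_radial_clusters(p, seed=2)
        assert df.r_nm.mean() == pytest.approx(2 * 419.0 / 3, rel=0.01)

    def test_seed_stability_of_projected_distribution(self):
        # different seeds give statistically indistinguishable r' samples
        p = RadialSimParams(n_clusters=2000)
        reference = simulate_radial_clusters(p, seed=0).r_prime_nm
        for seed in range(1, 11):
            sample = simulate_radial_clusters(p, seed=seed).r_prime_nm
            assert stats.ks_2samp(reference, sample).pvalue > 0.01


class TestIpalmLayers:
    def test_noiseless_layer_mean_is_exact(self):
        table = simulate_ipalm_layers([(67.0, 1000)], z_precision=0.0, seed=0)
        layer = table.select_channel("layer0")
        assert np.mean(layer.z) == pytest.approx(67.0, abs=1e-12)

    def test_surface_fwhm_round_trip(self):
        from divlayers.ipalm import fit_surface_z

        table = simulate_ipalm_layers(
            [(117.0, 100)], surface_n=20_000, surface_fwhm=10.0, seed=1
        )
        _, fwhm = fit_surface_z(table.select_channel("surface"))
        assert fwhm == pytest.approx(10.0, rel=0.1)

    def test_total_record_count(self):
        table = simulate_ipalm_layers(
            [(67.0, 300), (117.0, 200)], surface_n=400, seed=2
        )
        assert len(table) == 300 + 200 + 400

    def test_empty_depths_rejected(self):
        with pytest.raises(ValueError):
            simulate_ipalm_layers([], seed=0)


class TestBeads:
    def test_identity_no_noise_pairs_coincide(self):
        df = simulate_beads(n_points=50, seed=0)
        np.testing.assert_allclose(df.x2, df.x1, atol=1e-12)

    def test_pure_translation(self):
        df = simulate_beads(offset=(50.0, -20.0), n_points=50, seed=1)
        np.testing.assert_allclose(df.x2 - df.x1, 50.0, atol=1e-12)
        np.testing.assert_allclose(df.y2 - df.y1, -20.0, atol=1e-12)

    def test_noise_rms_pair_distance(self):
        # two channels x two axes of sd-5 noise: rms pair distance 5 sqrt(2)...
        # per-axis difference has sd 5*sqrt(2); 2D rms distance = 10
        df = simulate_beads(n_points=5000, noise_sd=5.0, seed=2)
        rms = np.sqrt(np.mean((df.x2 - df.x1) ** 2 + (df.y2 - df.y1) ** 2))
        assert rms == pytest.approx(5.0 * 2.0, rel=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            simulate_beads(n_points=2)


class TestFrap:
    def test_halfway_point_at_halftime(self):
        p = FrapSimParams(halftime=20.0, noise_sd=0.0, n_traces=1)
        trace = simulate_frap(p, seed=0)[0]
        floor = 1.0 - p.bleach_depth
        # frame at t' = tau_1/2: index first_postbleach - 1 + tau/interval
        idx = (trace.first_postbleach - 1) + int(p.halftime / p.frame_interval)
        expected = floor + (p.plateau - floor) * 0.5
        assert trace.i_bleach[idx] == pytest.approx(expected, abs=1e-12)

    def test_default_timing_120_frames_4_min(self):
        p = FrapSimParams()
        trace = simulate_frap(p, seed=0)[0]
        assert trace.n_frames == 120
        assert (trace.n_frames - 1) * trace.frame_interval == pytest.approx(238.0)
        assert trace.n_frames * trace.frame_interval == pytest.approx(240.0)

    def test_noiseless_fit_self_consistency(self):
        from divlayers.frap import fit_halftime

        p = FrapSimParams(halftime=19.8, noise_sd=0.0, n_traces=3)
        fit = fit_halftime(simulate_frap(p, seed=0))
        assert fit.halftime == pytest.approx(19.8, abs=1e-3)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FrapSimParams(halftime=-1.0)
        with pytest.raises(ValueError):
            FrapSimParams(n_frames=2, bleach_frame=2)
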