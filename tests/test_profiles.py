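"""Cortex line profiles: extraction, resampling, averaging, polarization."""

import numpy as np
import pytest

from cortexkymo.profiles import (
    CortexProfile,
    average_profiles,
    cortex_trace,
    polarization_metrics,
    resample_profiles,
)
from cortexkymo.experiments import (
    polarization_recovery_experiment,
    tip_profile_experiment,
)
from cortexkymo.simulate import SimulationConfig, build_geometry, render_movie


def make_profile(values, region="daughter", cell_id=1, step=0.1):
    values = np.asarray(values, dtype=float)
    return CortexProfile(cell_id=cell_id, region=region,
                         arc_positions=np.arange(len(values)) * step, intensities=values)


@pytest.fixture(scope="module")
def diffuse_cell():
    # PSF sampled well above Nyquist (sigma = 5 px) so the band crest is
    # not aliased by the pixel grid and flatness is meaningful
    cfg = SimulationConfig(n_frames=1, diffuse_density=400.0, cytoplasm_density=40.0,
                           event_rate_daughter=0.0, event_rate_mother=0.0,
                           psf_sigma=0.4, pixel_size=0.08,
                           shot_noise=False, read_noise_sd=0.0)
    g = build_geometry(cfg)
    movie, _ = render_movie(g, [], cfg)
    return cfg, g, movie.data[0, 0]


class TestCortexTrace:
    def test_uniform_cortex_yields_flat_background_subtracted_profile(self, diffuse_cell):
        cfg, g, img = diffuse_cell
        prof = cortex_trace(img, g.boundary, "mother", cfg.pixel_size)
        # away from the neck (where the daughter band bleeds over), the cortex
        # value above the interior background is constant along the arc
        inner = prof.intensities[25:-25]
        assert np.ptp(inner) / np.median(inner) < 0.02

    def test_zero_image_gives_zero_profile(self, budded_geometry):
        g = budded_geometry
        img = np.zeros(g.mask.shape)
        prof = cortex_trace(img, g.boundary, "daughter", g.config.pixel_size)
        assert np.allclose(prof.intensities, 0.0)

    def test_absent_region_rejected(self):
        cfg = SimulationConfig(bud_radius=0.0, n_frames=1)
        g = build_geometry(cfg)
        img = np.zeros(g.mask.shape)
        with pytest.raises(ValueError):
            cortex_trace(img, g.boundary, "daughter", cfg.pixel_size)

    def test_tip_polarized_signal_peaks_mid_daughter_arc(self):
        cfg = SimulationConfig(n_frames=1, diffuse_density=400.0, diffuse_profile="tip",
                               diffuse_polarization=3.0, event_rate_daughter=0.0,
                               event_rate_mother=0.0, shot_noise=False, read_noise_sd=0.0)
        g = build_geometry(cfg)
        movie, _ = render_movie(g, [], cfg)
        prof = cortex_trace(movie.data[0, 0], g.boundary, "daughter", cfg.pixel_size)
        peak = np.argmax(prof.intensities) / (prof.n_samples - 1)
        assert 0.4 <= peak <= 0.6


class TestResampleProfiles:
    def test_target_length_is_the_mean_trace_length(self):
        profs = [make_profile(np.ones(n)) for n in (80, 100, 120)]
        assert resample_profiles(profs).shape == (3, 100)

    def test_profiles_already_at_target_length_are_unchanged(self):
        vals = np.sin(np.linspace(0, 3, 50))
        mat = resample_profiles([make_profile(vals), make_profile(vals[::-1])])
        assert np.allclose(mat[0], vals)
        assert np.allclose(mat[1], vals[::-1])

    @pytest.mark.parametrize("n_out_src", [(30, 77), (101, 40), (64, 64)])
    def test_linear_ramp_stays_linear_with_exact_endpoints(self, n_out_src):
        n_other, n_src = n_out_src
        ramp = np.linspace(-2.0, 7.0, n_src)
        mat = resample_profiles([make_profile(ramp), make_profile(np.zeros(n_other))])
        out = mat[0]
        assert out[0] == -2.0 and out[-1] == 7.0
        assert np.allclose(out, np.linspace(-2.0, 7.0, len(out)), atol=1e-12)

    def test_resampling_preserves_smooth_profile_mean(self):
        x = np.linspace(0, 1, 200)
        smooth = 5 + np.sin(2 * np.pi * x)
        mat = resample_profiles([make_profile(smooth), make_profile(np.zeros(120))])
        assert mat[0].mean() == pytest.approx(smooth.mean(), rel=0.01)

    def test_mixed_regions_rejected(self):
        with pytest.raises(ValueError):
            resample_profiles([make_profile([1, 2]), make_profile([1, 2], region="mother")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resample_profiles([])


class TestAverageProfiles:
    def test_identical_profiles_have_zero_width_band(self):
        mat = np.tile(np.linspace(0, 1, 30), (4, 1))
        band = average_profiles(mat)
        assert np.allclose(band.mean, mat[0])
        assert np.allclose(band.ci_halfwidth, 0.0)

    def test_two_constant_profiles_average_to_their_midpoint(self):
        band = average_profiles(np.vstack([np.ones(20), 3 * np.ones(20)]))
        assert np.allclose(band.mean, 2.0)

    def test_single_profile_flags_undefined_interval(self):
        band = average_profiles(np.ones((1, 10)))
        assert not band.ci_defined
        assert np.all(np.isnan(band.ci_halfwidth))

    def test_averaging_is_permutation_invariant(self, rng):
        mat = rng.normal(size=(8, 25))
        perm = rng.permutation(8)
        a, b = average_profiles(mat), average_profiles(mat[perm])
        assert np.allclose(a.mean, b.mean)
        assert np.allclose(a.ci_halfwidth, b.ci_halfwidth)

    def test_confidence_band_covers_the_true_mean(self, rng):
        # 35 noisy profiles per replicate; t-band should cover ~95% per position
        true = 10 + np.sin(np.linspace(0, 2 * np.pi, 40))
        n_reps, covered, total = 200, 0, 0
        for _ in range(n_reps):
            mat = true + rng.normal(0, 1.5, size=(35, 40))
            band = average_profiles(mat)
            covered += int(np.sum(np.abs(band.mean - true) <= band.ci_halfwidth))
            total += 40
        assert covered / total >= 0.93


class TestPolarization:
    def test_ratio_of_given_means(self):
        d = [make_profile(10 * np.ones(30), "daughter", cell_id=i) for i in range(3)]
        m = [make_profile(2 * np.ones(40), "mother", cell_id=i) for i in range(3)]
        table, ratio = polarization_metrics(d, m)
        assert ratio == pytest.approx(5.0)
        assert len(table) == 6

    def test_non_positive_mother_mean_yields_nan_not_infinity(self):
        d = [make_profile(np.ones(10), "daughter")]
        m = [make_profile(np.zeros(10), "mother")]
        _, ratio = polarization_metrics(d, m)
        assert np.isnan(ratio)

    def test_symmetric_signal_gives_unit_ratio(self):
        res = polarization_recovery_experiment(seed=3, pol_values=(1.0,), n_cells=8)
        assert res["recovered_ratios"][0] == pytest.approx(1.0, abs=0.1)

    def test_recovered_ratio_tracks_simulated_polarization(self):
        res = polarization_recovery_experiment(seed=2, pol_values=(1.0, 2.0, 5.0), n_cells=12)
        r = res["recovered_ratios"]
        assert r[0] < r[1] < r[2]
        assert r[2] == pytest.approx(5.0, rel=0.2)

    def test_tip_polarized_average_profile_is_unimodal_at_the_tip(self):
        res = tip_profile_experiment(seed=2, n_cells=10)
        assert 0.4 <= res["peak_rel_position"] <= 0.6
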