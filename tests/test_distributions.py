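"""Population analytics: KDE summaries, mixtures, overlap model, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organelle_stoich import (
    CellGeometry,
    EstimationError,
    ParameterError,
    calibrate,
    compare_conditions,
    confocal_foci_intensities,
    cytosolic_background_correct,
    fit_triple_gaussian,
    functional_units,
    grouped_sampling_error,
    kde_estimate,
    overlap_fraction,
    proportion_percent,
    subtract_background_distribution,
)
from organelle_stoich.distributions import significance_stars


class TestKDE:
    def test_gaussian_peak_and_hwhm(self):
        """Peak within 1 of the mean; HWHM within 5% of 1.177 sigma.

        An oversmoothed kernel (0.4 sigma) is used for mode location: the KDE
        mode of a symmetric density is unbiased, and a wide kernel suppresses
        the argmax jitter of a flat-topped density."""
        v = np.random.default_rng(2).normal(100, 20, 10_000)
        d = kde_estimate(v, kernel_width=8.0)
        assert d.peak == pytest.approx(100.0, abs=1.0)
        d2 = kde_estimate(v, kernel_width="standard")
        assert d2.hwhm == pytest.approx(1.177 * 20, rel=0.05)

    def test_identical_values_peak_at_value(self):
        d = kde_estimate(np.full(100, 37.0), kernel_width=0.5)
        assert d.peak == pytest.approx(37.0, abs=0.01)
        assert d.hwhm == pytest.approx(1.177 * 0.5, rel=0.05)  # kernel-limited width

    def test_pentamer_multiples_resolved_with_half_molecule_kernel(self):
        """Mass at multiples of 5 with a 0.5-molecule kernel shows maxima at ~5k."""
        rng = np.random.default_rng(3)
        mult = rng.integers(1, 9, 400) * 5
        v = mult + rng.normal(0, 0.4, 400)
        d = kde_estimate(v, kernel_width=0.5)
        maxima = d.local_maxima(min_height_fraction=0.1)
        assert len(maxima) >= 4
        offsets = np.abs(maxima / 5.0 - np.round(maxima / 5.0)) * 5.0
        assert np.all(offsets < 1.0)

    def test_small_samples_refused(self):
        with pytest.raises(EstimationError):
            kde_estimate(np.arange(5.0))


class TestBackgroundSubtraction:
    def test_self_subtraction_vanishes(self):
        v = np.random.default_rng(0).normal(12, 6, 3000)
        d = kde_estimate(v, kernel_width=1.0)
        corr = subtract_background_distribution(d, d, background_rate=1.0)
        assert np.all(corr.density <= 1e-6 * d.density.max() + 1e-12)

    def test_known_mixture_recovers_signal_peak(self):
        """70% N(37,8) + 30% background N(12,6): corrected peak within 2 of 37."""
        rng = np.random.default_rng(1)
        mix = np.concatenate([rng.normal(37, 8, 1400), rng.normal(12, 6, 600)])
        bg = rng.normal(12, 6, 5000)
        corr = subtract_background_distribution(
            kde_estimate(mix, kernel_width=2.0), kde_estimate(bg, kernel_width=2.0),
            background_rate=0.3,
        )
        assert corr.peak == pytest.approx(37.0, abs=2.0)

    def test_distant_background_leaves_peak_unaffected(self):
        """When the signal peak is far from the background peak, the correction
        moves it by < 1%."""
        rng = np.random.default_rng(2)
        sig = rng.normal(314, 40, 2000)
        bg = rng.normal(12, 6, 3000)
        d = kde_estimate(sig, kernel_width="standard")
        corr = subtract_background_distribution(d, kde_estimate(bg, kernel_width="standard"),
                                                background_rate=0.2)
        assert abs(corr.peak - d.peak) < 0.01 * d.peak

    def test_invalid_rate_rejected(self):
        v = np.random.default_rng(0).normal(10, 2, 100)
        d = kde_estimate(v)
        with pytest.raises(ParameterError):
            subtract_background_distribution(d, d, background_rate=1.5)


class TestFunctionalUnits:
    def test_pentamer_and_rubisco_arithmetic(self):
        assert functional_units(37, 5) == pytest.approx(7.4)
        assert round(functional_units(6822, 8)) == 853
        assert round(functional_units(12057, 8)) == 1507
        assert functional_units(0, 6) == 0.0

    @given(st.floats(0.1, 100.0), st.floats(0, 1e4), st.integers(1, 12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_linearity(self, a, x, m):
        assert functional_units(a * x, m) == pytest.approx(a * functional_units(x, m))

    def test_zero_oligomer_rejected(self):
        with pytest.raises(ParameterError):
            functional_units(10, 0)

    def test_proportion_percent(self):
        assert proportion_percent(16, 27) == 59
        assert proportion_percent(3, 33) == 9
        assert proportion_percent(4, 51) == 8


class TestTripleGaussian:
    def test_three_component_recovery(self):
        """Means within 5%, area fractions within 0.05, on a 2000-draw mixture."""
        rng = np.random.default_rng(4)
        v = np.concatenate([
            rng.normal(35, 8, 1200), rng.normal(60, 6, 400), rng.normal(95, 10, 400)
        ])
        fit = fit_triple_gaussian(kde_estimate(v, kernel_width=2.0))
        assert np.allclose(fit.means, [35, 60, 95], rtol=0.05)
        assert np.allclose(fit.fractions, [0.6, 0.2, 0.2], atol=0.05)

    def test_pure_gaussian_concentrates_in_one_component(self):
        v = np.random.default_rng(5).normal(50, 7, 2000)
        fit = fit_triple_gaussian(kde_estimate(v, kernel_width=2.0),
                                  initial_means=[40, 50, 60])
        assert fit.fractions.max() >= 0.95

    def test_seeding_at_known_population_means(self):
        """Seeds at the three capping populations (~35, 60, ~95 subunits)."""
        rng = np.random.default_rng(6)
        v = np.concatenate([
            rng.normal(35, 6, 1500), rng.normal(60, 5, 350), rng.normal(96, 8, 150)
        ])
        fit = fit_triple_gaussian(kde_estimate(v, kernel_width=2.0),
                                  initial_means=[35, 60, 96])
        assert 32 <= fit.means[0] <= 38
        assert 57 <= fit.means[1] <= 63
        assert 91 <= fit.means[2] <= 102


class TestOverlapModel:
    def test_single_focus_never_overlaps(self):
        m = overlap_fraction(1, CellGeometry(3.0, 0.5), 250.0)
        assert m.overlap_fraction == 0.0

    @pytest.mark.parametrize("n", [2, 5, 10, 20])
    def test_analytic_matches_montecarlo(self, n):
        geo = CellGeometry(3.0, 0.5)
        ana = overlap_fraction(n, geo, 250.0, mode="analytic")
        mc = overlap_fraction(n, geo, 250.0, mode="montecarlo",
                              n_placements=30_000, rng_seed=n)
        assert abs(ana.overlap_fraction - mc.overlap_fraction) <= 3 * mc.mc_sd

    def test_overlap_increases_with_density(self):
        geo = CellGeometry(3.0, 0.5)
        fr = [overlap_fraction(n, geo, 250.0).overlap_fraction for n in (2, 5, 10)]
        assert fr[0] < fr[1] < fr[2]

    def test_pair_distribution_doubles_singles_peak(self):
        """Random overlap of two single organelles peaks near twice the singles peak."""
        v = np.random.default_rng(7).normal(35, 5, 2000)
        singles = kde_estimate(v, kernel_width=2.0)
        m = overlap_fraction(5, CellGeometry(3.0, 0.5), 250.0, singles=singles)
        grid2, dens2 = m.pair_distribution
        assert grid2[np.argmax(dens2)] == pytest.approx(70.0, abs=3.0)


class TestConfocalPhotometry:
    def test_flat_image_yields_no_maxima(self):
        assert confocal_foci_intensities(np.full((50, 50), 9.0), 5.0).size == 0

    def test_five_foci_rank_order_preserved(self):
        rr, cc = np.mgrid[0:60, 0:60]
        amps = [100, 150, 200, 250, 300]
        spots = [(10, 10), (20, 40), (40, 20), (45, 45), (30, 30)]
        img = np.full((60, 60), 50.0)
        for (r, c), a in zip(spots, amps):
            img += a * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / 8.0)
        peaks = confocal_foci_intensities(img, noise_tolerance=20.0)
        assert len(peaks) == 5
        assert np.allclose(np.sort(peaks), np.array(amps) + 50.0, rtol=0.01)

    def test_twin_peaks_within_resolution_merge(self):
        rr, cc = np.mgrid[0:40, 0:40]
        img = (100 * np.exp(-((rr - 20) ** 2 + (cc - 18) ** 2) / 8.0)
               + 95 * np.exp(-((rr - 20) ** 2 + (cc - 22) ** 2) / 8.0))
        assert len(confocal_foci_intensities(img, noise_tolerance=30.0)) == 1

    def test_saturated_foci_excluded(self):
        rr, cc = np.mgrid[0:40, 0:40]
        img = 100 * np.exp(-((rr - 10) ** 2 + (cc - 10) ** 2) / 8.0)
        img += 5000 * np.exp(-((rr - 30) ** 2 + (cc - 30) ** 2) / 8.0)
        img = np.minimum(img, 4095.0)  # 12-bit saturation
        peaks = confocal_foci_intensities(img, noise_tolerance=30.0, saturation_level=4095.0)
        assert len(peaks) == 1 and peaks[0] < 200


class TestCytosolicCorrection:
    def test_zero_cytosol_leaves_intensities(self):
        corrected, bg, flags = cytosolic_background_correct(
            [100.0, 200.0], np.zeros(50)
        )
        assert bg == 0.0 and np.allclose(corrected, [100, 200])

    def test_constant_cytosol_removed(self):
        rng = np.random.default_rng(0)
        profile = 40.0 + rng.normal(0, 1, 100)
        profile[45:55] += 300.0  # the focus region on the central line
        corrected, bg, _ = cytosolic_background_correct([340.0, 360.0], profile)
        assert bg == pytest.approx(40.0, abs=1.0)
        assert np.allclose(corrected, [300.0, 320.0], atol=2.0)

    def test_focus_dimmer_than_cytosol_clipped_and_flagged(self):
        corrected, bg, flags = cytosolic_background_correct(
            [30.0], np.full(50, 50.0), focus_mask=np.zeros(50, dtype=bool)
        )
        assert corrected[0] == 0.0 and any("clipped" in f for f in flags)


class TestCalibration:
    def test_factor_arithmetic(self):
        cal = calibrate(confocal_peak=500.0, slimfield_peak=37.0)
        assert cal.factor == pytest.approx(0.074)
        assert cal.apply(1000.0) == pytest.approx(74.0)

    def test_round_trip_reproduces_slimfield_peak(self):
        cal = calibrate(confocal_peak=812.0, slimfield_peak=37.0)
        assert cal.apply(812.0) == pytest.approx(37.0, rel=1e-12)

    def test_strain_mismatch_refused(self):
        with pytest.raises(ParameterError):
            calibrate(500.0, 37.0, strain_confocal="ccmK4", strain_slimfield="ccmL")

    def test_doubled_copies_give_doubled_calibrated_peak(self):
        """Scaling true copies x2 at fixed optics doubles the calibrated peak."""
        rng = np.random.default_rng(1)
        gain = 13.7  # arbitrary intensity units per molecule
        copies_ref = rng.normal(37, 5, 2000)
        intens_ref = copies_ref * gain + rng.normal(0, 20, 2000)
        intens_2x = 2 * copies_ref * gain + rng.normal(0, 20, 2000)
        peak_ref = kde_estimate(intens_ref, kernel_width=30.0).peak
        peak_2x = kde_estimate(intens_2x, kernel_width=30.0).peak
        cal = calibrate(confocal_peak=peak_ref, slimfield_peak=37.0)
        assert cal.apply(peak_2x) / cal.apply(peak_ref) == pytest.approx(2.0, rel=0.05)


class TestConditionComparison:
    def test_identical_samples_not_significant(self):
        v = np.random.default_rng(0).normal(100, 20, 400)
        c = compare_conditions(v, v.copy())
        assert c.p_value > 0.05 and c.fold_change == pytest.approx(1.0)
        assert c.stars == "ns"

    def test_thirty_percent_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(100, 20, 500)
        c = compare_conditions(a * 1.3, a)
        assert c.p_value < 0.005 and c.stars == "***"
        assert c.fold_change == pytest.approx(1.3, rel=0.05)

    def test_mann_whitney_agrees_with_permutation_oracle(self):
        """Two-sided MW p matches a rank-sum permutation p within MC error."""
        from scipy.stats import rankdata

        rng = np.random.default_rng(2)
        a = rng.normal(100, 20, 60)
        b = rng.normal(108, 20, 60)
        c = compare_conditions(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 4000
        obs = rankdata(pooled)[: len(a)].sum()
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            stat = rankdata(perm)[: len(a)].sum()
            if abs(stat - len(a) * (len(pooled) + 1) / 2) >= abs(obs - len(a) * (len(pooled) + 1) / 2):
                exceed += 1
        p_perm = exceed / n_perm
        mc_sd = np.sqrt(max(p_perm, 1e-4) * (1 - min(p_perm, 1 - 1e-4)) / n_perm)
        assert abs(c.p_value - p_perm) <= 4 * mc_sd + 0.005

    def test_significance_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "***"
        assert significance_stars(0.2) == "ns"

    def test_all_tie_samples_warn(self):
        with pytest.warns(UserWarning):
            c = compare_conditions(np.full(10, 5.0), np.full(10, 5.0))
        assert c.p_value == 1.0


class TestGroupedSamplingError:
    def test_constant_data_has_zero_error(self):
        g = grouped_sampling_error(np.full(500, 37.0), group_size=100, rng_seed=0,
                                   kernel_width=0.5)
        assert g.relative_error == 0.0 and not g.exceeds_5_percent

    def test_normal_sample_error_scales_like_standard_error(self):
        """Relative peak error is within 2x of sd/(mean sqrt(group_size))."""
        v = np.random.default_rng(3).normal(100, 20, 1000)
        g = grouped_sampling_error(v, group_size=100, n_resamples=10, rng_seed=1)
        bound = 20.0 / (100.0 * np.sqrt(100))
        assert g.relative_error < 2 * 2 * bound  # KDE mode is noisier than the mean

    def test_small_sample_refused_with_required_n(self):
        with pytest.raises(EstimationError, match="need n >="):
            grouped_sampling_error(np.arange(50.0), group_size=70)

    def test_error_flag_above_5_percent(self):
        v = np.random.default_rng(4).lognormal(3, 1.5, 200)
        g = grouped_sampling_error(v, group_size=70, n_resamples=10, rng_seed=2)
        assert g.exceeds_5_percent == (g.relative_error > 0.05)
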