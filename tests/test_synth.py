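import numpy as np
import pytest
from dataclasses import replace

import marshphen as mp
from marshphen import synth, timeseries
from marshphen.indices import compute_vi


class TestObservationDates:
    def test_zero_retention_excludes_gap_window(self):
        regime = synth.ClimateRegime("continental", (335, 59), 0.0)
        days = synth.sample_observation_dates(regime, 73, seed=1)
        assert not regime.in_gap(days).any()  # no Dec-Feb day survives

    def test_full_retention_keeps_nominal_calendar(self):
        regime = synth.ClimateRegime("continental", (335, 59), 1.0)
        days = synth.sample_observation_dates(regime, 73, seed=1)
        assert len(days) == 73
        assert np.all(np.diff(days) == 5.0)

    def test_strictly_increasing_within_year(self):
        days = synth.sample_observation_dates(synth.MONSOONAL, 80, seed=3)
        assert np.all(np.diff(days) > 0)
        assert days.min() >= 1 and days.max() <= 365

    def test_thinning_probability_converges(self):
        """Monte-Carlo: mean retained in-window fraction ~= gap_retention."""
        regime = synth.ClimateRegime("monsoonal", (152, 243), 0.3)
        nominal = 3.0 + 5.0 * np.arange(73)
        n_window = int(regime.in_gap(nominal).sum())
        fracs = [regime.in_gap(synth.sample_observation_dates(regime, 73, seed=s)).sum()
                 / n_window for s in range(1000)]
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.05)


class TestTrueCurve:
    def test_dormant_value_is_base_level(self, template):
        assert synth.true_curve_value(template, 1) == pytest.approx(
            template.base_level, abs=1e-3)

    def test_peak_value_approaches_base_plus_amplitude(self, template):
        v = synth.true_curve_value(template, template.peak_day)
        assert v == pytest.approx(template.base_level + template.amplitude,
                                  rel=0.05)

    def test_positive_shift_raises_senescence_values(self, template):
        lagged = replace(template, cycle_shift=20.0)
        day = template.peak_day + template.senescence_width  # senescence limb
        assert synth.true_curve_value(lagged, day) > synth.true_curve_value(template, day)

    def test_day_domain_enforced(self, template):
        with pytest.raises(ValueError):
            synth.true_curve_value(template, 366)


class TestSimulateObservations:
    def test_inverse_construction_identity(self, template):
        """With all noise off, NDVI recomputed from the bands reproduces the
        template curve at every date to float precision."""
        dates = synth.sample_observation_dates(synth.CONTINENTAL, 73, seed=5)
        s = synth.simulate_observations(template, dates, synth.NoiseConfig(seed=0))
        v = compute_vi(s.blue, s.green, s.red, s.nir, "NDVI")
        assert np.abs(v - synth.true_curve_value(template, dates)).max() < 1e-12

    def test_tide_event_depresses_ndvi(self, template):
        dates = np.array([200.0])
        clean = synth.simulate_observations(template, dates, synth.NoiseConfig(seed=1))
        flooded = synth.simulate_observations(
            template, dates,
            synth.NoiseConfig(tide_event_rate=1.0, tide_nir_attenuation=0.5, seed=1))
        ndvi = lambda s: compute_vi(s.blue, s.green, s.red, s.nir, "NDVI")[0]
        assert ndvi(flooded) < ndvi(clean)

    def test_cloud_event_perturbs_evi_more_than_ndvi(self, template):
        """Omitted clouds hit blue/green; EVI amplifies blue via its 7.5x
        coefficient while NDVI ignores it entirely."""
        dates = np.array([200.0])
        clean = synth.simulate_observations(template, dates, synth.NoiseConfig(seed=1))
        cloudy = synth.simulate_observations(
            template, dates,
            synth.NoiseConfig(cloud_omission_rate=1.0, bluegreen_perturbation=0.08,
                              seed=1))
        def dev(vi):
            a = compute_vi(clean.blue, clean.green, clean.red, clean.nir, vi)[0]
            b = compute_vi(cloudy.blue, cloudy.green, cloudy.red, cloudy.nir, vi)[0]
            return abs(a - b)
        assert dev("EVI") > dev("NDVI")

    def test_cloud_events_keep_clear_sc_codes(self, template):
        """Omitted clouds are by definition not flagged in the SC band."""
        dates = np.arange(3.0, 364.0, 5.0)
        s = synth.simulate_observations(
            template, dates,
            synth.NoiseConfig(cloud_omission_rate=1.0, seed=2))
        assert set(np.unique(s.sc_codes)) <= {4, 5}

    def test_reflectances_in_unit_interval(self, template):
        dates = np.arange(3.0, 364.0, 5.0)
        s = synth.simulate_observations(
            template, dates, replace(synth.DEFAULT_NOISE, gaussian_sigma=0.05, seed=7))
        for b in (s.blue, s.green, s.red, s.nir):
            assert b.min() >= 0.0 and b.max() <= 1.0


class TestScCodes:
    @pytest.mark.parametrize("rate,allowed", [
        (0.0, {4, 5}), (1.0, {3, 8, 9, 10, 11}),
    ])
    def test_rate_extremes(self, rate, allowed):
        codes = synth.simulate_sc_codes(np.arange(100.0), rate, seed=0)
        assert set(np.unique(codes)) <= allowed

    def test_flagged_fraction_binomial(self):
        codes = synth.simulate_sc_codes(np.arange(10000.0), 0.2, seed=1)
        frac = np.isin(codes, (3, 8, 9, 10, 11)).mean()
        assert frac == pytest.approx(0.2, abs=0.01)


class TestSampleSet:
    def test_cardinality_and_labels(self, template):
        other = replace(template, class_name="other", peak_day=180)
        samples = synth.generate_sample_set([template, other], 5,
                                            synth.CONTINENTAL,
                                            synth.NoiseConfig(), seed=1)
        assert len(samples) == 10
        assert sorted({s.class_name for s in samples}) == ["other", "veg"]

    def test_seeded_determinism(self, template):
        other = replace(template, class_name="other")
        kw = dict(n_per_class=3, regime=synth.CONTINENTAL,
                  noise=synth.DEFAULT_NOISE, seed=9)
        a = synth.generate_sample_set([template, other], **kw)
        b = synth.generate_sample_set([template, other], **kw)
        assert synth.samples_to_frame(a).equals(synth.samples_to_frame(b))
        assert synth.labels_to_frame(a).equals(synth.labels_to_frame(b))

    def test_duplicate_class_names_rejected(self, template):
        with pytest.raises(ValueError, match="duplicate"):
            synth.generate_sample_set([template, template], 2,
                                      synth.CONTINENTAL, synth.NoiseConfig())

    def test_class_mean_peak_ordering_matches_templates(self):
        """Averaged simulated series preserve the template peak ordering."""
        quiet = synth.NoiseConfig(gaussian_sigma=0.005, seed=0)
        samples = synth.generate_sample_set(synth.DEFAULT_CLASSES, 8,
                                            synth.CONTINENTAL, quiet, seed=4)
        peaks = {}
        for s in samples:
            v = compute_vi(s.series.blue, s.series.green, s.series.red,
                           s.series.nir, "NDVI")
            peaks.setdefault(s.class_name, []).append(v.max())
        observed = sorted(peaks, key=lambda c: np.mean(peaks[c]))
        expected = sorted([t.class_name for t in synth.DEFAULT_CLASSES],
                          key=lambda n: next(t.base_level + t.amplitude
                                             for t in synth.DEFAULT_CLASSES
                                             if t.class_name == n))
        assert observed == expected


def test_template_validation():
    with pytest.raises(ValueError):
        synth.PhenologyTemplate("x", 0.1, -0.5, 200, 50, 50)
    with pytest.raises(ValueError):
        synth.PhenologyTemplate("x", 0.1, 0.5, 400, 50, 50)
    with pytest.raises(ValueError):
        synth.NoiseConfig(tide_event_rate=1.5)
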