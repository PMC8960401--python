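"""The generator must plant exactly the structure it reports as ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from meanet import (
    EIMapEndpoints,
    SyntheticNetworkSpec,
    ei_spec,
    generate_ei_series,
    generate_psc_events,
    generate_raw_trace,
    generate_well,
)
from meanet.synthetic import default_spike_template


class TestGenerateWell:
    def test_silent_spec_yields_zero_spikes(self):
        spec = SyntheticNetworkSpec(tonic_rate_hz=0.0, nb_rate_per_min=0.0, seed=3)
        well, gt = generate_well(spec)
        assert well.total_spikes() == 0
        assert gt.n_windows == 0

    def test_window_count_matches_renewal_expectation(self):
        # renewal: exponential gaps at 10/min plus ~0.5 s gamma durations
        spec = SyntheticNetworkSpec(
            duration_s=600.0, nb_rate_per_min=10.0, nb_duration_ms=500.0,
            nb_duration_cv=0.2, seed=11,
        )
        _, gt = generate_well(spec)
        mean_cycle = 6.0 + 0.5
        expected = 600.0 / mean_cycle
        var_cycle = 6.0**2 + (0.2 * 0.5) ** 2
        sd = np.sqrt(600.0 * var_cycle / mean_cycle**3)
        assert abs(gt.n_windows - expected) <= 3 * sd

    def test_deterministic_given_seed(self, small_spec):
        w1, g1 = generate_well(small_spec)
        w2, g2 = generate_well(small_spec)
        assert w1.channel_ids == w2.channel_ids
        for ch in w1.channel_ids:
            np.testing.assert_array_equal(w1.trains[ch], w2.trains[ch])
            np.testing.assert_array_equal(g1.in_burst[ch], g2.in_burst[ch])

    def test_adding_channels_preserves_existing_streams(self, small_spec):
        w1, _ = generate_well(small_spec)
        w2, _ = generate_well(dataclasses.replace(small_spec, n_channels=12))
        for ch in w1.channel_ids:
            np.testing.assert_array_equal(w1.trains[ch], w2.trains[ch])

    def test_planted_spikes_inside_duration_and_windows(self, small_spec):
        well, gt = generate_well(small_spec)
        intervals = list(zip(gt.windows["start_s"], gt.windows["end_s"]))
        for ch in well.channel_ids:
            t = well.trains[ch]
            assert np.all((t >= 0) & (t <= well.duration_s))
            burst_times = t[gt.in_burst[ch]]
            for bt in burst_times:
                assert any(s <= bt <= e for s, e in intervals)

    def test_tonic_rate_within_three_poisson_sd(self, small_spec):
        well, gt = generate_well(small_spec)
        windows = list(zip(gt.windows["start_s"], gt.windows["end_s"]))
        burst_time = sum(e - s for s, e in windows)
        non_burst = well.duration_s - burst_time
        for ch in well.channel_ids:
            t = well.trains[ch]
            outside = sum(
                1 for x in t if not any(s <= x <= e for s, e in windows)
            )
            lam = small_spec.tonic_rate_hz * non_burst
            assert abs(outside - lam) <= 3 * np.sqrt(max(lam, 1.0))

    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_channels", 0),
            ("duration_s", -1.0),
            ("tonic_rate_hz", -0.1),
            ("participation_frac", 0.0),
            ("participation_frac", 1.5),
            ("nb_duration_cv", -0.2),
            ("inhibitory_fraction", 0.5),
        ],
    )
    def test_invalid_spec_rejected_naming_field(self, field, value):
        spec = dataclasses.replace(SyntheticNetworkSpec(), **{field: value})
        with pytest.raises(ValueError, match=field):
            generate_well(spec)

    def test_rejects_specs_with_unidentifiable_gaps(self):
        # 10 bursts/min of 5.9 s leaves a 0.1-s mean gap: below the floor
        spec = SyntheticNetworkSpec(nb_rate_per_min=10.0, nb_duration_ms=5900.0)
        with pytest.raises(ValueError, match="gap"):
            generate_well(spec)


class TestEISeries:
    def test_planted_trends_monotone(self, small_spec):
        series = generate_ei_series(small_spec, [0.0, 0.05, 0.25, 0.35])
        assert len(series) == 4
        nbd = [gt.spec.nb_duration_ms for _, gt in series]
        in_rate = [gt.spec.in_burst_rate_hz for _, gt in series]
        tonic = [gt.spec.tonic_rate_hz for _, gt in series]
        assert all(b < a for a, b in zip(nbd, nbd[1:]))
        assert all(b < a for a, b in zip(in_rate, in_rate[1:]))
        assert all(b > a for a, b in zip(tonic, tonic[1:]))

    def test_endpoint_specs_match_configured_endpoints(self, small_spec):
        ep = EIMapEndpoints()
        lo = ei_spec(small_spec, 0.0, ep)
        hi = ei_spec(small_spec, 0.35, ep)
        assert lo.nb_duration_ms == ep.nbd_ms_at_0
        assert hi.nb_duration_ms == ep.nbd_ms_at_max
        assert hi.tonic_rate_hz == ep.tonic_hz_at_max
        # untouched fields copied from base
        assert hi.n_channels == small_spec.n_channels
        assert hi.onset_jitter_ms == small_spec.onset_jitter_ms

    def test_empty_fraction_list(self, small_spec):
        assert generate_ei_series(small_spec, []) == []

    def test_fraction_out_of_range_rejected(self, small_spec):
        with pytest.raises(ValueError):
            ei_spec(small_spec, 0.6)
        with pytest.raises(ValueError):
            generate_ei_series(small_spec, [-0.1, 0.2])

    def test_unsorted_fractions_rejected(self, small_spec):
        with pytest.raises(ValueError, match="ascending"):
            generate_ei_series(small_spec, [0.2, 0.1])


class TestRawTrace:
    def test_noise_sd_recovered(self):
        trace = generate_raw_trace(
            [], default_spike_template(), noise_sd=1.0,
            duration_s=600.0, seed=5,
        )
        assert abs(np.std(trace.samples) - 1.0) < 0.02

    def test_noiseless_trace_equals_template_at_offset(self):
        tmpl = default_spike_template(amplitude=4.0)
        trace = generate_raw_trace(
            [1.0], tmpl, noise_sd=0.0, duration_s=2.0, seed=0
        )
        peak_idx = int(np.argmax(np.abs(trace.samples)))
        assert abs(peak_idx / 10_000.0 - 1.0) < 1e-3
        lo = peak_idx - int(np.argmax(np.abs(tmpl)))
        np.testing.assert_allclose(trace.samples[lo : lo + len(tmpl)], tmpl)
        rest = np.delete(trace.samples, np.arange(lo, lo + len(tmpl)))
        assert np.all(rest == 0)

    def test_planted_peaks_exceed_detection_threshold(self):
        noise_sd = 2.0
        tmpl = default_spike_template(amplitude=8 * noise_sd)
        times = np.arange(100) * 0.05 + 0.01
        trace = generate_raw_trace(
            times, tmpl, noise_sd=noise_sd, duration_s=5.1, seed=2
        )
        idx = np.round(times * 10_000).astype(int)
        assert np.all(np.abs(trace.samples[idx]) > 4.5 * noise_sd)

    def test_overlapping_templates_warn(self):
        tmpl = default_spike_template()
        with pytest.warns(UserWarning, match="overlap"):
            generate_raw_trace([0.5, 0.50005], tmpl, noise_sd=0.0, duration_s=1.0)


class TestPSCEvents:
    def test_single_population_labels(self):
        df = generate_psc_events(0, 50, seed=1)
        assert (df["true_class"] == "GABAergic").all()

    def test_tail_fraction_matches_truncated_normal(self):
        df = generate_psc_events(10_000, 0, glu_decay_ms=(2.0, 0.5), seed=9)
        frac = float((df["decay_ms"] > 3.8).mean())
        a = (0.0 - 2.0) / 0.5
        expected = stats.truncnorm.sf(3.8, a, np.inf, loc=2.0, scale=0.5)
        assert abs(frac - expected) < 0.01

    def test_deterministic_given_seed(self):
        d1 = generate_psc_events(100, 100, seed=4)
        d2 = generate_psc_events(100, 100, seed=4)
        assert d1.equals(d2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_psc_events(-1, 10)
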