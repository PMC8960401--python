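"""Feature definitions, burst shapes, and the Holm-Sidak bin comparison."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meanet import (
    Burst,
    NetworkBurst,
    burst_shape,
    compare_shapes,
    compute_features,
    detect_well,
    generate_well,
    holm_sidak,
)

from oracles import holm_sidak_bruteforce


class TestComputeFeatures:
    def test_tonic_only_well(self, well_factory):
        well = well_factory({"a": np.linspace(0.5, 599.5, 600)}, duration_s=600.0)
        f = compute_features(well, {"a": []}, [])
        assert f.mfr_hz == pytest.approx(1.0)
        assert f.prs_pct == pytest.approx(100.0)
        assert f.nbr_per_min == 0.0
        assert math.isnan(f.nbd_ms) and math.isnan(f.nibi_s)

    def test_prs_definition_arithmetic(self, well_factory):
        # 100 spikes, 80 inside a burst window: PRS = 20%
        in_burst = np.linspace(10.0, 10.79, 80)
        random = np.linspace(100.0, 500.0, 20)
        well = well_factory({"a": np.sort(np.concatenate([in_burst, random]))})
        bursts = {"a": [Burst("a", 10.0, 10.79, 80)]}
        f = compute_features(well, bursts, [])
        assert f.prs_pct == pytest.approx(20.0)

    def test_prs_complement_identity(self, small_spec):
        well, _ = generate_well(small_spec)
        bursts, nbs = detect_well(well)
        f = compute_features(well, bursts, nbs)
        non_random_pct = 100.0 - f.prs_pct
        assert f.prs_pct + non_random_pct == pytest.approx(100.0)
        assert 0.0 <= f.prs_pct <= 100.0

    def test_network_burst_rate_and_duration(self, well_factory):
        # 50 constructed 400-ms network bursts in 10 min: NBR 5/min, NBD 400 ms
        well = well_factory({"a": np.linspace(1, 599, 300)})
        nbs = [
            NetworkBurst(10.0 * i, 10.0 * i + 0.4, frozenset({"a"}), 10)
            for i in range(50)
        ]
        f = compute_features(well, {"a": []}, nbs)
        assert f.nbr_per_min == pytest.approx(5.0)
        assert f.nbd_ms == pytest.approx(400.0)
        assert f.nibi_s == pytest.approx(9.6)

    def test_empty_well_flagged_missing(self, well_factory):
        well = well_factory({"a": []}, duration_s=600.0)
        f = compute_features(well, {"a": []}, [])
        assert all(math.isnan(getattr(f, k)) for k in f.PARAMETERS)

    def test_prs_scope_flag(self, well_factory):
        # a spike on channel b inside a network-burst window but not in a
        # burst of its own is random only under the own-burst reading
        well = well_factory(
            {"a": np.linspace(10.0, 10.5, 60), "b": np.array([10.2, 300.0])}
        )
        bursts = {"a": [Burst("a", 10.0, 10.5, 60)], "b": []}
        nbs = [NetworkBurst(10.0, 10.5, frozenset({"a"}), 61)]
        inclusive = compute_features(well, bursts, nbs, prs_scope="burst_or_network")
        own_only = compute_features(well, bursts, nbs, prs_scope="own_burst")
        assert inclusive.prs_pct < own_only.prs_pct


class TestBurstShape:
    def test_single_burst_profile(self, well_factory):
        well = well_factory({"a": np.linspace(100.0, 100.009, 10)})
        nb = NetworkBurst(100.0, 100.05, frozenset({"a"}), 10)
        shape = burst_shape(well, [nb], bin_width_ms=10.0)
        assert shape.counts.shape == (1, 5)
        np.testing.assert_array_equal(shape.counts[0], [10, 0, 0, 0, 0])

    def test_mean_of_identical_bursts(self, well_factory):
        spikes = np.concatenate([np.linspace(10.0, 10.09, 12), np.linspace(20.0, 20.09, 12)])
        well = well_factory({"a": spikes})
        nbs = [
            NetworkBurst(10.0, 10.1, frozenset({"a"}), 12),
            NetworkBurst(20.0, 20.1, frozenset({"a"}), 12),
        ]
        shape = burst_shape(well, nbs, bin_width_ms=10.0)
        np.testing.assert_array_equal(shape.counts[0], shape.counts[1])
        np.testing.assert_array_equal(shape.mean_profile, shape.counts[0])

    def test_row_sums_equal_window_spike_counts(self, small_spec):
        well, _ = generate_well(small_spec)
        _, nbs = detect_well(well)
        shape = burst_shape(well, nbs)
        for row, nb in zip(shape.counts, nbs):
            assert row.sum() == nb.n_spikes

    def test_flat_planted_rate_gives_flat_profile(self, small_spec):
        # flat in-burst rate, no jitter, fixed window length: each interior
        # bin is Poisson with the same mean
        spec = dataclasses.replace(
            small_spec, onset_jitter_ms=0.0, nb_duration_cv=0.0, tonic_rate_hz=0.0,
            seed=29,
        )
        well, gt = generate_well(spec)
        _, nbs = detect_well(well)
        shape = burst_shape(well, nbs, bin_width_ms=50.0)
        expected = spec.n_channels * spec.in_burst_rate_hz * 0.050
        interior = shape.mean_profile[1:-1]
        sd = math.sqrt(expected / shape.n_bursts)
        assert np.all(np.abs(interior - expected) < 3 * sd + 1e-9)

    def test_no_network_bursts_flagged_empty(self, well_factory):
        shape = burst_shape(well_factory({"a": [1.0]}), [])
        assert shape.n_bursts == 0 and shape.mean_profile.size == 0


class TestHolmSidak:
    def test_single_bin_threshold_equals_alpha(self):
        assert holm_sidak(np.array([0.049]), alpha=0.05)[0]
        assert not holm_sidak(np.array([0.051]), alpha=0.05)[0]

    def test_ten_bin_first_step_threshold(self):
        # smallest of 10 p-values tested against 1 - 0.95^(1/10) = 0.005116
        p = np.array([0.004] + [0.9] * 9)
        assert holm_sidak(p, alpha=0.05)[0]
        p = np.array([0.0052] + [0.9] * 9)
        assert not holm_sidak(p, alpha=0.05).any()

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        ),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_stepdown(self, p, alpha):
        got = holm_sidak(np.array(p), alpha=alpha)
        np.testing.assert_array_equal(got, holm_sidak_bruteforce(p, alpha))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 15))
            reject, *_ = multipletests(p, alpha=0.05, method="holm-sidak")
            np.testing.assert_array_equal(holm_sidak(p, 0.05), reject)


class TestCompareShapes:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, size=(6, 20))
        p, sig = compare_shapes(a, a.copy())
        assert not sig.any()

    def test_planted_difference_found_in_shifted_bins(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1, size=(8, 20))
        b = rng.normal(10, 1, size=(8, 20))
        b[:, 5] += 8.0
        _, sig = compare_shapes(a, b)
        assert sig[5]
        assert sig.sum() <= 2

    def test_mismatched_bins_rejected(self):
        a = np.zeros((3, 10))
        b = np.zeros((3, 12))
        with pytest.raises(ValueError, match="bin count"):
            compare_shapes(a, b)

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError, match="2 wells"):
            compare_shapes(np.zeros((1, 5)), np.zeros((3, 5)))
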