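"""Trace normalization, viability, endpoint rules, CD conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memrupt.assays import (
    CDSpectrum,
    TraceSet,
    critical_time,
    hemolysis_percent,
    mean_residue_ellipticity,
    mic_endpoint,
    normalize_traces,
    order_heatmap,
    survival_curve,
    synth_guv_traces,
    viability_table,
)


def make_traces(arrs, background=0.0, times=None):
    arrs = np.atleast_2d(np.asarray(arrs, dtype=float))
    if times is None:
        times = np.arange(arrs.shape[1], dtype=float)
    return TraceSet(times, arrs, [f"v{i}" for i in range(arrs.shape[0])], background)


class TestNormalization:
    def test_constant_trace_becomes_ones(self):
        ts = normalize_traces(make_traces(np.full(10, 150.0), background=50.0))
        assert np.allclose(ts.intensities, 1.0)

    def test_scale_invariance(self):
        shape = np.linspace(100, 20, 12)
        ts = normalize_traces(make_traces([shape, 2 * shape]))
        assert np.allclose(ts.intensities[0], ts.intensities[1])

    def test_lysis_step_normalizes_to_known_levels(self):
        trace = np.where(np.arange(20) < 8, 100.0, 20.0) + 10.0
        ts = normalize_traces(make_traces(trace, background=10.0))
        assert np.allclose(ts.intensities[0][:8], 1.0)
        assert np.allclose(ts.intensities[0][8:], 0.2)

    def test_nonpositive_initial_intensity_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding"):
            ts = normalize_traces(
                make_traces([np.full(10, 5.0), np.full(10, 100.0)], background=50.0)
            )
        assert ts.vesicle_ids == ["v1"]


class TestCriticalTime:
    def test_constant_trace_censored(self):
        assert np.isnan(critical_time(np.ones(10), np.arange(10)))

    def test_first_strict_crossing(self):
        trace = np.where(np.arange(20) < 10, 1.0, 0.4)
        assert critical_time(trace, np.arange(20)) == 10

    def test_touching_half_exactly_is_censored(self):
        trace = np.array([1.0, 0.5, 0.5, 1.0])
        assert np.isnan(critical_time(trace, np.arange(4)))

    @given(st.floats(min_value=0.1, max_value=100), st.integers(2, 18))
    def test_invariant_under_positive_rescaling_of_raw_intensity(self, scale, step):
        raw = np.where(np.arange(20) < step, 80.0, 8.0)
        t1 = viability_table(normalize_traces(make_traces(raw))).critical_times[0]
        t2 = viability_table(normalize_traces(make_traces(raw * scale))).critical_times[0]
        assert t1 == t2 == step


class TestSurvival:
    def test_all_censored_constant_one(self):
        ts = normalize_traces(make_traces(np.ones((5, 10)) * 100))
        _, s = survival_curve(viability_table(ts))
        assert np.all(s == 1.0)

    def test_single_event_time_drops_to_zero(self):
        traces = np.ones((4, 10))
        traces[:, 5:] = 0.1
        _, s = survival_curve(viability_table(normalize_traces(make_traces(traces * 100))))
        assert s[-1] == 0.0

    def test_survivor_plateau_recovered_from_generator(self):
        ts = synth_guv_traces(n=500, survivor_fraction=0.5, rng_seed=3)
        _, s = survival_curve(viability_table(normalize_traces(ts)))
        assert s[-1] == pytest.approx(0.5, abs=0.05)

    def test_curve_monotone_non_increasing_and_starts_at_one(self):
        ts = synth_guv_traces(n=100, survivor_fraction=0.3, rng_seed=9)
        _, s = survival_curve(viability_table(normalize_traces(ts)))
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0)


class TestOrdering:
    def test_rows_sorted_by_critical_time_censored_last(self):
        traces = np.ones((3, 12))
        traces[0, 6:] = 0.1  # critical at 6
        traces[1, 2:] = 0.1  # critical at 2
        ts = normalize_traces(make_traces(traces * 100))
        order = order_heatmap(ts, viability_table(ts))
        assert order == ["v1", "v0", "v2"]

    def test_all_censored_fall_back_to_id_order(self):
        ts = normalize_traces(make_traces(np.ones((3, 10)) * 100))
        assert order_heatmap(ts, viability_table(ts)) == ["v0", "v1", "v2"]

    def test_order_independent_of_input_permutation(self):
        traces = np.ones((3, 12))
        traces[0, 6:] = 0.1
        traces[1, 2:] = 0.1
        ts = normalize_traces(make_traces(traces * 100))
        perm = TraceSet(ts.times, ts.intensities[::-1], ts.vesicle_ids[::-1])
        assert order_heatmap(perm, viability_table(perm)) == order_heatmap(
            ts, viability_table(ts)
        )


class TestMIC:
    def test_reference_pattern(self):
        conc = [100, 50, 25, 12.5, 6.25]
        assert mic_endpoint(conc, [False, False, False, True, True]) == 25

    def test_growth_at_top_concentration_not_reached(self):
        assert mic_endpoint([100, 50, 25], [True, True, True]) is None

    def test_no_growth_anywhere_gives_lowest_tested(self):
        assert mic_endpoint([100, 50, 25], [False, False, False]) == 25

    def test_non_monotone_series_rejected(self):
        with pytest.raises(ValueError):
            mic_endpoint([100, 100, 25], [False, False, True])

    @given(st.integers(min_value=0, max_value=8))
    def test_agrees_with_brute_force_scan_on_monotone_patterns(self, k):
        # growth reappears below some index k (monotone growth pattern)
        conc = [100 / 2**i for i in range(8)]
        growth = [i >= k for i in range(8)]
        # oracle: smallest concentration such that it and all larger are clear
        clear = [c for i, c in enumerate(conc) if all(not growth[j] for j in range(i + 1))]
        expected = min(clear) if clear else None
        assert mic_endpoint(conc, growth) == expected


class TestHemolysis:
    @pytest.mark.parametrize(
        "A,expected", [(0.9, 100.0), (0.1, 0.0), (0.5, 50.0)]
    )
    def test_linear_scale_between_buffer_and_water(self, A, expected):
        res = hemolysis_percent(A, 0.1, 0.9)
        assert res.percent == pytest.approx(expected)

    def test_out_of_range_clipped_with_raw_retained(self):
        res = hemolysis_percent(1.3, 0.1, 0.9)
        assert res.percent == 100.0
        assert res.raw_percent == pytest.approx(150.0)

    def test_water_below_buffer_rejected(self):
        with pytest.raises(ValueError):
            hemolysis_percent(0.5, 0.9, 0.8)


class TestMRE:
    def make(self, theta, conc=40e-6, bonds=9):
        return CDSpectrum(
            wavelengths=np.arange(190, 260, dtype=float),
            ellipticity_mdeg=np.full(70, theta),
            pathlength_cm=0.1,
            peptide_conc_M=conc,
            n_residues=9,
            n_peptide_bonds=bonds,
        )

    def test_zero_signal_maps_to_zero(self):
        assert np.all(mean_residue_ellipticity(self.make(0.0)) == 0.0)

    def test_reference_conversion(self):
        mre = mean_residue_ellipticity(self.make(-10.0))
        assert mre[0] == pytest.approx(-27_778, rel=1e-3)

    def test_doubling_concentration_halves_mre(self):
        a = mean_residue_ellipticity(self.make(-10.0, conc=40e-6))
        b = mean_residue_ellipticity(self.make(-10.0, conc=80e-6))
        assert np.allclose(a, 2 * b)


class TestGenerator:
    def test_deterministic_per_seed(self):
        a = synth_guv_traces(20, 0.5, rng_seed=11)
        b = synth_guv_traces(20, 0.5, rng_seed=11)
        assert np.array_equal(a.intensities, b.intensities)

    def test_all_survivors_without_noise_are_censored(self):
        ts = synth_guv_traces(20, 1.0, noise_sd=0.0, bleach_rate=0.0, rng_seed=1)
        vt = viability_table(normalize_traces(ts))
        assert np.all(np.isnan(vt.critical_times))

    def test_step_decay_critical_times_track_drawn_lysis_times(self):
        ts = synth_guv_traces(
            50, 0.0, lysis_time_dist=("uniform", 10.0, 300.0),
            decay=("step", 0.1), noise_sd=0.0, bleach_rate=0.0, rng_seed=2
        )
        vt = viability_table(normalize_traces(ts))
        observed = vt.critical_times
        assert not np.any(np.isnan(observed))
        # regenerate the lysis draws with the same stream structure
        rng = np.random.default_rng(2)
        drawn = []
        for _ in range(50):
            rng.uniform(0.8, 1.2)
            if rng.random() >= 0.0:
                drawn.append(rng.uniform(10.0, 300.0))
        # critical time lands on the first sampled frame at/after lysis
        assert np.allclose(np.sort(observed), np.sort(np.ceil(drawn)))

    def test_csv_round_trip(self, tmp_path):
        ts = synth_guv_traces(5, 0.5, rng_seed=4)
        path = tmp_path / "traces.csv"
        ts.to_csv(path)
        back = TraceSet.from_csv(path)
        assert back.vesicle_ids == ts.vesicle_ids
        assert np.allclose(back.intensities, ts.intensities)
        assert np.allclose(back.background, ts.background)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            synth_guv_traces(5, 0.5, lysis_time_dist=("exponential", -3.0))
        with pytest.raises(ValueError):
            synth_guv_traces(5, 1.5)
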