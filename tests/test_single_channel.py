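"""Idealization, gating statistics, G-V curves and macroscopic ratios."""

import numpy as np
import pytest

import bilayerlab as bl
from bilayerlab.single_channel import CurrentTrace, EventList


def square_trace(n_events=20, amp=4.5, dwell_s=0.05, fs=5000.0, voltage=200.0, noise=0.0, seed=0):
    """Alternating closed/open square wave with equal dwell times."""
    rng = np.random.default_rng(seed)
    samples_per = int(dwell_s * fs)
    level = np.tile(np.concatenate([np.zeros(samples_per), np.full(samples_per, amp)]), n_events)
    level = np.concatenate([level, np.zeros(samples_per)])
    if noise:
        level = level + rng.normal(0, noise, level.size)
    return CurrentTrace(level, sampling_rate=fs, voltage=voltage, filter_cutoff=None)


def synthetic_events(dwells_open, amp=4.5, voltage=200.0, dead_time=0.0, dwells_closed=None):
    d_open = np.asarray(dwells_open, dtype=float)
    d_closed = np.full(d_open.size, 0.1) if dwells_closed is None else np.asarray(dwells_closed)
    states = np.zeros(2 * d_open.size, dtype=bool)
    states[1::2] = True
    dwells = np.empty(2 * d_open.size)
    dwells[0::2] = d_closed
    dwells[1::2] = d_open
    amps = np.where(states, amp, 0.0)
    starts = np.concatenate([[0.0], np.cumsum(dwells[:-1])])
    return EventList(states, starts, dwells, amps, baseline=0.0,
                     dead_time=dead_time, voltage=voltage)


class TestIdealize:
    def test_noiseless_square_events_detected_exactly(self):
        trace = square_trace(n_events=20)
        events = bl.idealize(trace, dead_time=0.0)
        assert events.ok
        opens = events.amplitudes_of("open")
        assert opens.size == 20
        np.testing.assert_allclose(opens, 4.5, atol=1e-9)

    def test_event_dwells_partition_trace(self):
        trace = square_trace(n_events=10, noise=0.3, seed=2)
        events = bl.idealize(trace, dead_time=0.0)
        assert events.dwells.sum() == pytest.approx(trace.duration, rel=1e-12)

    def test_slow_channel_trace_recovery(self):
        """Slow-channel regime (4.5 pA at 200 mV, mean open dwell 3 s,
        noise 0.5 pA, 600 s): detected event count within 10% and total
        open time within 5% of simulator truth."""
        model = bl.GatingModel(open_rate=1 / 6.0, close_rate=1 / 3.0, unit_current=4.5,
                               voltage=200.0, duration=600.0, noise_sd=0.5, seed=8)
        trace, truth = bl.gen_channel_trace(model, return_events=True)
        events = bl.idealize(trace)
        assert events.ok
        n_true = truth.dwells_of("open").size
        n_est = events.dwells_of("open").size
        assert abs(n_est - n_true) / n_true <= 0.10
        open_true = truth.dwells_of("open").sum()
        open_est = events.dwells_of("open").sum()
        assert abs(open_est - open_true) / open_true <= 0.05

    def test_unimodal_trace_yields_no_events(self):
        rng = np.random.default_rng(0)
        trace = CurrentTrace(rng.normal(0, 0.2, 50_000), sampling_rate=5000.0,
                             voltage=200.0, filter_cutoff=None)
        events = bl.idealize(trace)
        assert not events.ok
        assert events.reason == "unimodal_amplitude_histogram"

    def test_all_events_below_dead_time_are_merged_away(self):
        # 2 ms square events against a 10 ms dead time
        trace = square_trace(n_events=15, dwell_s=0.002)
        events = bl.idealize(trace, dead_time=0.010)
        assert not events.ok


class TestConductanceStats:
    def test_slow_channel_conductance_from_amplitude(self):
        """4.5 pA events at 200 mV give 22.5 pS."""
        events = synthetic_events(np.full(1200, 0.05), amp=4.5)
        st = bl.conductance_stats(events, min_events=1000)
        assert st.g_sc == pytest.approx(22.5)
        assert st.accepted

    def test_fast_channel_conductance(self):
        """9.8 pA events at 200 mV give 49 pS."""
        events = synthetic_events(np.full(1200, 0.05), amp=9.8)
        assert bl.conductance_stats(events).g_sc == pytest.approx(49.0)

    def test_normal_amplitudes_recovered_with_accepted_fit(self):
        rng = np.random.default_rng(3)
        amps = rng.normal(4.5, 0.12, 1200)
        events = synthetic_events(np.full(1200, 0.05), amp=4.5)
        events.amplitudes[events.states] = amps
        st = bl.conductance_stats(events, min_events=1000)
        se = 0.12 / np.sqrt(1200) / 0.2  # pS
        assert abs(st.g_sc - 22.5) <= 3 * se
        assert st.chi2_amplitude.p_value >= 0.05

    def test_insufficient_events_reported(self):
        st = bl.conductance_stats(synthetic_events(np.full(10, 0.05)), min_events=1000)
        assert not st.ok
        assert "insufficient" in st.reason


class TestDwellStats:
    def test_exponential_mean_recovered(self):
        """Mean open dwell 3.0 s at n=2000 with negligible dead time."""
        rng = np.random.default_rng(5)
        d = rng.exponential(3.0, 2000)
        st = bl.dwell_stats(synthetic_events(d), state="open", min_events=1500)
        assert st.ok
        assert abs(st.tau - 3.0) <= 3 * (3.0 / np.sqrt(2000))
        assert st.chi2_dwell.p_value >= 0.05

    def test_degenerate_equal_dwells_rejected_by_chi2(self):
        st = bl.dwell_stats(synthetic_events(np.full(2000, 0.5)), min_events=1500)
        assert st.chi2_dwell.p_value < 0.05
        assert not st.accepted

    def test_truncation_corrected_mle_unbiased(self):
        """Left-truncated exponential dwells (fast-channel regime:
        tau = 114 ms, dead time 3 ms): the corrected MLE is unbiased
        while the naive mean is biased up by exactly the dead time."""
        rng = np.random.default_rng(6)
        tau, dead = 0.114, 0.003
        d = dead + rng.exponential(tau, 2000)  # exact truncated-exp sample
        events = synthetic_events(d, dead_time=dead)
        st = bl.dwell_stats(events, min_events=1500)
        se = tau / np.sqrt(2000)
        assert abs(st.tau - tau) <= 3 * se
        # the corrected MLE is exactly the naive mean minus the dead
        # time (E[X|X>d] = tau + d), so the naive mean estimates tau + d
        assert st.tau == pytest.approx(d.mean() - dead)
        assert d.mean() == pytest.approx(tau + dead, abs=3 * se)

    def test_dead_time_robustness(self):
        """For dead times up to tau/100 the estimator bias stays below 2%."""
        rng = np.random.default_rng(7)
        tau = 1.0
        taus = []
        for _ in range(40):
            d = rng.exponential(tau, 4000)
            dead = tau / 100
            kept = d[d >= dead]
            st = bl.dwell_stats(synthetic_events(kept, dead_time=dead), min_events=1500)
            taus.append(st.tau)
        assert abs(np.mean(taus) - tau) / tau < 0.02

    def test_estimator_consistency_with_duration(self):
        """Median absolute errors of tau-hat and g-hat decrease as the
        trace grows (20 seeds per duration)."""
        errs = []
        for duration in (40.0, 120.0, 360.0):
            e = []
            for seed in range(20):
                model = bl.GatingModel(open_rate=1 / 0.2, close_rate=1 / 0.1,
                                       unit_current=4.5, voltage=200.0,
                                       duration=duration, noise_sd=0.5, seed=seed)
                events = bl.idealize(bl.gen_channel_trace(model))
                st = bl.dwell_stats(events, min_events=10)
                e.append(abs(st.tau - 0.1) / 0.1)
            errs.append(np.median(e))
        assert errs[2] < errs[0]


class TestGVCurve:
    def _stats(self, voltages, g, sd=1.0):
        return [(v, gi, sd) for v, gi in zip(voltages, g)]

    def test_table_ordered_and_signed(self):
        df = bl.gv_curve(self._stats([100.0, -100.0, 200.0, -200.0], [20.0, 19.0, 41.0, 40.0]))
        assert list(df.voltage_mV) == [-200.0, -100.0, 100.0, 200.0]
        with pytest.raises(bl.DomainError):
            bl.gv_curve(self._stats([50.0, 100.0, 200.0], [10.0, 20.0, 40.0]))

    def test_pure_scale_factor_has_zero_shape_deviation(self):
        a = bl.gv_curve(self._stats([-200.0, -100.0, 100.0, 200.0], [40.0, 19.0, 21.0, 41.0]))
        b = a.copy()
        b["g_sc_pS"] = b["g_sc_pS"] * 1.15
        assert bl.gv_shape_deviation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_seeds_within_band(self):
        rng = np.random.default_rng(0)
        v = np.array([-200.0, -100.0, 100.0, 200.0])
        g_true = np.abs(v) * 0.2
        dev = []
        for _ in range(20):
            a = bl.gv_curve(self._stats(v, g_true + rng.normal(0, 0.5, 4)))
            b = bl.gv_curve(self._stats(v, g_true + rng.normal(0, 0.5, 4)))
            dev.append(bl.gv_shape_deviation(a, b))
        assert np.median(dev) < 0.1


class TestMacroscopicRatio:
    def test_identical_traces_ratio_one(self):
        tr = bl.gen_macroscopic_trace(100.0, 2.0, seed=0)
        res = bl.macroscopic_ratio(tr, tr, (0.5, 2.0))
        assert res.ratio == pytest.approx(1.0)

    def test_fivefold_inhibition(self):
        before = bl.gen_macroscopic_trace(100.0, 2.0)
        after = bl.gen_macroscopic_trace(20.0, 2.0)
        assert bl.macroscopic_ratio(before, after, (0.5, 2.0)).ratio == pytest.approx(0.2)

    def test_noisy_activation_recovered(self):
        """9.8-fold activation at 5% noise: median recovered ratio over
        50 seeds within 2%."""
        ratios = []
        for seed in range(50):
            before = bl.gen_macroscopic_trace(100.0, 2.0, noise_sd=5.0, seed=seed)
            after = bl.gen_macroscopic_trace(980.0, 2.0, noise_sd=49.0, seed=seed + 1000)
            ratios.append(bl.macroscopic_ratio(before, after, (0.5, 2.0)).ratio)
        assert np.median(ratios) == pytest.approx(9.8, rel=0.02)

    def test_window_outside_trace_rejected(self):
        tr = bl.gen_macroscopic_trace(100.0, 2.0)
        with pytest.raises(bl.DomainError):
            bl.macroscopic_ratio(tr, tr, (1.0, 5.0))
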