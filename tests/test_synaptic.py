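"""Template detection, event summaries, multiplicity, evoked I/O and PPR."""

import numpy as np
import pandas as pd
import pytest

from slicephys import synthgen as sg
from slicephys.core import ParameterError, Sweep
from slicephys.kernels import KernelSpec
from slicephys.synaptic import (EventTable, detect_events_template, io_curve,
                                match_events, multiplicity_compare,
                                paired_pulse_ratio, summarize_events)


class TestTemplateDetection:
    def test_noiseless_exact_recovery(self, noiseless_mepsc):
        cfg, sweep, gt = noiseless_mepsc
        table = detect_events_template(sweep, cfg.ampa_kernel)
        interior = [t for t, e in zip(gt.event_times, gt.event_edge_flag) if not e]
        assert len(table) == len(interior)
        for t_true, t_det in zip(sorted(interior), sorted(table.times)):
            assert abs(t_det - t_true) <= 1.0 / sweep.sampling_rate + 1e-9

    def test_noiseless_amplitude_unbiased(self, noiseless_mepsc):
        cfg, sweep, gt = noiseless_mepsc
        table = detect_events_template(sweep, cfg.ampa_kernel)
        # peak convention: mean over the 1 ms window centered on the peak
        k = cfg.ampa_kernel
        expected = k.mean_over_window(k.t_peak - 0.5, k.t_peak + 0.5)
        assert table.events.peak_amp.mean() == pytest.approx(expected, rel=0.02)

    def test_decay_tau_recovered(self, noiseless_mepsc):
        cfg, sweep, _ = noiseless_mepsc
        table = detect_events_template(sweep, cfg.ampa_kernel)
        assert table.events.decay_tau.dropna().mean() == pytest.approx(
            cfg.ampa_kernel.tau_decay, rel=0.05)

    def test_translation_invariance(self, ampa):
        cfg = sg.SimConfig(seed=21, duration=10_000.0, event_rate=1.0, noise_sd=8.0)
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        shift = 100  # samples
        shifted = Sweep(np.r_[np.zeros(shift), sweep.values[:-shift]],
                        sweep.sampling_rate, units="pA")
        t0 = detect_events_template(sweep, ampa).times
        t1 = detect_events_template(shifted, ampa).times
        dt = shift / sweep.sampling_rate
        keep = t0 < sweep.duration - dt - ampa.length
        np.testing.assert_allclose(t1[: keep.sum()], t0[keep] + dt, atol=1e-9)

    def test_snr5_sensitivity_and_fdr(self, ampa):
        res = []
        for seed in (31, 32):
            cfg = sg.SimConfig(seed=seed, duration=60_000.0, event_rate=1.0,
                               noise_sd=ampa.amp / 5.0)
            sweep, gt = sg.simulate_event_trace(cfg, "mEPSC")
            table = detect_events_template(sweep, ampa, criterion=4.0)
            res.append(match_events(table.times, gt.event_times))
        sens = np.mean([r["sensitivity"] for r in res])
        fdr = (sum(r["n_detected"] - r["n_matched"] for r in res)
               / max(1, sum(r["n_detected"] for r in res)))
        assert sens >= 0.95
        assert fdr <= 0.05

    def test_pure_noise_false_positive_rate(self, ampa, rng):
        sweep = Sweep(rng.normal(0.0, 8.0, int(20 * 60_000)), 20.0, units="pA")
        table = detect_events_template(sweep, ampa, criterion=4.0)
        assert len(table) / 60.0 < 0.1  # events per second

    def test_template_longer_than_trace_rejected(self, ampa):
        sweep = Sweep(np.zeros(10), 20.0, units="pA")
        with pytest.raises(ParameterError):
            detect_events_template(sweep, ampa)

    def test_outward_sign_flag_mirrors_inward(self, ampa):
        cfg = sg.SimConfig(seed=22, duration=10_000.0, event_rate=1.0, noise_sd=4.0)
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        flipped = Sweep(-sweep.values, sweep.sampling_rate, units="pA")
        t_in = detect_events_template(sweep, ampa, sign="inward").times
        t_out = detect_events_template(flipped, ampa, sign="outward").times
        np.testing.assert_allclose(t_in, t_out)


class TestSummaries:
    def test_interval_and_amplitude_arithmetic(self):
        df = pd.DataFrame({"time": [0.0, 100.0, 200.0],
                           "peak_time": [1.0, 101.0, 201.0],
                           "peak_amp": [40.0, 40.0, 40.0],
                           "rise_10_90": [0.5] * 3, "decay_tau": [5.0] * 3,
                           "charge": [200.0] * 3, "detection_score": [9.0] * 3})
        s = summarize_events(EventTable(events=df))
        assert s["mean_iei_ms"] == pytest.approx(100.0)
        assert s["mean_amp_pA"] == pytest.approx(40.0)

    def test_single_event_intervals_flagged(self):
        df = pd.DataFrame({"time": [5.0], "peak_time": [6.0], "peak_amp": [30.0],
                           "rise_10_90": [0.5], "decay_tau": [5.0],
                           "charge": [150.0], "detection_score": [8.0]})
        s = summarize_events(EventTable(events=df))
        assert s.get("iei_undefined") and np.isnan(s["mean_iei_ms"])


class TestMultiplicity:
    @staticmethod
    def _amps_table(amps):
        n = len(amps)
        df = pd.DataFrame({"time": np.arange(n) * 50.0,
                           "peak_time": np.arange(n) * 50.0 + 1.0,
                           "peak_amp": amps, "rise_10_90": 0.5,
                           "decay_tau": 5.0, "charge": 200.0,
                           "detection_score": 8.0})
        return EventTable(events=df)

    def test_null_case_ratio_one(self, rng):
        a = self._amps_table(rng.normal(40.0, 5.0, 60))
        b = self._amps_table(rng.normal(40.0, 5.0, 60))
        rep = multiplicity_compare(a, b)
        assert rep["ratio"] == pytest.approx(1.0, abs=0.1)
        assert not rep["multiplicity_present"]

    def test_doubled_amplitudes_detected(self, rng):
        k = 1 + rng.poisson(1.0, 200)
        s = self._amps_table(40.0 * k + rng.normal(0, 2, 200))
        m = self._amps_table(40.0 + rng.normal(0, 2, 200))
        rep = multiplicity_compare(s, m)
        assert rep["ratio"] == pytest.approx(2.0, rel=0.15)
        assert rep["multiplicity_present"]

    def test_empty_table_rejected(self, rng):
        a = self._amps_table(rng.normal(40.0, 5.0, 10))
        empty = EventTable(events=a.events.iloc[:0])
        with pytest.raises(ParameterError):
            multiplicity_compare(a, empty)


class TestEvoked:
    def test_io_recovers_planted_sigmoid_noiseless(self):
        cfg = sg.SimConfig(seed=23, noise_sd=0.0)
        sweeps, gt = sg.simulate_evoked_series(cfg)
        res = io_curve(sweeps, gt.params["stimuli_uA"])
        for (s, peak), true in zip(res.io_points, gt.params["true_peaks_pA"]):
            assert peak == pytest.approx(true, rel=0.02, abs=0.5)

    def test_io_length_mismatch(self):
        cfg = sg.SimConfig(seed=24, noise_sd=0.0)
        sweeps, gt = sg.simulate_evoked_series(cfg)
        with pytest.raises(ParameterError):
            io_curve(sweeps, gt.params["stimuli_uA"][:-1])

    def test_ppr_noiseless_exact(self):
        for planted in (1.0, 1.5):
            cfg = sg.SimConfig(seed=25, noise_sd=0.0)
            sweeps, _ = sg.simulate_evoked_series(cfg, sg.EvokedConfig(ppr=planted),
                                                  paired=True)
            res = paired_pulse_ratio(sweeps)
            assert res.ppr == pytest.approx(planted, rel=0.02)

    def test_ppr_noisy_six_traces(self):
        cfg = sg.SimConfig(seed=26, noise_sd=10.0)
        sweeps, _ = sg.simulate_evoked_series(cfg, sg.EvokedConfig(ppr=1.5),
                                              paired=True)
        res = paired_pulse_ratio(sweeps)
        assert res.n_traces_averaged == 6
        assert res.ppr == pytest.approx(1.5, rel=0.10)

    def test_ppr_averaging_idempotence(self):
        cfg = sg.SimConfig(seed=27, noise_sd=5.0)
        sweeps, _ = sg.simulate_evoked_series(cfg, sg.EvokedConfig(ppr=1.2, n_repeats=1),
                                              paired=True)
        single = paired_pulse_ratio(sweeps)
        doubled = paired_pulse_ratio(sweeps * 2)
        assert doubled.ppr == pytest.approx(single.ppr, abs=1e-12)

    def test_ppr_undefined_below_noise_floor(self):
        sr = 20.0
        flat = Sweep(np.zeros(int(200 * sr)), sr, units="pA",
                     epochs={"stim1": (20.0, 21.0), "stim2": (70.0, 71.0)})
        with pytest.raises(ParameterError):
            paired_pulse_ratio([flat])
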