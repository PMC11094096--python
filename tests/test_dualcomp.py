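"""AMPA/NMDA decomposition, single-event components, ANCOVA, tonic current."""

import numpy as np
import pandas as pd
import pytest

from slicephys import synthgen as sg
from slicephys.core import ParameterError
from slicephys.dualcomp import (AverageEvent, InsufficientEventsError,
                                build_average_event, correlate_components,
                                decompose_ampa_nmda, single_event_components,
                                tonic_current)
from slicephys.kernels import KernelSpec
from slicephys.synaptic import detect_events_template


def _avg_from_kernels(*kernels, amp_scale=1.0, sr=20.0, dur=600.0):
    wave = sum(k.waveform(sr, dur) for k in kernels)
    return AverageEvent(-amp_scale * wave, sr, n_events=100)


class TestAverageEvent:
    def test_average_of_identical_events_matches_kernel(self):
        cfg = sg.SimConfig(seed=30, duration=150_000.0, event_rate=1.0, noise_sd=0.0)
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        table = detect_events_template(sweep, cfg.ampa_kernel)
        avg = build_average_event(table, sweep, min_n=50, post_ms=30.0)
        kernel = -cfg.ampa_kernel.waveform(sweep.sampling_rate, 25.0)
        n = min(avg.waveform.size, kernel.size)
        # onset alignment starts at the 10% point, so compare peak values
        assert avg.waveform.min() == pytest.approx(kernel.min(), rel=0.02)
        assert avg.n_events >= 50

    def test_insufficient_events_guard(self):
        cfg = sg.SimConfig(seed=31, duration=12_000.0, event_rate=1.0, noise_sd=0.0)
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        table = detect_events_template(sweep, cfg.ampa_kernel)
        with pytest.raises(InsufficientEventsError):
            build_average_event(table, sweep, min_n=50)

    def test_noisy_average_within_clt_bound(self):
        noise = 8.0
        cfg = sg.SimConfig(seed=32, duration=150_000.0, event_rate=1.0, noise_sd=noise)
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        table = detect_events_template(sweep, cfg.ampa_kernel)
        avg = build_average_event(table, sweep, min_n=50, post_ms=30.0)
        kernel = cfg.ampa_kernel
        assert abs(avg.waveform.min()) == pytest.approx(
            kernel.amp, abs=3 * noise / np.sqrt(avg.n_events) + 0.05 * kernel.amp)


class TestDecomposition:
    def test_identical_averages_flag_ratio(self):
        a = _avg_from_kernels(KernelSpec(100.0, 0.5, 5.0))
        res = decompose_ampa_nmda(a, a)
        assert not res.ratio_defined and res.ratio is None
        assert np.allclose(res.nmda_waveform, 0.0, atol=1e-12)

    def test_analytic_charges(self):
        ampa = KernelSpec(100.0, 0.5, 5.0)
        nmda = KernelSpec(20.0, 5.0, 80.0)
        res = decompose_ampa_nmda(_avg_from_kernels(ampa, nmda), _avg_from_kernels(ampa))
        # closed form: Q = coeff * (tau_d - tau_r)
        assert res.Q_ampa == pytest.approx(ampa.charge(), rel=0.02)
        assert res.Q_nmda == pytest.approx(nmda.charge(), rel=0.02)
        assert res.ratio == pytest.approx(ampa.charge() / nmda.charge(), rel=0.04)

    def test_linearity_in_amplitude(self):
        ampa = KernelSpec(100.0, 0.5, 5.0)
        nmda = KernelSpec(20.0, 5.0, 80.0)
        r1 = decompose_ampa_nmda(_avg_from_kernels(ampa, nmda), _avg_from_kernels(ampa))
        r2 = decompose_ampa_nmda(_avg_from_kernels(ampa, nmda, amp_scale=3.0),
                                 _avg_from_kernels(ampa, amp_scale=3.0))
        assert r2.Q_ampa == pytest.approx(3 * r1.Q_ampa, rel=1e-6)
        assert r2.Q_nmda == pytest.approx(3 * r1.Q_nmda, rel=1e-6)
        assert r2.ratio == pytest.approx(r1.ratio, rel=1e-6)

    @pytest.mark.parametrize("sr", [20.0, 40.0, 80.0])
    def test_trapezoid_charge_converges_with_sampling(self, sr):
        ampa = KernelSpec(100.0, 0.5, 5.0)
        res = decompose_ampa_nmda(
            _avg_from_kernels(ampa, KernelSpec(20.0, 5.0, 80.0), sr=sr),
            _avg_from_kernels(ampa, sr=sr))
        # error shrinks toward the analytic value as the rate increases
        tol = {20.0: 0.02, 40.0: 0.015, 80.0: 0.012}[sr]
        assert res.Q_ampa == pytest.approx(ampa.charge(), rel=tol)


class TestSingleEvents:
    def test_pure_ampa_residual_matches_closed_form(self):
        # sparse events so no 22-27 ms window is contaminated by a neighbor
        cfg = sg.SimConfig(seed=33, duration=300_000.0, event_rate=0.3, noise_sd=0.0,
                           ampa_kernel=KernelSpec(100.0, 0.5, 5.0))
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        table = detect_events_template(sweep, cfg.ampa_kernel)
        rows = single_event_components(table, sweep, rms_noise=1.0)
        k = cfg.ampa_kernel
        # oracle: analytic mean of the kernel over [t_pk+22, t_pk+27]
        expected = k.mean_over_window(k.t_peak + 22.0, k.t_peak + 27.0)
        assert len(rows) > 50
        # median: robust to the rare event whose window clips a close pair
        assert rows.nmda_meas.median() == pytest.approx(expected, rel=0.05, abs=0.05)

    def test_dual_event_components(self):
        cfg = sg.SimConfig(seed=34, duration=150_000.0, event_rate=1.0, noise_sd=0.0,
                           ampa_kernel=KernelSpec(100.0, 0.5, 5.0),
                           nmda_kernel=KernelSpec(20.0, 5.0, 80.0))
        sweep, _ = sg.simulate_event_trace(cfg, "dual")
        table = detect_events_template(sweep, cfg.ampa_kernel)
        rows = single_event_components(table, sweep, rms_noise=1.0)
        # oracle: brute-force sample of the combined kernel, same peak rule
        sr = sweep.sampling_rate
        wave = (cfg.ampa_kernel.waveform(sr, 400.0)
                + cfg.nmda_kernel.waveform(sr, 400.0))
        i_pk = int(np.argmax(wave))
        w0, w1 = i_pk + int(22 * sr), i_pk + int(27 * sr)
        expected = wave[w0:w1].mean()
        assert rows.nmda_meas.mean() == pytest.approx(expected, rel=0.10)

    def test_small_events_excluded_by_30pA_rule(self):
        cfg = sg.SimConfig(seed=35, duration=60_000.0, event_rate=1.0, noise_sd=0.0,
                           ampa_kernel=KernelSpec(20.0, 0.5, 5.0))
        sweep, _ = sg.simulate_event_trace(cfg, "mEPSC")
        table = detect_events_template(sweep, cfg.ampa_kernel)
        rows = single_event_components(table, sweep, rms_noise=0.1)
        assert len(table) > 0 and len(rows) == 0


class TestAncova:
    @staticmethod
    def _line(rng, n, slope=0.2, intercept=2.0, noise=0.3, shift=0.0):
        x = rng.uniform(30.0, 100.0, n)
        y = intercept + slope * x + shift + rng.normal(0, noise, n)
        return pd.DataFrame({"time": np.arange(n, dtype=float),
                             "ampa_peak": x, "nmda_meas": y})

    def test_null_offset_nonsignificant(self, rng):
        a = self._line(rng, 40)
        b = self._line(rng, 40)
        rows = pd.concat([a, b], ignore_index=True)
        rep = correlate_components(rows, ["wt"] * 40 + ["ko"] * 40)
        (offset,) = rep["ancova_offset_pA"].values()
        assert abs(offset) < 0.5
        assert rep["group_p"] > 0.05

    def test_planted_shift_recovered(self, rng):
        a = self._line(rng, 60)
        b = self._line(rng, 60, shift=-5.0)
        rows = pd.concat([a, b], ignore_index=True)
        rep = correlate_components(rows, ["a"] * 60 + ["b"] * 60)
        (offset,) = rep["ancova_offset_pA"].values()
        assert offset == pytest.approx(-5.0, abs=0.5)
        assert rep["group_p"] < 0.05

    def test_collinear_r_is_one(self, rng):
        a = self._line(rng, 20, noise=0.0)
        b = self._line(rng, 20, noise=0.0, shift=1.0)
        rows = pd.concat([a, b], ignore_index=True)
        rep = correlate_components(rows, ["a"] * 20 + ["b"] * 20)
        assert rep["per_group"]["a"]["r"] == pytest.approx(1.0, abs=1e-9)

    def test_tiny_group_rejected(self, rng):
        rows = self._line(rng, 5)
        with pytest.raises(ParameterError):
            correlate_components(rows, ["a", "a", "a", "b", "b"])


class TestTonic:
    def test_noiseless_step_recovered_exactly(self):
        cfg = sg.SimConfig(seed=36, duration=25_000.0, noise_sd=0.0)
        sweep, gt = sg.simulate_tonic_block(cfg, step_pA=20.0, event_rate_hz=0.0)
        res = tonic_current(sweep, gt.params["drug_time_ms"])
        assert res.I_drug_sensitive == pytest.approx(20.0)
        assert res.rms_change == pytest.approx(0.0, abs=1e-9)

    def test_rms_change_tracks_noise_sd(self):
        cfg = sg.SimConfig(seed=37, duration=30_000.0, noise_sd=5.0)
        sweep, gt = sg.simulate_tonic_block(cfg, step_pA=10.0, noise_sd_after=3.0)
        res = tonic_current(sweep, gt.params["drug_time_ms"],
                            np.asarray(gt.event_times))
        assert res.rms_before == pytest.approx(5.0, abs=0.3)
        assert res.rms_after == pytest.approx(3.0, abs=0.3)

    def test_null_step_near_zero(self):
        cfg = sg.SimConfig(seed=38, duration=25_000.0, noise_sd=5.0)
        sweep, gt = sg.simulate_tonic_block(cfg, step_pA=0.0, event_rate_hz=0.0)
        res = tonic_current(sweep, gt.params["drug_time_ms"])
        assert abs(res.I_drug_sensitive) < 0.5

    def test_busy_trace_rejected(self):
        cfg = sg.SimConfig(seed=39, duration=25_000.0, noise_sd=2.0)
        sweep, gt = sg.simulate_tonic_block(cfg, step_pA=10.0, event_rate_hz=30.0)
        with pytest.raises(ParameterError):
            tonic_current(sweep, gt.params["drug_time_ms"],
                          np.asarray(gt.event_times))

    def test_short_trace_rejected(self):
        cfg = sg.SimConfig(seed=40, duration=12_000.0, noise_sd=1.0)
        sweep, gt = sg.simulate_tonic_block(cfg, step_pA=10.0, event_rate_hz=0.0)
        with pytest.raises(ParameterError):
            tonic_current(sweep, gt.params["drug_time_ms"])
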