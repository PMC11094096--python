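"""Detection and summary of spontaneous/miniature synaptic currents, and
evoked input-output / paired-pulse analysis.

Event detection re-implements the scaled-template search of Clements &
Bekkers (1997): at every lag the template is optimally scaled and offset
against the trace, and the detection criterion is the fitted scale divided
by the standard deviation of the fit residual.  Local maxima of the
criterion above threshold become events.  Inhibitory currents (outward,
positive-going) reuse the same machinery through a single sign flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from .core import ParameterError, Sweep
from .kernels import KernelSpec


@dataclass
class EventTable:
    """Detected synaptic events, one row per event.

    Columns: time (ms, onset), peak_time (ms), peak_amp (pA, magnitude),
    rise_10_90 (ms), decay_tau (ms, NaN where the fit failed), charge (fC),
    detection_score.
    """

    events: pd.DataFrame
    condition: str = "mEPSC"
    trace_meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return self.events["time"].to_numpy()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


@dataclass
class EvokedResult:
    io_points: list = None          # (stimulus uA, peak pA)
    ppr: float = None               # A2/A1
    A1: float = None                # pA
    A2: float = None                # pA
    n_traces_averaged: int = 0


def _sliding_template_criterion(y: np.ndarray, w: np.ndarray):
    """Clements-Bekkers detection criterion at every template lag.

    For each lag the least-squares fit ``y ~ scale * w + offset`` is solved
    in closed form with running sums; returns (criterion, scale) arrays of
    length ``len(y) - len(w) + 1``.
    """
    M = w.size
    if M > y.size:
        raise ParameterError("template longer than trace")
    sw = w.sum()
    sww = (w * w).sum()
    ones = np.ones(M)
    # running sums over the trace via convolution with a flat kernel
    sy = fftconvolve(y, ones[::-1], mode="valid")
    syy = fftconvolve(y * y, ones[::-1], mode="valid")
    swy = fftconvolve(y, w[::-1], mode="valid")
    denom = sww - sw * sw / M
    scale = (swy - sw * sy / M) / denom
    offset = (sy - scale * sw) / M
    sse = syy + scale ** 2 * sww + M * offset ** 2 \
        - 2 * (scale * swy + offset * sy - scale * offset * sw)
    sse = np.maximum(sse, 0.0)
    # floor the residual SD so exact (noiseless) matches yield a large,
    # finite criterion instead of a division by zero
    sd = np.maximum(np.sqrt(sse / (M - 1)), 1e-6)
    return scale / sd, scale


def _local_maxima_above(crit: np.ndarray, threshold: float, min_sep: int):
    """One detection per suprathreshold excursion of the criterion.

    Contiguous runs of ``crit > threshold`` yield their argmax; peaks closer
    than ``min_sep`` samples are merged keeping the larger criterion, so a
    noisy criterion bump around one event cannot split into doublets.
    """
    above = crit > threshold
    if not above.any():
        return np.empty(0, dtype=int)
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.r_[0 if above[0] else [], edges[~above[edges]] + 1].astype(int)
    stops = np.r_[edges[above[edges]] + 1, crit.size if above[-1] else []].astype(int)
    peaks = [s + int(np.argmax(crit[s:e])) for s, e in zip(starts, stops)]
    kept = []
    for i in peaks:
        if kept and i - kept[-1] < min_sep:
            if crit[i] > crit[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return np.asarray(kept, dtype=int)


def detect_events_template(sweep: Sweep, template: KernelSpec,
                           criterion: float = 4.0,
                           sign: str = "inward",
                           baseline_ms: float = 2.0,
                           min_separation_ms: float | None = None,
                           decay_fit: bool = True) -> EventTable:
    """Sliding scaled-template event detection on a current sweep.

    Parameters
    ----------
    template : KernelSpec
        Bi-exponential template; length used is rise + 5 decay constants.
    criterion : float
        Detection threshold on scale / SD(residual); 4 is the conventional
        value for Clements-Bekkers matching.
    sign : str
        ``"inward"`` for negative-going (E)PSCs, ``"outward"`` for IPSCs
        recorded as positive deflections.
    """
    if sweep.units != "pA":
        raise ParameterError("event detection requires a current (pA) sweep")
    if sign not in ("inward", "outward"):
        raise ParameterError("sign must be 'inward' or 'outward'")
    sgn = -1.0 if sign == "inward" else 1.0

    sr = sweep.sampling_rate
    w = template.waveform(sr)
    w = w / w.max()            # unit peak: the fitted scale is then in pA
    y = sweep.values * sgn     # make events positive for matching
    crit, scale = _sliding_template_criterion(y, w)
    # default separation: the template rise time, floored at the 2 ms
    # single-event spacing so one noisy criterion bump cannot split
    if min_separation_ms is None:
        min_separation_ms = max(template.tau_rise, 2.0)
    min_sep = max(1, int(round(min_separation_ms * sr)))
    onsets = _local_maxima_above(crit, criterion, min_sep)

    rows = []
    n = y.size
    peak_search = int(round((template.t_peak + 2.0) * sr))
    for i0 in onsets:
        t_on = i0 / sr
        b0 = max(0, i0 - int(round(baseline_ms * sr)))
        baseline = y[b0:i0].mean() if i0 > b0 else 0.0
        seg = y[i0:min(n, i0 + max(peak_search, int(round(template.length * sr))))] - baseline
        if seg.size < 3:
            continue
        i_raw = int(np.argmax(seg[:peak_search]))
        # 1 ms running-mean refinement around the raw extremum
        win = max(1, int(round(1.0 * sr)))
        half = win // 2
        lo = max(0, i_raw - half)
        sm = np.convolve(seg, np.ones(win) / win, mode="same")
        i_pk = lo + int(np.argmax(sm[lo:min(seg.size, i_raw + half + 1)]))
        amp = float(sm[i_pk])
        if amp <= 0:
            continue
        # 10-90% rise time on the raw segment
        pre = seg[: i_raw + 1]
        try:
            i10 = int(np.flatnonzero(pre >= 0.1 * seg[i_raw])[0])
            i90 = int(np.flatnonzero(pre >= 0.9 * seg[i_raw])[0])
            rise = (i90 - i10) / sr
        except IndexError:
            rise = np.nan
        # mono-exponential decay fit from the raw peak
        tau = np.nan
        if decay_fit:
            dseg = seg[i_raw:int(round(min(seg.size, i_raw + 5 * template.tau_decay * sr)))]
            if dseg.size >= 5 and dseg[0] > 0:
                t = np.arange(dseg.size) / sr
                try:
                    popt, _ = curve_fit(
                        lambda tt, a, td, c: a * np.exp(-tt / td) + c,
                        t, dseg, p0=(dseg[0], template.tau_decay, 0.0), maxfev=2000,
                        bounds=([0.0, 1e-4, -np.inf], [np.inf, np.inf, np.inf]))
                    if popt[1] > 0:
                        tau = float(popt[1])
                except RuntimeError:
                    pass
        charge = float(np.trapezoid(np.maximum(seg, 0.0), dx=1.0 / sr))
        rows.append({"time": t_on, "peak_time": t_on + i_pk / sr,
                     "peak_amp": amp, "rise_10_90": rise, "decay_tau": tau,
                     "charge": charge, "detection_score": float(crit[i0])})

    df = pd.DataFrame(rows, columns=["time", "peak_time", "peak_amp", "rise_10_90",
                                     "decay_tau", "charge", "detection_score"])
    return EventTable(events=df, condition=sweep.meta.get("condition", "mEPSC"),
                      trace_meta={"sampling_rate": sr, "sign": sign})


def summarize_events(table: EventTable) -> dict:
    """Mean/median inter-event interval, mean amplitude and mean decay tau."""
    df = table.events
    out = {"n_events": len(df)}
    if len(df) >= 2:
        iei = np.diff(df["time"].to_numpy())
        out["mean_iei_ms"] = float(iei.mean())
        out["median_iei_ms"] = float(np.median(iei))
    else:
        out["mean_iei_ms"] = out["median_iei_ms"] = np.nan
        out["iei_undefined"] = True
    out["mean_amp_pA"] = float(df["peak_amp"].mean()) if len(df) else np.nan
    out["mean_decay_tau_ms"] = float(df["decay_tau"].dropna().mean()) if len(df) else np.nan
    return out


def multiplicity_compare(sepsc: EventTable, mepsc: EventTable) -> dict:
    """Compare sEPSC vs mEPSC amplitudes as a synaptic-multiplicity readout.

    Multivesicular release shows up as sEPSC amplitudes exceeding mEPSC
    amplitudes; the two-group test is selected by the normality/variance
    routing used throughout the study.
    """
    from .stats import select_two_group_test

    if len(sepsc) == 0 or len(mepsc) == 0:
        raise ParameterError("both event tables must be non-empty")
    a = sepsc.events["peak_amp"].to_numpy()
    b = mepsc.events["peak_amp"].to_numpy()
    report = select_two_group_test(a, b)
    ratio = a.mean() / b.mean()
    return {
        "mean_sepsc_pA": float(a.mean()),
        "mean_mepsc_pA": float(b.mean()),
        "ratio": float(ratio),
        "test": report,
        "multiplicity_present": bool(ratio > 1.0 and report.p_value < 0.05),
    }


def _peak_after_stimulus(values: np.ndarray, sr: float, stim_ms: float,
                         baseline: float, blank_ms: float, window_ms: float,
                         sgn: float) -> float:
    i0 = int(round((stim_ms + blank_ms) * sr))
    i1 = int(round((stim_ms + window_ms) * sr))
    seg = (values[i0:i1] - baseline) * sgn
    return float(seg.max()) if seg.size else np.nan


def io_curve(series: list[Sweep], stimuli_uA: list[float],
             blank_ms: float = 1.0, window_ms: float = 40.0,
             sign: str = "inward") -> EvokedResult:
    """Peak EPSC magnitude per stimulus strength, artifact-blanked.

    The stimulus artifact is excluded by a configurable 1 ms blanking window
    after stimulus onset; peaks are measured relative to the pre-stimulus
    baseline.
    """
    if len(series) != len(stimuli_uA):
        raise ParameterError("series and stimuli lengths differ")
    sgn = -1.0 if sign == "inward" else 1.0
    pts = []
    for sweep, s in zip(series, stimuli_uA):
        stim_ms = sweep.epochs.get("stim1", (0.0, 1.0))[0]
        base = sweep.slice(max(0.0, stim_ms - 10.0), stim_ms)
        baseline = base.mean() if base.size else 0.0
        pk = _peak_after_stimulus(sweep.values, sweep.sampling_rate, stim_ms,
                                  baseline, blank_ms, window_ms, sgn)
        pts.append((float(s), pk))
    pts.sort(key=lambda p: p[0])
    return EvokedResult(io_points=pts, n_traces_averaged=len(series))


def paired_pulse_ratio(traces: list[Sweep], blank_ms: float = 1.0,
                       window_ms: float = 40.0, sign: str = "inward",
                       noise_floor_pA: float = 1.0) -> EvokedResult:
    """PPR = A2/A1 from point-wise averaged paired-pulse traces.

    Traces are averaged first; A1 is measured from the pre-first-stimulus
    baseline and A2 from the local baseline immediately before the second
    stimulus (decay-extrapolation subtraction is deliberately not applied).
    """
    if len(traces) < 1:
        raise ParameterError("need at least one trace")
    sr = traces[0].sampling_rate
    n = min(t.n_samples for t in traces)
    avg = np.mean([t.values[:n] for t in traces], axis=0)
    ref = traces[0]
    if "stim1" not in ref.epochs or "stim2" not in ref.epochs:
        raise ParameterError("traces must mark stim1 and stim2 epochs")
    s1 = ref.epochs["stim1"][0]
    s2 = ref.epochs["stim2"][0]
    sgn = -1.0 if sign == "inward" else 1.0

    b1 = avg[int(round(max(0.0, (s1 - 10.0)) * sr)):int(round(s1 * sr))].mean()
    a1 = _peak_after_stimulus(avg, sr, s1, b1, blank_ms,
                              min(window_ms, s2 - s1 - 1.0), sgn)
    i2a = int(round((s2 - 2.0) * sr))
    i2b = int(round(s2 * sr))
    b2 = avg[i2a:i2b].mean()
    a2 = _peak_after_stimulus(avg, sr, s2, b2, blank_ms, window_ms, sgn)
    if not np.isfinite(a1) or a1 < noise_floor_pA:
        raise ParameterError("A1 at or below the noise floor; PPR undefined")
    return EvokedResult(ppr=float(a2 / a1), A1=float(a1), A2=float(a2),
                        n_traces_averaged=len(traces))


def match_events(detected_ms: np.ndarray, truth_ms: np.ndarray,
                 tolerance_ms: float = 5.0) -> dict:
    """Greedy one-to-one matching of detected to planted event times.

    Returns sensitivity (matched / planted) and false-discovery rate
    (unmatched detections / detections); used to score detectors against
    generator ground truth.
    """
    detected = np.sort(np.asarray(detected_ms, dtype=float))
    truth = np.sort(np.asarray(truth_ms, dtype=float))
    used = np.zeros(truth.size, dtype=bool)
    n_match = 0
    for t in detected:
        j = np.searchsorted(truth, t)
        best, bestd = -1, tolerance_ms
        for k in (j - 1, j):
            if 0 <= k < truth.size and not used[k] and abs(truth[k] - t) <= bestd:
                best, bestd = k, abs(truth[k] - t)
        if best >= 0:
            used[best] = True
            n_match += 1
    sens = n_match / truth.size if truth.size else np.nan
    fdr = (detected.size - n_match) / detected.size if detected.size else 0.0
    return {"n_detected": int(detected.size), "n_truth": int(truth.size),
            "n_matched": int(n_match), "sensitivity": float(sens), "fdr": float(fdr)}
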