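"""Passive-membrane and excitability analysis of patch-clamp sweeps.

The membrane test follows the classical whole-cell configuration: a 10 mV
hyperpolarizing step produces a transient capacitive current peaking at
``Ip = V / Rs`` and relaxing mono-exponentially to ``Is = V / Rt`` with
``Rt = Rs + Rm``.  Cell capacitance is computed as

    Cm = tau * (Is + Ip)^2 / (V * Is)

which is algebraically ``tau / (Rs * Rm / (Rs + Rm))`` when Ip is referenced
to the steady state; an alternative convention referencing Ip to baseline is
available through ``cm_convention`` (see Notes in the methods document).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .core import DegenerateSweepError, ParameterError, Sweep


class FitError(RuntimeError):
    """Exponential fit failed to converge; carries diagnostics."""


@dataclass
class MembraneTestResult:
    Rt: float    # MOhm, input (total) resistance
    Rs: float    # MOhm, series resistance
    Rm: float    # MOhm, membrane resistance (= Rt - Rs)
    Cm: float    # pF
    tau: float   # ms, transient decay constant
    Is: float    # pA, steady-state step current (magnitude)
    Ip: float    # pA, peak transient current (magnitude)
    V: float     # mV, step size (magnitude)


@dataclass
class ExcitabilityResult:
    resting_potential: float            # mV
    fi_curve: list                      # (injected pA, spike count, Hz)
    rheobase: Optional[float]           # pA; None if no step spiked
    threshold_voltage: Optional[float]  # mV
    spike_times: dict                   # injected pA -> list of ms


def _fit_monoexp(t, y, tau0):
    """Least-squares y ~ a * exp(-t/tau) + c with log-linear initialization."""
    c0 = y[-len(y) // 4:].mean()
    a0 = y[0] - c0
    resid = y - c0
    # log-linear initial tau where the residual keeps the initial sign
    ok = np.sign(resid) == np.sign(a0) if a0 != 0 else np.zeros(len(y), bool)
    if ok.sum() >= 3 and a0 != 0:
        z = np.log(np.abs(resid[ok]))
        slope = np.polyfit(t[ok], z, 1)[0]
        if slope < 0:
            tau0 = -1.0 / slope
    try:
        popt, _ = curve_fit(lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
                            t, y, p0=(a0, max(tau0, 1e-3), c0), maxfev=5000,
                            bounds=([-np.inf, 1e-4, -np.inf], [np.inf, np.inf, np.inf]))
    except RuntimeError as e:  # pragma: no cover - diagnostic path
        raise FitError(f"mono-exponential fit did not converge: {e}") from e
    if popt[1] <= 0:
        raise FitError(f"non-physical tau {popt[1]:.3g} ms from fit")
    return popt  # a, tau, c


def measure_membrane_test(sweep: Sweep, cm_convention: str = "as_printed",
                          fit_start_ms: float = 0.1) -> MembraneTestResult:
    """Estimate Rt, Rs, Rm, Cm and tau from a membrane-test sweep.

    Requires ``baseline`` and ``step`` epochs and pA units.  The baseline is
    the mean over the 50 ms preceding the step (or the whole baseline epoch
    if shorter); the steady state is the mean over the last quarter of the
    step.  tau comes from a mono-exponential fit of the transient from
    ``fit_start_ms`` after the peak to the end of the step.
    """
    if sweep.units != "pA":
        raise ParameterError("membrane test requires a current (pA) sweep")
    for name in ("baseline", "step"):
        if name not in sweep.epochs:
            raise ParameterError(f"sweep lacks {name!r} epoch")
    V = abs(sweep.meta.get("step_mV", -10.0))

    b0, b1 = sweep.epochs["baseline"]
    base = sweep.slice(max(b0, b1 - 50.0), b1)
    baseline = base.mean()

    s0, s1 = sweep.epochs["step"]
    step = sweep.epoch_values("step")
    q = step[int(len(step) * 0.75):]
    Is = abs(q.mean() - baseline)

    centered = step - baseline
    i_pk = int(np.argmax(np.abs(centered)))
    Ip = abs(centered[i_pk])
    if Ip <= Is or Is == 0:
        raise DegenerateSweepError("no detectable capacitive transient (Ip <= Is)")

    sr = sweep.sampling_rate
    i_fit0 = i_pk + max(1, int(round(fit_start_ms * sr)))
    y = np.abs(centered[i_fit0:])
    t = np.arange(y.size) / sr
    if y.size < 5:
        raise DegenerateSweepError("step too short to fit the transient decay")
    _, tau, _ = _fit_monoexp(t, y, tau0=1.0)

    Rt = V / Is * 1e3  # mV/pA = GOhm -> MOhm
    Rs = V / Ip * 1e3
    Rm = Rt - Rs
    if cm_convention == "as_printed":
        Cm = tau * (Is + Ip) ** 2 / (V * Is)  # ms * pA^2 / (mV * pA) = pF
    elif cm_convention == "two_compartment":
        # tau / (Rs * Rm / Rt) with Ip measured from baseline
        Cm = tau / (Rs * Rm / Rt) * 1e3  # ms / MOhm = nF -> pF
    else:
        raise ParameterError(f"unknown cm_convention {cm_convention!r}")
    return MembraneTestResult(Rt=Rt, Rs=Rs, Rm=Rm, Cm=Cm, tau=tau, Is=Is, Ip=Ip, V=V)


def series_resistance_stable(rs_values, max_change: float = 0.20) -> bool:
    """QC rule: False (exclude the cell) if Rs changed by more than 20%."""
    rs = np.asarray(list(rs_values), dtype=float)
    if rs.size < 2:
        return True
    return bool((rs.max() - rs.min()) / rs.min() <= max_change)


def detect_spikes(sweep: Sweep, crossing_mV: float = 0.0,
                  min_separation_ms: float = 1.0) -> np.ndarray:
    """Times (ms) of upward crossings of ``crossing_mV``, >= 1 ms apart."""
    if sweep.units != "mV":
        raise ParameterError("spike detection requires a voltage (mV) sweep")
    v = sweep.values
    up = np.flatnonzero((v[:-1] < crossing_mV) & (v[1:] >= crossing_mV)) + 1
    times = up / sweep.sampling_rate
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= min_separation_ms:
            kept.append(t)
            last = t
    return np.asarray(kept)


def threshold_voltage(sweep: Sweep, spike_time_ms: float,
                      dvdt_threshold: float = 20.0,
                      search_back_ms: float = 5.0) -> Optional[float]:
    """Voltage at the first sample of the ascending phase where dV/dt
    exceeds ``dvdt_threshold`` mV/ms (3-point central difference)."""
    v = sweep.values
    sr = sweep.sampling_rate
    i_sp = sweep.idx(spike_time_ms)
    i0 = max(1, i_sp - int(round(search_back_ms * sr)))
    dvdt = (v[2:] - v[:-2]) * sr / 2.0  # central difference, mV/ms
    for i in range(i0, min(i_sp + 1, len(v) - 1)):
        if dvdt[i - 1] > dvdt_threshold:
            return float(v[i])
    return None


def analyze_excitability(steps: list[Sweep], step_duration_ms: float = 500.0,
                         dvdt_threshold: float = 20.0) -> ExcitabilityResult:
    """F-I curve, rheobase and spike threshold from a current-step family.

    Sweeps must carry ``injected_pA`` metadata and be ordered by injected
    current.  Rheobase is the first step current eliciting at least one
    spike; if no step spikes it is flagged as None rather than raising.
    """
    if not steps:
        raise ParameterError("no sweeps given")
    currents = [s.meta.get("injected_pA") for s in steps]
    if any(c is None for c in currents):
        raise ParameterError("sweeps must carry 'injected_pA' metadata")

    resting = np.nan
    for s in steps:
        if s.meta["injected_pA"] == 0 and "baseline" in s.epochs:
            resting = float(s.epoch_values("baseline").mean())
            break

    fi, spike_times = [], {}
    rheobase = None
    vthresh = None
    for s in steps:
        I = float(s.meta["injected_pA"])
        st = detect_spikes(s)
        spike_times[I] = list(st)
        n = len(st)
        fi.append((I, n, n / (step_duration_ms / 1000.0)))
        if n > 0 and rheobase is None:
            rheobase = I
            vthresh = threshold_voltage(s, st[0], dvdt_threshold)
    return ExcitabilityResult(resting_potential=resting, fi_curve=fi,
                              rheobase=rheobase, threshold_voltage=vthresh,
                              spike_times=spike_times)
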