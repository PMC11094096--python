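"""Bi-exponential synaptic kernels and their closed-form properties.

The canonical kernel is the difference of exponentials

    g(t) = c * (exp(-t / tau_decay) - exp(-t / tau_rise)),   t >= 0

with ``tau_decay > tau_rise > 0``.  Two amplitude conventions are used:

* *coefficient* (``c``): the analytic charge is simply ``c * (tau_decay -
  tau_rise)`` and the late decay follows ``c * exp(-t / tau_decay)``;
* *peak*: ``c`` is rescaled so that the kernel maximum equals the requested
  amplitude.  This is the convention of the trace generators, so a planted
  "40 pA" event really peaks at 40 pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterError


@dataclass(frozen=True)
class KernelSpec:
    """Bi-exponential kernel parameters (amplitude is the *peak*, in pA)."""

    amp: float
    tau_rise: float  # ms
    tau_decay: float  # ms

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ParameterError("need tau_decay > tau_rise > 0")

    @property
    def t_peak(self) -> float:
        """Time of the kernel maximum, ms."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def peak_factor(self) -> float:
        """Value of the unit-coefficient kernel at its peak."""
        tp = self.t_peak
        return np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise)

    @property
    def coeff(self) -> float:
        """Coefficient c such that the kernel peaks at ``amp``."""
        return self.amp / self.peak_factor

    @property
    def length(self) -> float:
        """Support length used when rendering: rise + 5 decay constants, ms."""
        return self.tau_rise + 5.0 * self.tau_decay

    def charge(self) -> float:
        """Analytic area under the kernel, fC (== coeff * (tau_d - tau_r))."""
        return self.coeff * (self.tau_decay - self.tau_rise)

    def waveform(self, sampling_rate: float, duration: float | None = None) -> np.ndarray:
        """Sample the kernel at ``sampling_rate`` kHz from t=0."""
        if duration is None:
            duration = self.length
        t = np.arange(0.0, duration, 1.0 / sampling_rate)
        return self.coeff * (np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise))

    def mean_over_window(self, t0: float, t1: float) -> float:
        """Analytic mean of the kernel over the time window [t0, t1] ms."""
        if t1 <= t0:
            raise ParameterError("need t1 > t0")
        tr, td = self.tau_rise, self.tau_decay

        def integral(tau):
            return tau * (np.exp(-t0 / tau) - np.exp(-t1 / tau))

        return self.coeff * (integral(td) - integral(tr)) / (t1 - t0)


def biexp(t: np.ndarray, amp: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Peak-normalized bi-exponential evaluated at times ``t`` (ms, t<0 -> 0)."""
    spec = KernelSpec(amp, tau_rise, tau_decay)
    t = np.asarray(t, dtype=float)
    out = spec.coeff * (np.exp(-np.maximum(t, 0) / tau_decay)
                        - np.exp(-np.maximum(t, 0) / tau_rise))
    return np.where(t < 0, 0.0, out)
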