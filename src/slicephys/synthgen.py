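"""Synthetic ground-truth generators for every pipeline input.

Each generator is fully determined by ``(config, seed)`` and returns the
synthetic object together with a :class:`~slicephys.core.GroundTruth` record
of everything that was planted, so downstream analyses can be validated
without any external data.

Default parameter values mirror the recording conditions of the study this
pipeline emulates: 20 kHz digitization, 10 mV hyperpolarizing membrane-test
steps, 500 ms current steps from -25 to 250 pA in 25 pA increments, paired
pulses 50 ms apart, and synaptic kernels typical for CA1 pyramidal cells
(AMPA tau_r = 0.5 ms / tau_d = 5 ms; NMDA tau_r = 5 ms / tau_d = 80 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import GroundTruth, ImageStack, ParameterError, Sweep
from .kernels import KernelSpec
from .morphology import MorphTree

# planted events are kept at least this far apart so single-event windows
# (e.g. the 22-27 ms NMDA readout) stay well-posed; configurable per call
DEFAULT_REFRACTORY_MS = 2.0


@dataclass
class MembraneParams:
    Rm: float = 190.0    # MOhm
    Rs: float = 10.0     # MOhm
    Cm: float = 200.0    # pF
    Vrest: float = -70.0  # mV
    Vth: float = -50.0    # mV

    def validate(self):
        if min(self.Rm, self.Rs, self.Cm) <= 0:
            raise ParameterError("Rm, Rs and Cm must be positive")


@dataclass
class SimConfig:
    """Shared configuration for the trace generators."""

    seed: int = 0
    sampling_rate: float = 20.0     # kHz
    duration: float = 60_000.0      # ms
    noise_sd: float = 8.0           # pA, Gaussian
    event_rate: float = 5.0         # Hz
    ampa_kernel: KernelSpec = field(default_factory=lambda: KernelSpec(40.0, 0.5, 5.0))
    nmda_kernel: KernelSpec = field(default_factory=lambda: KernelSpec(10.0, 5.0, 80.0))
    # release-site multiplicity k per event: "single" -> k = 1 (mEPSC-like),
    # "one_plus_poisson" -> k = 1 + Poisson(multiplicity_mean)
    multiplicity: str = "single"
    multiplicity_mean: float = 1.0
    refractory_ms: float = DEFAULT_REFRACTORY_MS
    membrane: MembraneParams = field(default_factory=MembraneParams)

    def validate(self):
        if self.noise_sd < 0 or self.event_rate < 0:
            raise ParameterError("noise_sd and event_rate must be non-negative")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ParameterError("sampling_rate and duration must be positive")
        self.membrane.validate()


def _rngs(seed: int, n: int):
    """Deterministic independent sub-streams for one simulation call."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# membrane test
# ---------------------------------------------------------------------------

def simulate_membrane_test(cfg: SimConfig, step_mV: float = -10.0,
                           baseline_ms: float = 50.0, step_ms: float = 50.0,
                           post_ms: float = 25.0) -> tuple[Sweep, GroundTruth]:
    """Two-compartment RC response to a hyperpolarizing voltage step.

    The pipette series resistance Rs and membrane Rm/Cm give an
    instantaneous current jump of ``V / Rs`` relaxing with
    ``tau = Cm * (Rs * Rm / (Rs + Rm))`` to the steady state
    ``V / (Rs + Rm)``.  The step onset falls exactly on a sample, so the
    first in-step sample carries the full analytic peak.
    """
    cfg.validate()
    m = cfg.membrane
    (rng,) = _rngs(cfg.seed, 1)
    sr = cfg.sampling_rate
    n_base = int(round(baseline_ms * sr))
    n_step = int(round(step_ms * sr))
    n_post = int(round(post_ms * sr))

    Rt = m.Rs + m.Rm
    tau = m.Cm * (m.Rs * m.Rm / Rt) * 1e-3  # pF * MOhm = us -> ms
    I_ss = step_mV / Rt * 1e3               # mV / MOhm = nA -> pA
    I_pk = step_mV / m.Rs * 1e3

    t_step = np.arange(n_step) / sr
    current = np.zeros(n_base + n_step + n_post)
    current[n_base:n_base + n_step] = I_ss + (I_pk - I_ss) * np.exp(-t_step / tau)
    # relaxation back after the step (mirror transient, off-step)
    t_post = np.arange(n_post) / sr
    current[n_base + n_step:] = -(I_pk - I_ss) * np.exp(-t_post / tau)
    current += rng.normal(0.0, cfg.noise_sd, current.size)

    sweep = Sweep(
        current, sr, units="pA",
        epochs={"baseline": (0.0, baseline_ms),
                "step": (baseline_ms, baseline_ms + step_ms),
                "post": (baseline_ms + step_ms, baseline_ms + step_ms + post_ms)},
        holding_potential=m.Vrest,
        meta={"step_mV": step_mV},
    )
    gt = GroundTruth(params={
        "Rt_MOhm": Rt, "Rs_MOhm": m.Rs, "Rm_MOhm": m.Rm,
        "Cm_pF": m.Cm, "tau_ms": tau,
        "Is_pA": abs(I_ss), "Ip_pA": abs(I_pk), "step_mV": abs(step_mV),
    })
    return sweep, gt


# ---------------------------------------------------------------------------
# current steps / LIF excitability
# ---------------------------------------------------------------------------

_AP_RISE_MS = 0.3   # stereotyped action-potential upstroke Vth -> +30 mV
_AP_FALL_MS = 1.0
_AP_PEAK_MV = 30.0


def simulate_current_steps(cfg: SimConfig, step_ms: float = 500.0,
                           currents_pA: np.ndarray | None = None,
                           baseline_ms: float = 100.0,
                           refractory_ms: float = 2.0,
                           noise_sd_mV: float = 0.0) -> tuple[list[Sweep], GroundTruth]:
    """Leaky integrate-and-fire voltage responses to a family of current steps.

    One 500 ms sweep per injected current (-25 ... 250 pA by default, 25 pA
    increments).  Spikes are pasted as a stereotyped waveform (fast linear
    upstroke to +30 mV, decay back to rest) so downstream threshold and
    spike detection operate on realistic dV/dt profiles.
    """
    cfg.validate()
    m = cfg.membrane
    if m.Vth <= m.Vrest:
        raise ParameterError("Vth must exceed Vrest")
    if currents_pA is None:
        currents_pA = np.arange(-25.0, 250.0 + 1e-9, 25.0)
    (rng,) = _rngs(cfg.seed, 1)

    sr = cfg.sampling_rate
    dt = 1.0 / sr
    tau_m = m.Rm * m.Cm * 1e-3  # ms
    n_base = int(round(baseline_ms * sr))
    n_step = int(round(step_ms * sr))
    n_rise = max(1, int(round(_AP_RISE_MS * sr)))
    n_fall = max(1, int(round(_AP_FALL_MS * sr)))
    upstroke = np.linspace(m.Vth, _AP_PEAK_MV, n_rise + 1)[1:]
    downstroke = np.linspace(_AP_PEAK_MV, m.Vrest, n_fall + 1)[1:]
    ap_wave = np.concatenate([upstroke, downstroke])
    n_refr = int(round(refractory_ms * sr))

    sweeps, spikes = [], {}
    for I in currents_pA:
        n_tot = n_base + n_step + n_base
        v = np.full(n_tot, float(m.Vrest))
        st = []
        i = n_base
        while i < n_base + n_step:
            dv = ((m.Vrest - v[i - 1]) / tau_m + I * m.Rm * 1e-3 / tau_m) * dt
            v[i] = v[i - 1] + dv
            # fire at threshold within a tiny tolerance so the boundary
            # current (asymptote exactly at Vth) spikes after finite latency
            if v[i] >= m.Vth - 1e-6:
                st.append(i * dt)
                seg = ap_wave[: n_tot - i]
                v[i:i + seg.size] = seg
                i_end = min(i + ap_wave.size + n_refr, n_tot)
                v[i + seg.size:i_end] = m.Vrest
                i = i_end
            else:
                i += 1
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, v.size)
        sweeps.append(Sweep(
            v, sr, units="mV",
            epochs={"baseline": (0.0, baseline_ms),
                    "step": (baseline_ms, baseline_ms + step_ms)},
            meta={"injected_pA": float(I)},
        ))
        spikes[float(I)] = st

    rheo_analytic = (m.Vth - m.Vrest) / m.Rm * 1e3  # pA
    gt = GroundTruth(spike_times=spikes, params={
        "rheobase_analytic_pA": rheo_analytic,
        "Vth_mV": m.Vth, "Vrest_mV": m.Vrest,
        "currents_pA": list(map(float, currents_pA)),
    })
    return sweeps, gt


# ---------------------------------------------------------------------------
# spontaneous / miniature event traces
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate_hz: float, duration_ms: float, refractory_ms: float):
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    times = np.sort(rng.uniform(0.0, duration_ms, n))
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_ms:
            kept.append(t)
            last = t
    return np.asarray(kept)


def _draw_multiplicity(rng, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.multiplicity == "single":
        return np.ones(n, dtype=int)
    if cfg.multiplicity == "one_plus_poisson":
        return 1 + rng.poisson(cfg.multiplicity_mean, n)
    raise ParameterError(f"unknown multiplicity model {cfg.multiplicity!r}")


def simulate_event_trace(cfg: SimConfig, mode: str = "mEPSC") -> tuple[Sweep, GroundTruth]:
    """Poisson train of quantal synaptic events on Gaussian noise.

    ``mode`` selects the event composition: ``"mEPSC"`` plants single quanta
    (k = 1), ``"sEPSC"`` draws a release-site count k per event from the
    configured multiplicity model and sums k quantal AMPA kernels, and
    ``"dual"`` additionally adds the slow NMDA kernel (Mg-free condition).
    Inward currents are negative-going; the ground truth records onset
    times, per-event k, true peak magnitudes, and per-component charges.
    """
    cfg.validate()
    if mode not in ("mEPSC", "sEPSC", "dual"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng_t, rng_k, rng_n = _rngs(cfg.seed, 3)

    sr = cfg.sampling_rate
    n_tot = int(round(cfg.duration * sr))
    times = _poisson_times(rng_t, cfg.event_rate, cfg.duration, cfg.refractory_ms)
    if mode == "mEPSC":
        ks = np.ones(times.size, dtype=int)
    else:
        ks = _draw_multiplicity(rng_k, cfg, times.size)

    # render to 10 decay constants so late-window measurements (e.g. the
    # 22-27 ms post-peak readout) see the untruncated tail
    def _render(k):
        return k.waveform(sr, k.tau_rise + 10.0 * k.tau_decay)

    ampa_wave = _render(cfg.ampa_kernel)
    nmda_wave = _render(cfg.nmda_kernel) if mode == "dual" else None
    kern_len_ms = (cfg.nmda_kernel.length if mode == "dual" else cfg.ampa_kernel.length)

    trace = np.zeros(n_tot)
    edge = []
    for t, k in zip(times, ks):
        i0 = int(round(t * sr))
        seg = ampa_wave[: n_tot - i0]
        trace[i0:i0 + seg.size] -= k * seg
        if nmda_wave is not None:
            seg = nmda_wave[: n_tot - i0]
            trace[i0:i0 + seg.size] -= k * seg
        edge.append(bool(t + kern_len_ms > cfg.duration))
    trace += rng_n.normal(0.0, cfg.noise_sd, n_tot)

    peak_amp = cfg.ampa_kernel.amp + (cfg.nmda_kernel.mean_over_window(
        cfg.ampa_kernel.t_peak - 0.5, cfg.ampa_kernel.t_peak + 0.5) if mode == "dual" else 0.0)
    charges = {"ampa": cfg.ampa_kernel.charge()}
    if mode == "dual":
        charges["nmda"] = cfg.nmda_kernel.charge()
    gt = GroundTruth(
        event_times=list(times),
        event_k=list(map(int, ks)),
        event_edge_flag=edge,
        true_peak_amps=[float(k * peak_amp) for k in ks],
        true_charges={c: q for c, q in charges.items()},
        params={"mode": mode, "quantal_peak_pA": peak_amp},
    )
    sweep = Sweep(trace, sr, units="pA", holding_potential=-70.0,
                  meta={"condition": mode})
    return sweep, gt


# ---------------------------------------------------------------------------
# evoked input-output series and paired pulses
# ---------------------------------------------------------------------------

@dataclass
class EvokedConfig:
    stimuli_uA: tuple = tuple(np.arange(10.0, 100.0 + 1e-9, 10.0))
    max_pA: float = 800.0       # sigmoid saturation of the true EPSC peak
    half_uA: float = 45.0       # stimulus at half-maximal response
    slope_uA: float = 12.0
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec(1.0, 1.0, 8.0))
    artifact_pA: float = 400.0  # biphasic stimulus artifact amplitude
    artifact_ms: float = 0.2
    ppr: float = 1.0            # planted A2/A1 for paired-pulse mode
    isi_ms: float = 50.0
    n_repeats: int = 6
    baseline_ms: float = 20.0
    tail_ms: float = 80.0


def _true_peak(ev: EvokedConfig, s: float) -> float:
    return ev.max_pA / (1.0 + np.exp(-(s - ev.half_uA) / ev.slope_uA))


def _render_evoked(sr, ev, stim_times_ms, peaks_pA, duration_ms, rng, noise_sd):
    n = int(round(duration_ms * sr))
    trace = np.zeros(n)
    n_art = max(1, int(round(ev.artifact_ms * sr)))
    for t0, pk in zip(stim_times_ms, peaks_pA):
        i0 = int(round(t0 * sr))
        art = ev.artifact_pA * np.concatenate([np.ones(n_art), -np.ones(n_art)])
        seg = art[: n - i0]
        trace[i0:i0 + seg.size] += seg
        wave = replace(ev.kernel, amp=pk).waveform(sr)
        i1 = i0 + 2 * n_art  # EPSC starts after the brief artifact
        seg = wave[: n - i1]
        trace[i1:i1 + seg.size] -= seg
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, n)
    return trace


def simulate_evoked_series(cfg: SimConfig, ev: EvokedConfig | None = None,
                           paired: bool = False) -> tuple[list[Sweep], GroundTruth]:
    """Evoked compound EPSCs: input-output series or 50 ms paired pulses.

    In input-output mode one sweep per stimulus strength is produced, the
    true peak following the configured sigmoid.  In paired mode
    ``n_repeats`` sweeps of two half-maximal EPSCs 50 ms apart with planted
    A2/A1 are produced.
    """
    cfg.validate()
    ev = ev or EvokedConfig()
    (rng,) = _rngs(cfg.seed, 1)
    sr = cfg.sampling_rate

    sweeps = []
    if paired:
        a1 = ev.max_pA / 2.0
        a2 = ev.ppr * a1
        dur = ev.baseline_ms + ev.isi_ms + ev.tail_ms
        stim_times = (ev.baseline_ms, ev.baseline_ms + ev.isi_ms)
        for _ in range(ev.n_repeats):
            tr = _render_evoked(sr, ev, stim_times, (a1, a2), dur, rng, cfg.noise_sd)
            sweeps.append(Sweep(tr, sr, units="pA",
                                epochs={"stim1": (stim_times[0], stim_times[0] + 1.0),
                                        "stim2": (stim_times[1], stim_times[1] + 1.0)},
                                meta={"paired": True}))
        gt = GroundTruth(params={"A1_pA": a1, "A2_pA": a2, "ppr": ev.ppr,
                                 "isi_ms": ev.isi_ms})
    else:
        peaks = [_true_peak(ev, s) for s in ev.stimuli_uA]
        dur = ev.baseline_ms + ev.tail_ms
        for s, pk in zip(ev.stimuli_uA, peaks):
            tr = _render_evoked(sr, ev, (ev.baseline_ms,), (pk,), dur, rng, cfg.noise_sd)
            sweeps.append(Sweep(tr, sr, units="pA",
                                epochs={"stim1": (ev.baseline_ms, ev.baseline_ms + 1.0)},
                                meta={"stimulus_uA": float(s)}))
        gt = GroundTruth(params={"stimuli_uA": list(ev.stimuli_uA),
                                 "true_peaks_pA": peaks})
    return sweeps, gt


# ---------------------------------------------------------------------------
# tonic current / drug block
# ---------------------------------------------------------------------------

def simulate_tonic_block(cfg: SimConfig, step_pA: float = 20.0,
                         drug_time_ms: float | None = None,
                         baseline_pA: float = -50.0,
                         noise_sd_after: float | None = None,
                         event_rate_hz: float = 1.0) -> tuple[Sweep, GroundTruth]:
    """Holding-current trace with a step change at drug application.

    A tonic inward current of magnitude ``step_pA`` holds the pre-drug
    current ``step_pA`` more negative than ``baseline_pA``; at
    ``drug_time_ms`` the blocker removes it and the holding current relaxes
    to ``baseline_pA``, while the noise SD may change to
    ``noise_sd_after``.  Sparse synaptic events are superimposed on both
    sides so event-free region selection is exercised.
    """
    cfg.validate()
    if drug_time_ms is None:
        drug_time_ms = cfg.duration / 2.0
    rng_t, rng_n = _rngs(cfg.seed, 2)
    sr = cfg.sampling_rate
    n = int(round(cfg.duration * sr))
    i_drug = int(round(drug_time_ms * sr))
    sd_after = cfg.noise_sd if noise_sd_after is None else noise_sd_after

    trace = np.full(n, float(baseline_pA))
    trace[:i_drug] -= step_pA
    trace[:i_drug] += rng_n.normal(0.0, cfg.noise_sd, i_drug)
    trace[i_drug:] += rng_n.normal(0.0, sd_after, n - i_drug)

    times = _poisson_times(rng_t, event_rate_hz, cfg.duration, cfg.refractory_ms)
    wave = cfg.ampa_kernel.waveform(sr)
    for t in times:
        i0 = int(round(t * sr))
        seg = wave[: n - i0]
        trace[i0:i0 + seg.size] -= seg

    sweep = Sweep(trace, sr, units="pA", meta={"drug_time_ms": drug_time_ms})
    gt = GroundTruth(event_times=list(times), params={
        "step_pA": step_pA, "drug_time_ms": drug_time_ms,
        "noise_sd_before": cfg.noise_sd, "noise_sd_after": sd_after,
    })
    return sweep, gt


# ---------------------------------------------------------------------------
# fluorescence stacks
# ---------------------------------------------------------------------------

@dataclass
class StackConfig:
    shape: tuple = (12, 256, 256)        # (z, y, x)
    pixel_size_xy: float = 0.0656        # um/px (67.2 um field at 1024 px)
    z_step: float = 0.25                 # um
    n_pairs: int = 20
    overlap_fraction: float = 1.0        # fraction of pairs planted colocalized
    radius_px: float = 5.0               # punctum disk radius
    oversize_radius_px: float = 12.0
    n_oversize: int = 0                  # extra colocalized pairs beyond 1.2 um^2
    undersize_radius_px: float = 2.0
    n_undersize: int = 0                 # extra colocalized pairs below 0.1 um^2
    amplitude: float = 3000.0
    background_slope: float = 100.0      # linear gradient range across the field
    noise_sd: float = 15.0
    min_sep_px: float = 28.0


def simulate_puncta_stack(cfg: SimConfig, sc: StackConfig | None = None
                          ) -> tuple[ImageStack, GroundTruth]:
    """Two-channel stack of disk-shaped puncta with controllable overlap.

    Pre- and postsynaptic puncta are rendered as crisp disks (replicated
    across z) on a smooth background gradient with Gaussian noise.
    Colocalized pairs share a center; non-colocalized pairs are displaced
    beyond the separation floor.  Ground truth records per-pair centers,
    areas (um^2), colocalization and size-exclusion flags.
    """
    sc = sc or StackConfig()
    (rng,) = _rngs(cfg.seed, 1)
    nz, ny, nx = sc.shape
    pre = np.zeros((nz, ny, nx))
    post = np.zeros((nz, ny, nx))

    # jittered grid of candidate centers with guaranteed separation
    pitch = sc.min_sep_px
    margin = sc.oversize_radius_px + 4
    ys = np.arange(margin, ny - margin, pitch)
    xs = np.arange(margin, nx - margin, pitch)
    grid = [(y, x) for y in ys for x in xs]
    rng.shuffle(grid)
    n_total = sc.n_pairs + sc.n_oversize + sc.n_undersize
    if len(grid) < n_total * 2:
        raise ParameterError("field too small for requested puncta count")

    yy, xx = np.mgrid[0:ny, 0:nx]

    def stamp(img, cy, cx, r):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[:, disk] += sc.amplitude
        return int(disk.sum())

    planted = []
    gi = iter(grid)
    n_coloc = int(round(sc.overlap_fraction * sc.n_pairs))
    for j in range(sc.n_pairs):
        cy, cx = next(gi)
        coloc = j < n_coloc
        area_px = stamp(pre, cy, cx, sc.radius_px)
        if coloc:
            stamp(post, cy, cx, sc.radius_px)
        else:
            cy2, cx2 = next(gi)
            stamp(post, cy2, cx2, sc.radius_px)
        planted.append({
            "center": (float(cy), float(cx)),
            "area_um2": area_px * sc.pixel_size_xy ** 2,
            "colocalized": bool(coloc),
            "oversize": False,
        })
    for n_extra, radius in ((sc.n_oversize, sc.oversize_radius_px),
                            (sc.n_undersize, sc.undersize_radius_px)):
        for _ in range(n_extra):
            cy, cx = next(gi)
            area_px = stamp(pre, cy, cx, radius)
            stamp(post, cy, cx, radius)
            area = area_px * sc.pixel_size_xy ** 2
            planted.append({
                "center": (float(cy), float(cx)),
                "area_um2": area,
                "colocalized": True,
                "oversize": area > 1.2 or area < 0.1,
            })

    gradient = sc.background_slope * (xx / nx + yy / ny) / 2.0
    for img in (pre, post):
        img += gradient
        img += rng.normal(0.0, sc.noise_sd, img.shape)
        np.clip(img, 0.0, None, out=img)

    stack = ImageStack({"pre": pre, "post": post},
                       pixel_size_xy=sc.pixel_size_xy, z_step=sc.z_step)
    gt = GroundTruth(planted_puncta=planted, params={
        "n_colocalized_in_range": sum(1 for p in planted
                                      if p["colocalized"] and not p["oversize"]),
    })
    return stack, gt


@dataclass
class BlobConfig:
    shape: tuple = (24, 128, 128)
    pixel_size_xy: float = 0.5
    z_step: float = 1.0
    n_blobs: int = 5
    radius_px: float = 10.0     # lateral soma radius (5 um at defaults)
    amplitude: float = 2000.0
    noise_sd: float = 15.0


def simulate_cell_stack(cfg: SimConfig, bc: BlobConfig | None = None
                        ) -> tuple[ImageStack, GroundTruth]:
    """3D stack of non-touching ellipsoidal somata for cell counting."""
    bc = bc or BlobConfig()
    (rng,) = _rngs(cfg.seed, 1)
    nz, ny, nx = bc.shape
    img = np.zeros((nz, ny, nx))
    # axial radius in voxels so the soma is spherical in physical units
    rz = max(2.0, bc.radius_px * bc.pixel_size_xy / bc.z_step)
    margin = int(bc.radius_px) + 2
    pitch = 4 * bc.radius_px
    grid = [(y, x) for y in np.arange(margin, ny - margin, pitch)
            for x in np.arange(margin, nx - margin, pitch)]
    rng.shuffle(grid)
    if len(grid) < bc.n_blobs:
        raise ParameterError("field too small for requested blob count")
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    centers = []
    for (cy, cx) in grid[: bc.n_blobs]:
        cz = rng.uniform(rz + 1, nz - rz - 1)
        ell = (((zz - cz) / rz) ** 2 + ((yy - cy) / bc.radius_px) ** 2
               + ((xx - cx) / bc.radius_px) ** 2) <= 1.0
        img[ell] += bc.amplitude
        centers.append((float(cz), float(cy), float(cx)))
    img += rng.normal(0.0, bc.noise_sd, img.shape)
    np.clip(img, 0.0, None, out=img)
    stack = ImageStack({"cells": img}, pixel_size_xy=bc.pixel_size_xy, z_step=bc.z_step)
    gt = GroundTruth(params={"n_blobs": bc.n_blobs, "centers": centers})
    return stack, gt


def simulate_uptake_stack(cfg: SimConfig, shape=(9, 128, 128),
                          pixel_size_xy: float = 0.0656, z_step: float = 0.25,
                          glia_radius_px: float = 40.0,
                          n_inside: int = 12, n_outside: int = 8,
                          punctum_radius_px: float = 3.0,
                          amplitude: float = 2000.0, noise_sd: float = 10.0
                          ) -> tuple[ImageStack, GroundTruth]:
    """Glial-soma channel plus a puncta channel split inside/outside the mask."""
    (rng,) = _rngs(cfg.seed, 1)
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    cy, cx = ny // 2, nx // 2
    glia_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= glia_radius_px ** 2
    glia = np.where(glia_mask, amplitude, 0.0)

    puncta = np.zeros(shape)
    pv = 0
    placed = 0
    while placed < n_inside:
        py = rng.uniform(cy - glia_radius_px, cy + glia_radius_px)
        px = rng.uniform(cx - glia_radius_px, cx + glia_radius_px)
        if (py - cy) ** 2 + (px - cx) ** 2 > (glia_radius_px - punctum_radius_px - 1) ** 2:
            continue
        pz = rng.integers(1, nz - 1)
        d = ((zz - pz) ** 2 <= 1) & ((yy - py) ** 2 + (xx - px) ** 2 <= punctum_radius_px ** 2)
        pv += int((d & glia_mask).sum())
        puncta[d] = amplitude
        placed += 1
    placed = 0
    while placed < n_outside:
        py, px = rng.uniform(0, ny), rng.uniform(0, nx)
        if (py - cy) ** 2 + (px - cx) ** 2 < (glia_radius_px + punctum_radius_px + 2) ** 2:
            continue
        pz = rng.integers(1, nz - 1)
        d = ((zz - pz) ** 2 <= 1) & ((yy - py) ** 2 + (xx - px) ** 2 <= punctum_radius_px ** 2)
        puncta[d] = amplitude
        placed += 1

    for img in (glia, puncta):
        img += rng.normal(0.0, noise_sd, img.shape)
        np.clip(img, 0.0, None, out=img)
    stack = ImageStack({"glia": glia, "puncta": puncta},
                       pixel_size_xy=pixel_size_xy, z_step=z_step)
    true_fraction = 100.0 * pv / int(glia_mask.sum())
    gt = GroundTruth(params={"volume_fraction_pct": true_fraction,
                             "glia_voxels": int(glia_mask.sum())})
    return stack, gt


# ---------------------------------------------------------------------------
# morphology trees
# ---------------------------------------------------------------------------

@dataclass
class TreeConfig:
    n_stems: int = 4
    max_depth: int = 3
    branch_prob: float = 0.7
    segment_length_um: tuple = (20.0, 60.0)   # uniform range per branch
    node_spacing_um: float = 5.0
    spines_per_segment: tuple = (5, 15)
    spine_length_um: tuple = (0.5, 2.5)


def simulate_tree(cfg: SimConfig, tc: TreeConfig | None = None,
                  sholl_step: float = 20.0) -> tuple[MorphTree, GroundTruth]:
    """Random outward-growing dendritic tree in SWC node form.

    Branch directions are constrained so the radial distance from the soma
    increases monotonically along every straight inter-node segment (the
    natural geometry of dendritic growth), and total cable length and
    per-radius sphere crossings are recorded as ground truth.
    """
    tc = tc or TreeConfig()
    (rng,) = _rngs(cfg.seed, 1)

    nodes = [dict(id=1, type=1, x=0.0, y=0.0, z=0.0, radius=5.0, parent=-1)]
    next_id = [2]

    def rand_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def grow(parent_idx, direction, depth):
        length = rng.uniform(*tc.segment_length_um)
        n_seg = max(2, int(round(length / tc.node_spacing_um)))
        step = length / n_seg
        p = np.array([nodes[parent_idx]["x"], nodes[parent_idx]["y"], nodes[parent_idx]["z"]])
        pid = nodes[parent_idx]["id"]
        for _ in range(n_seg):
            d = direction + 0.25 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            # keep growth outward: ||p|| must be non-decreasing along the segment
            if np.dot(p, d) < 0:
                d = d - 2 * np.dot(p, d) * p / max(np.dot(p, p), 1e-12)
                d /= np.linalg.norm(d)
            q = p + step * d
            nodes.append(dict(id=next_id[0], type=3, x=q[0], y=q[1], z=q[2],
                              radius=0.5, parent=pid))
            pid = next_id[0]
            next_id[0] += 1
            p = q
            direction = d
        tip_idx = len(nodes) - 1
        if depth < tc.max_depth and rng.uniform() < tc.branch_prob:
            for _ in range(2):
                d = direction + 0.8 * rng.normal(size=3)
                d /= np.linalg.norm(d)
                grow(tip_idx, d, depth + 1)

    for _ in range(tc.n_stems):
        grow(0, rand_dir(), 1)

    tree = MorphTree.from_records(nodes)
    # attach spines to random dendritic nodes
    n_spines = int(rng.integers(*tc.spines_per_segment))
    dend_ids = [n["id"] for n in nodes[1:]]
    spines = [{"attach_id": int(rng.choice(dend_ids)),
               "length_um": float(rng.uniform(*tc.spine_length_um))}
              for _ in range(n_spines)]
    tree.spines = spines

    total = tree.total_length()
    r_max = max(np.hypot(np.hypot(n["x"], n["y"]), n["z"]) for n in nodes)
    radii = np.arange(sholl_step, r_max + sholl_step, sholl_step)
    crossings = {float(r): _exact_crossings(nodes, r) for r in radii}
    gt = GroundTruth(tree_total_length=total, tree_crossings=crossings,
                     params={"n_nodes": len(nodes)})
    return tree, gt


def _exact_crossings(nodes, r: float) -> int:
    by_id = {n["id"]: n for n in nodes}
    count = 0
    for n in nodes:
        if n["parent"] == -1:
            continue
        p = by_id[n["parent"]]
        d1 = np.sqrt(p["x"] ** 2 + p["y"] ** 2 + p["z"] ** 2) - r
        d2 = np.sqrt(n["x"] ** 2 + n["y"] ** 2 + n["z"] ** 2) - r
        if d1 * d2 < 0:
            count += 1
    return count


def straight_tree(length_um: float = 90.0, spacing_um: float = 9.0) -> MorphTree:
    """Single straight radial branch along +x, useful as an exact fixture.

    Default node spacing avoids placing nodes exactly on the 20 um Sholl
    spheres (an exact touch counts as no crossing by the strict-sign rule).
    """
    nodes = [dict(id=1, type=1, x=0.0, y=0.0, z=0.0, radius=5.0, parent=-1)]
    xs = np.arange(spacing_um, length_um + 1e-9, spacing_um)
    for i, x in enumerate(xs, start=2):
        nodes.append(dict(id=i, type=3, x=float(x), y=0.0, z=0.0,
                          radius=0.5, parent=i - 1))
    return MorphTree.from_records(nodes)


def y_tree(stem_um: float = 30.0, daughter_um: float = 40.0,
           angle_deg: float = 30.0) -> MorphTree:
    """Stem splitting into two daughters, both tips beyond the stem radius."""
    a = np.deg2rad(angle_deg)
    nodes = [dict(id=1, type=1, x=0.0, y=0.0, z=0.0, radius=5.0, parent=-1),
             dict(id=2, type=3, x=stem_um, y=0.0, z=0.0, radius=0.5, parent=1)]
    tip1 = (stem_um + daughter_um * np.cos(a), daughter_um * np.sin(a))
    tip2 = (stem_um + daughter_um * np.cos(a), -daughter_um * np.sin(a))
    nodes.append(dict(id=3, type=3, x=tip1[0], y=tip1[1], z=0.0, radius=0.5, parent=2))
    nodes.append(dict(id=4, type=3, x=tip2[0], y=tip2[1], z=0.0, radius=0.5, parent=2))
    return MorphTree.from_records(nodes)
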