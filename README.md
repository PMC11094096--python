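# slicephys

Quantitative analysis of hippocampal slice electrophysiology and histology,
built for studies that profile CA1 pyramidal neurons across passive
membrane properties, excitability, synaptic transmission and morphology —
for example when comparing microglia-deficient (Csf1r ΔFIRE/ΔFIRE) mice
with wild-type littermates. Every analysis stage is paired with a
synthetic-data generator that records its ground truth, so the whole
pipeline is testable at desk scale without any recorded data.

## What it computes

**Passive membrane and excitability** (`slicephys.cellprops`). From a
10 mV membrane-test step: Rt = V/Is, Rs = V/Ip, and cell capacitance from
the transient decay constant, Cm = τ·(Is+Ip)²/(V·Is) (the two-compartment
convention Cm = τ/(Rs·Rm/(Rs+Rm)) is available as an option). From 500 ms
current steps (−25…250 pA, 25 pA increments): the F–I curve, rheobase (first
step with ≥1 spike) and spike threshold (first point with dV/dt > 20 mV/ms).

**Synaptic events** (`slicephys.synaptic`). Clements–Bekkers scaled-template
detection: at every lag the bi-exponential template is optimally scaled and
offset, and the detection criterion is scale/SD(residual) with threshold 4.
Summaries (inter-event interval, amplitude, mono-exponential decay τ), the
sEPSC/mEPSC multiplicity contrast, evoked input–output curves with 1 ms
artifact blanking, and paired-pulse ratio A2/A1 from six averaged traces.

**AMPA/NMDA decomposition** (`slicephys.dualcomp`). The NMDA component is
the onset-aligned subtraction of the average AMPA-only mEPSC from the
average mixed AMPA+NMDA mEPSC; charges are trapezoidal areas (fC) and the
headline statistic is the AMPA/NMDA charge ratio. Single-event analysis
measures the AMPA peak (1 ms window) and the NMDA component (22–27 ms
after the peak; |peak| ≥ 30 pA and ≥ 3×RMS noise inclusion), with ANCOVA
across groups. Tonic receptor currents come from 10 s holding-current
windows around drug application and RMS noise over ten event-free 100 ms
regions.

**Imaging** (`slicephys.imaging`). Median filter → max projection →
rolling-ball background subtraction (radius 10 px) → Otsu. Synapse counts
as 8-connected components of the pre AND post mask with size exclusion
(components outside 0.1–1.2 µm² discarded), glial coverage/intensity, the
ramification index P/(2√(πA)), 26-connected 3D cell counts, and astrocytic
synaptic-uptake volume fractions.

**Morphology** (`slicephys.morphology`). SWC trees, Sholl analysis
(sphere crossings at 20 µm increments, strict sign rule, with a
dense-sampling brute-force oracle), total cable length, and five-segment
spine density/length metrics.

**Statistics** (`slicephys.stats`, `slicephys.junction`). Assumption-routed
two-group tests (Anderson–Darling + Shapiro–Wilk + variance F-test → t-test,
else Mann–Whitney U), the sequential rank-multiplication p-value correction,
two-way ANOVA with Bonferroni post-hocs, exact noncentral-t power/sample
size, the novel-object discrimination index, ELISA normalization, and
liquid junction potentials via the generalized Henderson equation with an
editable limiting-mobility table.

## Worked example

```python
from slicephys import synthgen as sg
from slicephys.cellprops import measure_membrane_test
from slicephys.synaptic import detect_events_template, summarize_events

cfg = sg.SimConfig(seed=5, duration=60_000.0, event_rate=1.0, noise_sd=8.0)
sweep, truth = sg.simulate_event_trace(cfg, "mEPSC")
events = detect_events_template(sweep, cfg.ampa_kernel, criterion=4.0)
print(summarize_events(events))

mt_sweep, mt_truth = sg.simulate_membrane_test(sg.SimConfig(seed=0, noise_sd=0.0))
r = measure_membrane_test(mt_sweep)
print(f"Rt={r.Rt:.1f} MOhm Rs={r.Rs:.1f} MOhm tau={r.tau:.2f} ms Cm={r.Cm:.0f} pF")
```

prints

```
{'n_events': 58, 'mean_iei_ms': 1042.5..., 'median_iei_ms': 701.2...,
 'mean_amp_pA': 40.21..., 'mean_decay_tau_ms': 5.20...}
Rt=200.0 MOhm Rs=10.0 MOhm tau=1.90 ms Cm=4189 pF
```

The 60 s trace at 1 Hz planted 58 events; the detector recovers all of
them with the planted ~1 s inter-event interval, the 40 pA quantal
amplitude, and the planted 5 ms decay constant.
The membrane test recovers the planted Rt/Rs/τ exactly; note that Cm uses
the printed formula with Ip measured from baseline, which deliberately
differs from the two-compartment value (200 pF, available via
`cm_convention="two_compartment"`; see `docs/methods.md`).

The `analysis/` directory holds numbered drivers that run each stage on
two-cohort synthetic studies (control vs deficient) and write their tables
under `results/`.

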