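# Methods notes

This document records the models behind the synthetic-data generators, the
analysis conventions, the numerical choices, and the known limitations —
the information a maintainer needs to judge what a passing test suite does
and does not establish.

## Units and sign conventions

Time is in ms, sampling rates in kHz, currents in pA, voltages in mV,
charge in fC (pA·ms), image dimensions in px with explicit µm/px pixel
sizes. Inward (excitatory) currents are negative-going in raw traces;
analysis layers report magnitudes as positive numbers. The tonic
drug-sensitive current is signed so that a *blocked inward* standing
current reports positive.

## Synthetic-data generators (`synthgen`)

Every generator is a deterministic function of `(config, seed)`; per-call
sub-streams are spawned from a single `SeedSequence`, so outputs are
byte-identical across runs and platforms.

**Membrane test.** The whole-cell pipette/membrane circuit is the standard
two-compartment RC: a −10 mV step drives an instantaneous current `V/Rs`
relaxing with `τ = Cm·(Rs·Rm/(Rs+Rm))` to `V/(Rs+Rm)`. The step onset is
sample-aligned so the first in-step sample carries the full analytic peak
— this makes noiseless recovery exact rather than discretization-limited.
Defaults (Rs 10 MΩ, Rm 190 MΩ, Cm 200 pF) are typical for CA1 pyramidal
whole-cell recordings.

**Current steps.** A leaky integrate-and-fire neuron (Euler at the sampling
rate) driven by 500 ms steps from −25 to 250 pA in 25 pA increments.
Spikes are pasted as a stereotyped waveform (0.3 ms linear upstroke from
threshold to +30 mV, 1 ms decay to rest, then a refractory clamp), giving
realistic dV/dt profiles for threshold measurement. The threshold
comparison uses a 1 µV tolerance so the boundary current — whose voltage
asymptote sits exactly at threshold — fires after a long finite latency
instead of depending on floating-point accidents; the analytic minimal
sustained current `(Vth−Vrest)/Rm` is recorded as ground truth.

**Synaptic event trains.** Homogeneous Poisson onsets thinned to a 2 ms
refractory floor (keeps single-event windows well-posed; configurable).
Each event sums k quantal bi-exponential kernels: k = 1 for mEPSC-like
traces, k ~ 1 + Poisson(λ) for multivesicular sEPSC-like traces, and the
"dual" mode adds the slow NMDA kernel (the Mg²⁺-free condition). Kernel
amplitudes are *peak* amplitudes; the closed forms (charge
`c·(τd−τr)`, window means) use the corresponding coefficient. Defaults:
AMPA τr 0.5 ms / τd 5 ms at 40 pA; NMDA τr 5 ms / τd 80 ms at 10 pA —
values typical for CA1 and chosen so the 22–27 ms window isolates the NMDA
component. The default event rate is 1 Hz, the scale of CA1 mEPSC
inter-event intervals; kernels are rendered to 10 decay constants so
late-window measurements see the untruncated tail. Events within one
kernel length of the trace end are flagged in the ground truth.

**Evoked series.** True compound-EPSC peaks follow a logistic curve of
stimulus strength (default max 800 pA, half-activation 45 µA); each sweep
carries a brief biphasic stimulus artifact ahead of the EPSC. Paired mode
emits two half-maximal EPSCs 50 ms apart with a configured A2/A1, six
repeats by default.

**Image stacks.** Puncta are crisp disks replicated across z on a smooth
background gradient plus Gaussian noise, placed on a shuffled jittered grid
with a guaranteed separation floor; colocalized pairs share a center.
Oversize (>1.2 µm²) and undersize (<0.1 µm²) objects can be planted to
exercise the size-exclusion rule. Disk rendering (rather than Gaussian
spots) makes Otsu segmentation recover planted counts exactly, which is
what the count-recovery guarantees test; it does not emulate a real PSF.
A second generator plants non-touching ellipsoidal somata for 3D counting,
and a third builds a glial-soma mask with puncta planted inside/outside
for the uptake volume fraction.

**Trees.** Random dendritic trees grow outward from the soma with a
monotonicity constraint: along every straight inter-node segment the
distance to the soma is non-decreasing (`p·d ≥ 0` at each step). This is
the natural geometry of radial dendritic growth and guarantees that the
strict-sign crossing rule and the dense-sampling oracle agree exactly
(a chord that enters and exits a sphere between nodes cannot occur).

## Analysis conventions

**Membrane test.** Baseline = mean of the 50 ms before the step; steady
state = mean of the last quarter of the step; Ip = extremal in-step sample
relative to baseline; τ from a bounded nonlinear least-squares
mono-exponential fit starting 0.1 ms after the peak, initialized
log-linearly. Cm uses the printed formula `τ·(Is+Ip)²/(V·Is)` by default.
With Ip measured from *baseline* this deliberately differs from the
two-compartment derivation `τ/(Rs·Rm/(Rs+Rm))` (which the alternative
`cm_convention="two_compartment"` reproduces, recovering the generator's
planted Cm). Both conventions are exposed; neither is silently corrected.
Cells whose series resistance changes by more than 20 % are flagged for
exclusion, not dropped.

**Event detection.** Clements–Bekkers scaled-template matching with the
closed-form sliding fit computed by FFT convolution. The template is the
bi-exponential kernel at unit peak over rise + 5 decay constants; the
criterion is fitted scale / SD(residual), threshold 4 (the conventional
value; the original template-search tooling does not expose one). Detection takes one
event per suprathreshold excursion of the criterion, merging peaks closer
than max(rise time, 2 ms): at realistic noise the criterion bump around a
single event is ~2 ms wide and would otherwise split into doublets. The
residual SD is floored at 1e-6 so noiseless exact matches yield a large
finite criterion. Event peaks are the extremum of a 1 ms running mean
(matching the single-event AMPA-peak convention); decay τ is a bounded
mono-exponential fit from the raw peak. Operating point at peak/noise = 5
with the default configuration: sensitivity ≈ 0.99, FDR ≈ 0 (pooled over
20 × 60 s seeded traces). Known failure mode: two events closer than
~2 ms, or whose criterion excursions merge, yield one detection.

**Evoked analysis.** Peaks are measured against the pre-stimulus baseline
with a 1 ms post-stimulus blanking window. PPR averages the six traces
point-wise first; A2 is referenced to the local baseline in the 2 ms
before the second stimulus (decay-extrapolation subtraction is not
applied — at τd 8 ms and 50 ms ISI the first EPSC has decayed to <0.2 %).

**AMPA/NMDA decomposition.** Averages are built from ≥50 events (the
conventional minimum for stable averages; published workflows vary
between 50 and >100 events, so `min_n` is configurable), each snippet baseline-subtracted and re-aligned at the
first sample exceeding 10 % of its peak. Charges integrate the magnitude
waveform from onset to return-to-baseline (1 % of peak), capped at 500 ms
(truncation error <0.2 % for τd 80 ms). The peak and the return crossing
are located on a 1 ms running mean of the magnitude: a sharp subtraction
residual at the fast AMPA edge otherwise masquerades as the component
peak and collapses the integration window. On noisy averages the
magnitude-area estimator carries a positive bias of roughly
mean|noise|×window; averaging more events shrinks it.

**Single events.** AMPA peak = mean over the 1 ms window at the peak;
NMDA measurement = mean over 22–27 ms after the peak; inclusion requires
|peak| ≥ 30 pA ("≥ −30 pA" read as magnitude for inward currents) *and*
≥ 3× RMS noise (gate factor configurable). Events whose 27 ms window
collides with the next detected event are dropped; contamination from an
*undetected* close neighbor remains possible, which is why per-cell
summaries should prefer the median.

**Tonic current.** Ten 100 ms event-free regions per side (greedy scan,
±20 ms guard around detected events) provide the RMS noise; the
drug-sensitive current is the change in 10 s mean holding current. Descriptions
of this procedure sometimes conflate the mean holding current with the RMS
noise; here the RMS is unambiguously the SD over event-free regions per
side, with the before/after difference reported.

**Imaging.** Fixed order: per-plane 3×3 median → max projection →
rolling-ball radius 10 px (scikit-image's implementation of the named
algorithm) → Otsu. The additive mask is the AND of the per-channel Otsu
masks (`mask_mode="sum"` gives the sum-then-threshold reading);
8-connectivity in 2D, 26 in 3D; size bounds are inclusive at 0.1 and
1.2 µm² since the exclusion rule is strict (">1.2", "<0.1"). The
ramification index measures boundary length on marching-squares contours
simplified with 1 px tolerance — Crofton with 4 directions under-measures
corners (square RI 1.067 vs 2/√π ≈ 1.128) and the classic weighted
estimator over-measures disks (1.046 vs 1.00); the simplified-contour
estimator lands within 3 % on both reference shapes. Touching 3D somata
merged by a voxel bridge count as one object (no watershed). The manual
surface step of the original uptake workflow becomes a configured
threshold value.

**Sholl.** Crossings use the strict sign rule — an endpoint exactly on a
sphere counts as no crossing (deterministic choice for a measure-zero
case). Soma center is the root node; multi-node somas collapse to their
centroid. 3D spheres by default with a 2D-projection mode, since the
original stack-based workflow may have counted in projection. The
brute-force oracle samples segments at 0.01 µm and counts sign changes.

**Statistics.** The t-test route requires *both* normality tests
(Anderson–Darling via statsmodels' p-value approximation, Shapiro–Wilk)
to pass at α = 0.05 for both samples plus a two-sided variance F-test;
any failure routes to Mann–Whitney U. Zero-variance samples route
nonparametric (the normality tests are undefined there). Calibration:
type-I error 0.03–0.07 on 1000 null Gaussian replicates at n = 10. The
sequential correction multiplies the i-th smallest p by (N−i+1) and caps
at 1 — exactly the printed rule, without Holm's step-down monotonicity
pass (the printed rule and its worked behavior are internally consistent
only without it). Power uses the exact noncentral-t distribution; the
standard scenario (effect 50 %, SD 25 %, power 0.80, α 0.05) yields
n = 6 per group, with a seeded Monte-Carlo oracle bracketing n = 5/6.

**Junction potentials.** Generalized Henderson equation over all charged
species, reported as bath minus pipette (a K-gluconate internal against a
NaCl-rich bath reports positive, the pipette sitting negative). The
mobility table ships as editable YAML with standard limiting equivalent
conductances; HEPES enters at its pH 7.2 anionic fraction (pKa 7.5), EGTA
as the divalent anion, MgATP split into its ions, and phosphocreatine/
nucleotides/QX-314 carry generic large-ion mobilities. Temperature
defaults to 35 °C (heated slice bath). Computed values: 14.37 mV
(K-gluconate internal vs ACSF) and 3.53 mV (KCl internal vs ACSF);
agreement with tool-computed reference values is only expected within
~±1.5 mV because the exact mobilities behind such tools are internal to
them. `henderson_ljp(a,b) = −henderson_ljp(b,a)` holds exactly.

## What passing tests do and do not show

The generators plant idealized objects: white Gaussian recording noise
(no 1/f or line noise, no Rs drift), identical quanta (no amplitude
variability unless multiplicity is used), crisp disk puncta (no PSF,
no chromatic offset), and outward-monotone trees (no recurving
dendrites). Recovery guarantees on these conditions validate the
*algorithms* — estimator bias, operating characteristics at a stated SNR,
geometric exactness — not performance on real recordings, where template
mismatch, correlated noise and segmentation ambiguity dominate. The
group-difference patterns produced by the `analysis/` drivers are planted
effects used to demonstrate direction and machinery, not reproductions of
measured animal data.

## Problem sizes

Test and driver problem sizes (60 s traces, 15-cell cohorts, 50 random
trees, 256² stacks) were chosen as the smallest sizes at which the checked
statistics are stable; all are configurable upward.
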