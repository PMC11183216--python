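# Methods

This note documents the models and procedures implemented in `lamseiz`,
the parameters that matter, and what the synthetic validation does and
does not establish.

## Recording model and geometry

A laminar probe is modelled as 24 contacts at 150 µm pitch oriented
perpendicular to the cortical surface (contact 1 most superficial), with
a low-frequency LFP band sampled at 2 kHz and a high-frequency MUA band at
20 kHz. The default contact-to-layer partition assigns contacts 1–10 to
the supragranular group, 11–13 to granular, and 14–24 to infragranular —
roughly human cortical proportions at this pitch; the mapping is fully
configurable because no histological registration is available for
simulated data.

## CSD estimation

CSD is the second spatial difference of the monopolar potential profile,

    CSD_i(t) = (φ_{i−1}(t) − 2 φ_i(t) + φ_{i+1}(t)) / h²,   h = 0.15 mm,

with the sign convention that a potential minimum in depth (a current
sink) is **positive**. Edge contacts are handled by appending
pseudo-channels above and below the array; the default appends zeros
(`edge_mode="zeros"`), with the classical duplicate-edge variant
available. A 5-point Hamming window ([0.08, 0.54, 1, 0.54, 0.08],
normalized to unit sum; truncated and renormalized at the edges) smooths
the profile spatially. No conductivity is modelled, so CSD values are in
arbitrary units; all downstream statistics either normalize them (sinks
to [0, 1], sources to [−1, 0], min/max taken jointly over channels and
time within the annotated ictal interval) or compare them with a
same-units baseline.

The printed form of the min-max rescaling equation in the source
literature inverts the orientation (min→1); the implementation uses the
standard orientation (max→1), which is what the reported sink/source
values require, and exposes an `invert` flag reproducing the literal
formula. Zeros count toward the sink-side minimum so that e.g.
{0, 2, 4} → {0, 0.5, 1}.

## Synthetic seizure generator

The generator is an explicit forward model from prescribed CSD motifs to
LFP. Each motif is a zero-sum per-contact weight vector (current
conservation); its potential profile solves the tridiagonal system
`second-difference(φ) = motif` with zero virtual boundary potentials, i.e.
exactly the discrete inverse of the CSD estimator with zero edge padding.
Roundtrip (motif → potential → CSD) is therefore exact to machine
precision, which anchors the test suite.

**Discharge kernel.** Each discharge is biphasic: a raised-cosine main
lobe over 0–50 ms (peak at +25 ms) and a rebound lobe over 60–90 ms
(peak at +75 ms, relative amplitude 0.35) whose spatial profile is
sign-inverted. Every sink at the discharge peak thus becomes a source
50 ms later, with a configurable alternation probability (default 1).
Ground-truth discharge times refer to the main-lobe peak.

**Rates.** Discharge onsets follow an inhomogeneous renewal process with
dead time equal to the waveform duration (90 ms): after each event the
hazard is λ(t)/(1 − λ(t)·d), sampled by thinning, so the *realized* rate
equals the configured λ(t) (plain thinning with a refractory period would
bias a nominal 7.1 Hz down to ≈4.3 Hz). Configured rates above 1/d are
clamped at 95 % of the dead-time limit.

**Default onset-zone schedule.** Phase 1 lasts 5.3 s with a linear ramp
anchored so that the *mean* rate over the first second is 1.3 Hz and over
the last second 8.9 Hz (the convention in which ramping discharge
frequencies are reported); phase 2 lasts 57 s at a constant 7.1 Hz. The
two phases use different deep motifs: the initial motif places sinks in
the granular/upper-infragranular cortex and at the deepest contacts,
flanking a mid-infragranular source; the sustained motif is a
granular-plus-upper-infragranular sink over a source at the deepest
contacts. Supragranular weights are zero in both.

**Default propagation-zone schedule.** One 60 s phase at 7.1 Hz with a
supragranular motif (sink at contacts 2–4 over a source at 6–8) active
throughout; additional zero-sum layer-group components switch on at
fractions of normalized seizure time — granular at 28 %, infragranular at
42 %. The granular add-on is a contiguous block (+1, +1, −2 at contacts
11–13) with amplitude 0.9 relative to the supragranular weights: an
isolated one-contact dipole is diluted ≈5× by the 5-point Hamming filter
and its middle contact cancels, which would make the recruitment
invisible to the 2 SD engagement rule; the block amplitude is set so the
post-recruitment granular engagement is roughly half the supragranular
level, matching the reported relative magnitudes.

**Amplitude calibration.** Discharge amplitude is expressed as a
signal-to-noise ratio on the potential-gradient channels — where
detection operates — with default 10: the peak gradient amplitude of the
motif equals 10·√2·σ_pink (√2 being the gradient noise SD for independent
per-channel noise). In the noiseless case a unit reference amplitude is
used.

**Noise.** Independent per-channel 1/f (pink) noise with SD 20 (arbitrary
µV-like units), a coherent line sinusoid (60 Hz default, amplitude 5),
optional common-mode pink noise (off by default), and white noise in the
MUA band (SD 5). The pre-ictal period (≥10 s, default 10 s) contains
noise only.

**MUA.** Spikes are 1 ms biphasic templates (8× the MUA noise SD) from
inhomogeneous Poisson trains with a 1 ms refractory period: a 2 Hz
homogeneous baseline plus discharge-locked bursts (raised-cosine-like lag
distribution within ±25 ms of each discharge peak, expected count
7.5 spikes per discharge at profile weight 1). Onset-zone motifs weight
spikes by an exponential depth ramp across the infragranular contacts
(length constant 3.5 contacts), concentrating activity in the deepest
20 % of the array; the propagation motif weights the superficial half of
the supragranular group most strongly.

Event times, LFP noise, and MUA are drawn from independently spawned RNG
streams of the config seed, so identical configs are bit-identical and
disabling MUA synthesis (`include_mua=False`) leaves the LFP and ground
truth unchanged.

## Preprocessing

All filters are 4th-order Butterworth IIR applied forward-backward
(zero-phase): LFP band-pass 0.2–500 Hz, MUA high-pass 300 Hz (a
200–5000 Hz band-pass is available), and a 2 Hz-bandwidth zero-phase
notch at the recording's line frequency. Bad channels are linearly
interpolated in depth from the nearest good neighbours (edge channels
copy the nearest good one); an automated robust-z amplitude flagger
replaces visual channel review and errors beyond a 25 % bad-channel
guard. Monopolar and successive-contact gradient representations
interconvert by differencing / cumulative summation with a zero reference
at the virtual contact above the array (monopolar profiles are recovered
up to that constant).

## Discharge detection and scoring

Detection runs per gradient channel on robust z-scores
(x − median)/(1.4826·MAD) with baseline statistics from the annotated
pre-ictal interval. Candidate events are maximal |z| > 4 runs; runs
closer than 20 ms merge; a run is kept if its duration is 20–200 ms and
the maximum rising and falling slopes (on a 3-sample-smoothed trace)
exceed 0.5 z/ms. Channel events within 25 ms collapse into one discharge
(time = median channel peak, channel = argmax |z|), and discharges closer
than 60 ms deduplicate to the stronger peak — the spatially inverted
rebound lobe of a biphasic discharge otherwise registers as a second
event 50 ms after the first.

Scoring treats the point process two ways. Sensitivity and precision use
greedy one-to-one nearest matching within ±50 ms. Specificity needs true
negatives, so it is defined over fixed 100 ms bins: among bins containing
no true event, the false-positive bins are those holding an *unmatched*
detection (a matched detection falling one bin over from its truth time
is not a false positive), and specificity = TN/(TN+FP). The
unmatched-detection rate per minute is also reported.

## MUA rates and depth fraction

MUA rates are threshold-crossing counts (|z| > 4·MAD, 1 ms refractory) in
10 ms bins, smoothed with a 100 ms boxcar and min-max normalized per
recording (per channel optionally). The depth fraction statistic sums the
ictal-minus-baseline rate (floored at zero) over the deepest
⌈fraction·n⌉ channels (⌈0.2·24⌉ = 5) and divides by the sum over all
channels, clipped to [0, 1].

## Layer statistics

Per-discharge peak-layer assignment takes the contact of maximum |CSD| in
a ±25 ms window around the event peak (ties go to the deepest contact);
zone-by-layer count tables are tested with Pearson's chi-square (df = 2),
falling back to a seeded fixed-margin permutation test (10⁵ draws,
vectorized hypergeometric sampling) when an expected cell drops below 5.
Sink/source summary statistics are the mean and variance of positive and
negative normalized CSD values per layer group and recording over the
ictal interval; groups are compared across recordings with Welch t-tests
(granular+infragranular vs supragranular inside the onset zone, reversed
outside). The alternation index per contact is the fraction of
discharges whose CSD sign flips 50 ms after the event peak, with contacts
below a noise floor (1 robust SD of baseline CSD) excluded from the
denominator at each event.

## Normalized-time engagement and onset estimation

Each seizure maps onto 100 equal-duration bins (the last absorbs the
sample remainder); per contact the bin value is the mean |CSD|. The
baseline is the pre-ictal |CSD| binned at the same duration (≥10 s
required), giving a per-contact mean and SD across baseline bins.
Engagement is the thresholded excess max(0, bin − (mean + 2·SD)) —
a `binary` flag switches to strict outlier counting — summed within layer
groups and normalized per bin to a distribution across groups.

The engagement-onset estimator scans every split k (early = bins < k,
k from 5 to 95) with a Welch t-test and returns the first bin of the
elevated regime at the split *maximizing* the t statistic among
significant ones (α = 0.01, late mean > early mean). Choosing the
maximizing split rather than the smallest significant one makes the
estimator exact for a noiseless step (a step at bin 30 yields onset 30)
and unbiased in noise; the smallest-significant rule degenerates to the
minimum segment length whenever the series is significantly elevated at
all. Degenerate zero-variance splits are handled analytically.

## ICA pattern identification

Each retained discharge contributes a 1 s CSD window centered on its peak
(windows crossing the recording edge are dropped), normalized by its max
|CSD|. The event × (channels·samples) matrix is whitened by uncentered
SVD to 8 dimensions and rotated with fixed-point ICA (FastICA,
deterministic given the seed); components are ordered by explained
variance share. Whitening is deliberately *uncentered*: the dominant
discharge motif of a seizure is close to the mean window, and centering
would remove it, leaving the majority of events with no motif-like
component to load on.

Components are reduced to patterns by correlation-template refinement.
Correlations use only the central ±150 ms of each window — the part
occupied by the discharge itself; at 7 Hz a 1 s window also contains
several neighbouring discharges whose lag structure otherwise dominates
component-specific templates. Events are assigned to the
best-correlating retained component (variance share ≥ 0.03); templates
whose correlation reaches 0.5 merge (distinct laminar motifs correlate
near or below zero, while finite-sample templates of one motif stay well
above 0.5 — the selection bias of noisy assignments keeps same-motif
templates from reaching ~0.9); events correlating below 0.25 with every
template remain unassigned (typically pure-noise windows or residual
rebound detections, which are spatially inverted). Assignment, template
rebuilding, and merging iterate to stability (≤10 rounds). A pattern
must hold at least max(4 % of events, 15 events) — the support floor is
deliberately low because the initial discharge pattern of a seizure can
comprise only ~6 % of its discharges (a 5.3 s ramping phase against 57 s
at 7.1 Hz) — and must be temporally contiguous: within the shortest
interval containing 80 % of its events, at least 80 % of the assigned
events must belong to it. Non-contiguous groups are reported with a
warning but not counted. The switch time between consecutive patterns is
the midpoint of the two events straddling the label-separating threshold
that minimizes misordered assignments.

## Problem sizes used in validation

The test suite and the acceptance script simulate default-length seizures
(72.3 s onset-zone, 70 s propagation-zone recordings): 10 seizures for
detector sensitivity/specificity, 50 for discharge-rate recovery, 10 for
ICA pattern counts and switch times, 20 for engagement-onset recovery,
and 2 (with the full 20 kHz MUA band) for the depth-fraction statistic.
These sizes give standard errors comfortably below the acceptance
tolerances while keeping a full run in the minutes range on one CPU.

## What the synthetic validation shows — and does not

Passing tests establish that each stage recovers the generator's ground
truth under realistic noise (1/f + line) at the published discharge
dynamics, and that the stages compose end to end. The generator does
not emulate: spatially correlated biological noise beyond an optional
common-mode term; discharge-morphology variability (one kernel per
motif, amplitude fixed); gradual motif drift (recruitment is stepwise);
interictal spikes in the baseline (available as an option but off by
default); electrode artifacts, movement, or amplifier saturation; or
volume conduction in 3-D. Performance numbers on synthetic data
therefore bound what clean clinical recordings could yield but do not
guarantee it; the detector and ICA thresholds are exposed as parameters
precisely because real recordings will need them re-examined.

## Known limitations

- CSD units are arbitrary (no conductivity model); only normalized or
  baseline-relative comparisons are meaningful.
- The binwise specificity definition depends on the bin width (100 ms
  default); both per-event precision and binwise specificity are
  reported.
- The engagement-onset scan assumes a single upward step; multi-step or
  transient engagement profiles return the strongest split only.
- EDF export quantizes to 16 bits per channel and zero-pads the final
  data record; it is for interoperability, not archival.
- With fewer than ~15 events per pattern the support floor suppresses
  genuine but sparse patterns; at very high discharge rates (>11 Hz) the
  dead-time renewal clamps the configured rate.
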