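# Methods

This note documents the models implemented by `incerta`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that matter when
comparing results across implementations.

## Head kinematics

Two markers (nose; between the ears) define the head midline per video
frame (30–100 fps). All measures are per-frame and converted to cm/s via
a pixel calibration applied once (`calibrate` sets a flag; calibrating
twice is an error).

* **Head angle** — orientation of the ears→nose vector,
  counter-clockwise positive, unwrapped across the ±180° seam so that
  frame-to-frame differences are meaningful. Frames with coincident
  markers are interpolated and logged.
* **Rotational speed** — |Δθ| in radians × radius × fps. The radius
  converts head rotation into a rim speed commensurate with translation;
  it defaults to **half the session-mean nose–ears distance** and is
  configurable. The first frame of every difference series is 0.
* **Linear / sideways speed** — ears-marker displacement *d* projected
  onto the midline of the earlier frame: linear = d·cos φ·fps,
  sideways = d·sin φ·fps. The projections are kept signed internally
  (forward/backward, left/right); the exported speed series are their
  magnitudes. Zero displacement ⇒ both 0 (φ undefined, 0 by convention).
* **Translational** = |linear| + |sideways|; **overall** = rotational +
  translational. Both identities hold exactly at every frame — they are
  definitions, not approximations — and they are what make the overall
  speed invariant to rigid motions of the arena coordinate frame.
* **Bias** — cumulative signed Δθ zeroed at a reference frame (the frame
  preceding a stimulus, typically). Whether positive means ipsiversive
  or contraversive depends on the implanted side; everything downstream
  takes a `contraversive_sign` parameter instead of hard-coding a side.
  The generator's convention is positive = contraversive.
* No smoothing is applied by default; an optional boxcar is available
  but off.

## Movement-event detection

A sample of a continuous measure is an event iff it is the extremum of
all samples within ±0.5 s around it (`half_window`, configurable). The
scan is strict with earliest-sample tie-breaking, so a plateau of equal
values yields exactly one event; the implementation (a centered maximum
filter plus an exact neighbourhood check) is tested for equality against
a brute-force O(n·w) scan.

For the head angle, an extremum is a **turn** when the angle change at
that point exceeds 10° (`turn_threshold`); its sign gives the direction.
The "change at this point" is measured from the **immediately preceding
windowed extremum** (series start if none). Under strict max/min
alternation this equals the change from the nearest opposite-sense
extremum; we use the preceding-extremum rule because the opposite-sense
rule double-counts when two same-sense extrema are adjacent (e.g. a
plateau noise peak shortly after a real turn would re-use the faraway
pre-turn reference and spuriously exceed the threshold).

For speed series the detector keeps maxima with a minimum prominence of
2 cm/s over the preceding trough (no threshold is inherent to the speed
measure, so this is an explicit, configurable parameter).

Detected events are categorized three ways, mirroring the triggered
analyses: *all* peaks; *onset-isolated* peaks with no detected peak
within an exclusion interval before them (3 s for photometry, 4 s for
unit recordings — extracts movement onsets from immobility); and a
*fixed-interval* subsample (greedy left-to-right, ≥5 s apart — movement
increases from ongoing movement). Both special categories are subsets of
*all*.

## Photometry

Acquisition interleaves the two excitation LEDs within each 10-ms cycle
(465 nm on 0–3 ms; 405 nm on 5–8 ms), acquired at 5–20 kHz; each
channel's per-cycle value is the sample at the end of its pulse, giving
100 Hz effective per channel. A truncated final cycle is dropped.

The calcium-independent 405-driven channel sees the same motion and
bleaching artifacts as the 465-driven signal channel but not the
calcium signal. F₀ is obtained by least-squares scaling of the control
to the signal channel; ΔF/F = (F − F₀)/F₀, then Z-scored.

Choices where the procedure admits variants:

* The fit uses **slope and intercept** by default (robust to additive
  offsets such as ambient light); a slope-only mode is available.
* Fit epoch and Z-score epoch default to the **whole session**;
  per-epoch fitting and pre-event-baseline Z are available for
  triggered analyses.
* Samples with F₀ ≤ 0 are masked, not clipped; an all-masked trace or a
  zero-variance ΔF/F raises instead of returning NaNs.

ΔF/F is exactly invariant to a common rescaling of both channels.

## PSTHs and unit classification

PSTHs are mean firing rates in 100-ms bins over a (−3, +3) s window
around movement peaks (time zero = the detected peak). A unit's usable
events are those whose window fits inside its recording support
(`t_start`/`t_stop` when recorded; otherwise all events are assumed
covered). The PSTH of a merged event set equals the event-count-weighted
mean of the per-subset PSTHs, exactly.

Classification is two-step:

1. Each PSTH is **baseline-z-scored** — baseline mean subtracted and
   divided by the baseline-bin SD (baseline window (−3, −1) s; SD floored
   at 0.1× the population median to guard silent units). This keeps
   response *amplitude* in units of each cell's own variability, which is
   what separates strong from weak movement coupling, and makes the
   classification invariant to a common rate rescaling and to unit
   order. PCA retains the leading components explaining ≥80% of variance
   (capped at 5), and a 2-means split (50 restarts, fixed seed) of the
   scores separates the movement-activated cluster (higher peri-zero
   elevation) — **Class1** — from **Class2**.
2. Class1 splits into **1a/1b** by a 2-means threshold on log baseline
   rate (1a high); Class2 splits into **2a/2b** by the sign of the raw
   peri-movement rate modulation (2a suppressed, 2b weakly activated).
   A lone Class1 unit is labeled against the population median rate.

Degenerate inputs (under 8 units, all-flat PSTHs, single cluster) raise
rather than guessing.

Rate–speed coupling is quantified on **nonoverlapping 200-ms windows**
(spike count per window vs mean speed): Pearson r and the least-squares
slope, which estimates the generator's coupling gain (recovered within
10% at 600 s of data). Sensory responsiveness is the mean evoked-rate
change (response window minus pre-stimulus baseline per stimulus) with a
percentile-bootstrap 95% CI; a unit is responsive when the CI excludes 0
(with a relative 1e-9 tolerance — resampled bounds that equal zero up to
float rounding must not count as exclusion). This criterion is a
construction of this package; it is calibrated (≤10% false positives) at
60 stimuli per unit.

## Triggered metrics

Snippets are extracted on a common relative-time grid by linear
interpolation (mixed 30–100 fps inputs resample cleanly); edge events
without full support are dropped and counted. Areas are per-event
trapezoidal integrals with the window endpoints interpolated onto the
grid, so adjacent windows add exactly. Peak-from-baseline takes the
largest absolute deviation from the pre-event baseline mean (signed
value reported; ties and flat snippets resolve to the earliest sample,
a flat snippet reporting peak 0 at the window start). Cross-correlation
is per-lag Pearson on the overlapping support (a true correlation at
every lag, not an FFT convolution). Statistics are computed on
**per-event areas**, not on the area of the mean trace.

The direction contrast compares ipsiversive vs contraversive triggered
areas (−3 to +3 s) with the pooled bootstrap test; ≥10 events per side
required.

## Resampling

The bootstrap difference test pools both samples irrespective of group,
draws groups of the original sizes with replacement `n_resamples` times
(1000–10,000 enforced), and reports p = (k+1)/(n+1) where k counts
resamples with |mean difference| ≥ observed. Two-sided by construction;
the add-one smoothing keeps p > 0. Empirical type-I error at nominal
0.05 is 0.04–0.07 over 1000 null pairs of n = 20.

The shuffle control averages both series in 200-ms windows, permutes one
variable's windowed values, and reports the observed windowed r against
the 2.5–97.5 percentile null band. The permutation null assumes windowed
values are exchangeable; for series whose autocorrelation is much longer
than the window the band is anticonservative — a property of the method,
not of this implementation.

## Avoidance scoring

A trial is an **avoid** when the response latency is within the CS's
avoidance interval, an **escape** otherwise (the US forces a response).
For the passive CS of AA3, shuttling during the avoidance interval is a
**passive_fail**, withholding a **passive_avoid**. Avoidance latency
averages successful avoids only. ITCs are counted from the event list;
latency is measured from CS onset to the compartment-entry event, which
is an input (no tracking-based inference). Procedure rosters: AA1/AA2
one 8-kHz CS with a 7-s interval (AA2 punishes ITCs); AA3 adds a 4-kHz
passive CS; AA4 uses three CSs (8/10/12 kHz) with 4/7/15-s intervals.
Escape latency always exceeds the avoidance interval by construction,
and % avoids is invariant to trial order.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under a fixed seed and return or store
their ground truth.

* **Trajectories** — the ears marker is fixed; the nose marker rotates
  about it so the midline angle integrates each scheduled turn with a
  raised-cosine angular-velocity profile (smooth, exactly integrable;
  the profile within real turns is unknown). Angular noise is white with
  SD `noise_sd` (deg). Random schedules alternate turn direction by
  default — exploratory head orientation is mean-reverting — with
  amplitudes 15–60°, durations 0.3–0.8 s and ≥1 s gaps;
  `p_same_direction` admits same-direction runs. Not emulated:
  locomotion of the ears marker (tests build translation explicitly),
  marker dropout, lens distortion.
* **Spike trains** — inhomogeneous Poisson on a 1-ms grid with rate
  max(0, baseline + gain·speed). Default class parameters (baseline
  20/8/8/6 spikes/s, gains +1.5/+1.5/−0.6/+0.2 (spikes/s)/(cm/s) for
  1a/1b/2a/2b) reproduce the *ordinal* relations of the recorded
  population — 1a fires faster than 1b, both strongly movement-coupled;
  2a mildly suppressed; 2b weakly activated — not any session's absolute
  rates. Not emulated: refractoriness, bursting, adaptation.
* **Photometry** — latent activity = movement drive convolved with a
  delayed single-exponential calcium kernel (τ = 0.5 s, GCaMP7f-like;
  onset delay 0.1 s), peak-normalized; a slow Gaussian-filtered shared
  artifact (SD 0.05, τ ≈ 2 s) multiplies **both** channels, while
  activity enters only the 465 channel (10% of baseline per unit
  activity); white read noise (SD 0.2 on a baseline of 100, SNR ≈ 50 per
  sample) is added per channel. Not emulated: bleaching trends (the
  shared multiplicative artifact subsumes slow drifts), hemodynamic
  contamination.
* **Avoidance sessions** — per-CS response latencies are truncated
  normals (AA4 means 2.0/3.5/6.0 s for the 4/7/15-s intervals: trained
  animals scale latency to the signaled interval); a draw beyond the
  interval becomes an escape at interval + 0.3 s + Exp(0.7). The passive
  CS is shuttled on with probability 0.15. ITIs are uniform 25–45 s with
  Poisson ITCs (rate 10× lower under ITC-punishing procedures). No
  learning dynamics are simulated — sessions model trained steady-state
  performance.

Because the generators realize exactly the statistical structure the
analyses assume (linear rate coupling, shared multiplicative artifact,
Poisson spiking), passing tests demonstrate correctness of the chain and
calibration of its statistics — not robustness to real-data pathologies
(non-Poisson firing, non-multiplicative artifacts, tracking dropouts).

## Problem sizes used in validation

Classification recovery uses 160 units (40/class) on 600 s of movement;
turn recovery uses ten 300-s sessions at 1° noise; photometry fidelity
five 120-s sessions; bootstrap calibration 1000 null pairs of n = 20;
shuffle coverage 50 independent pairs; the direction contrast twenty
900-s sessions with turns ≥2.5 s apart (55–70 events/side), spacing
chosen so neighbouring turns stay outside each other's ±3 s area
windows. A detected turn is credited to the planted turn whose
mid-turn-to-next-mid-turn interval contains it (the windowed extremum may sit
legitimately on plateau noise a second or two after the turn ends, so a
fixed time tolerance would miscount).

## Known limitations

* The windowed-extremum detector cannot resolve two same-direction turns
  separated by less than the detection window — they merge into one
  event with the summed amplitude.
* The shuffle-control null is anticonservative for series autocorrelated
  beyond the integration window (see above).
* The percentile bootstrap CI for sensory responses is mildly
  anticonservative below ~40 stimuli.
* Mixed-effects ANOVA/Tukey analyses are out of scope; group contrasts
  here use the bootstrap test throughout.
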