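# incerta

Analysis toolkit for behavioral neurophysiology studies of movement
coding — built around the kind of experiment in which zona incerta
activity is recorded (single units or GCaMP fiber photometry) while mice
explore an arena or perform signaled active-avoidance tasks, with head
movement tracked by two colored markers (nose and between-ears).

The package implements the full analysis chain as a tested, reusable
library plus a command-line pipeline:

* **kinematics** — decomposition of two-marker tracking into speed
  components. With the head-midline angle θ (ears→nose vector) and the
  ears-marker displacement *d* between succeeding frames,

  - rotational = |Δθ| (rad) · radius · fps
  - linear = d·cos φ · fps, sideways = d·sin φ · fps
    (φ = angle between displacement and midline)
  - translational = |linear| + |sideways|, overall = rotational + translational
  - head-angle *bias* = accumulated signed Δθ, zeroed at a reference frame

* **events** — turns and movement peaks as strict local extrema within a
  ±0.5 s window; a turn is an extremum whose angle change exceeds 10°,
  signed by direction (ipsiversive/contraversive). Detected peaks are
  categorized as *all*, *onset-isolated* (no peak within an exclusion
  interval before) and *fixed-interval* subsets.

* **photometry** — two-channel (465/405 nm) processing: demultiplexing of
  the interleaved pulse acquisition at the 100 Hz effective rate, linear
  scaling of the calcium-independent control channel to the signal channel
  (the fitted values are F₀), ΔF/F = (F − F₀)/F₀, and Z-scoring. The
  control channel carries the same motion/bleaching artifacts as the
  signal channel, which is what makes the correction work.

* **units** — movement-aligned PSTHs, the two-step four-class
  classification (PCA on baseline-z-scored PSTHs → 2-means split into
  movement-activated Class1 vs Class2; Class1 split 1a/1b by baseline
  rate, Class2 split 2a/2b by the sign of peri-movement modulation),
  windowed rate–speed correlation, and bootstrap sensory responsiveness.

* **metrics** — event-triggered snippet stacks, per-event trapezoidal
  areas, peak-from-baseline and time-to-peak, per-lag Pearson
  cross-correlation, and the ipsiversive-vs-contraversive contrast.

* **resampling** — the pooled bootstrap difference test (resampling all
  values irrespective of group, 1000–10,000 times; two-sided on the
  absolute mean difference, add-one smoothed) and the shuffle-control
  null band for windowed correlations.

* **behavior** — scoring of the AA1–AA4 avoidance procedures: % avoids,
  avoidance latency (successful avoids only), intertrial crossings, and
  the per-CS latency analysis for the multi-interval AA4 procedure.

* **synth** — generators for every input with stored ground truth:
  marker trajectories integrating a turn schedule, inhomogeneous-Poisson
  spike trains with class-specific movement coupling, two-channel
  photometry with a shared motion artifact, and avoidance trial streams.

## Worked example

```python
import numpy as np
from incerta import synth, kinematics as K, events as E, photometry as P, metrics as M

sched = synth.TurnSchedule.random(300.0, seed=11)            # known turns
track, _ = synth.gen_head_trajectory(sched, duration=300.0, noise_sd=0.5, seed=11)
kin = K.compute_kinematics(K.calibrate(track))
turns = E.categorize_peaks(E.detect_peaks(kin.head_angle, fps=track.fps, kind="turn"))

truth = synth.make_photometry_truth(kin.t, kin.overall, seed=11)
raw = synth.gen_photometry(truth, seed=11)                   # 465/405 channels
dff = P.process(raw)                                         # fit → ΔF/F → Z

stack = M.extract_triggered(raw.t, dff.z, turns.select("onset_isolated"), window=(-3, 3))
areas = M.area_measure(stack, (-3.0, 3.0))
peaks, lats = M.peak_and_latency(stack, (0.0, 3.0), baseline=(-3.0, -1.0))
```

With the prints shown in `README` order this produces:

```
planted turns: 22   detected: 22 (11 contraversive)
movement-onset events (no peak 3 s prior): 20
isosbestic fit: slope 1.276, intercept 0.760
corr(Z, true activity) = 0.908
triggered on 20 movement onsets: area 1.86 z·s, peak 3.68 z at +0.67 s
```

Every planted turn is recovered with its direction; the isosbestic fit
removes the motion artifact so the Z-scored ΔF/F tracks the latent
neural activity (r = 0.91); and the movement-onset-triggered calcium
response peaks ~0.7 s after the movement peak — the kernel delay plus
the calcium indicator's rise.

The same chain is available from the shell:

```sh
incerta simulate --procedure AA4 --seed 7 --out data/
incerta kinematics --markers data/markers.csv --out data/
incerta detect-events --kinematics data/kinematics.csv --measure head_angle --out data/
incerta dff --photometry data/photometry.csv --out data/
incerta avoidance-score --trials data/trials.json --out data/
```

Each command writes JSON/CSV results and a `run_manifest.json` recording
parameters and seed. Exit codes: 0 success, 2 schema error, 3
degenerate input.

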