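# Methods

## Scope and data model

`saltatrack` analyzes pre-tracked, pre-calibrated trajectories: tables of
`(cell_id, frame/t_min, x_um, y_um, group)`. All internal units are μm and
minutes; a `z` column is ignored (the analysis is planar). Image
segmentation and tracking are out of scope. Tracks need at least two
points, strictly increasing times and finite coordinates; cells with fewer
than two rows are dropped with a warning.

## Kinematic feature definitions

For consecutive positions at uniform frame interval Δt (default 5 min):

* **displacement** `d_i` — Euclidean distance between frames `i` and `i+1`;
* **pause** — `d_i ≤ ε`. The biological definition is "no displacement",
  which is unattainable under tracking noise, so ε defaults to 0.5 μm:
  below the event threshold, above the expected noise displacement
  (two positions jittered with SD 0.2 μm per axis give a Rayleigh-
  distributed spurious displacement with σ ≈ 0.28 μm). ε is configurable.
* **nucleokinesis step** — `d_i > θ`, θ = 5 μm by default;
* **slide** — anything between ε and θ: continuous sub-threshold movement.
* **nucleokinesis event** — a maximal run of consecutive supra-threshold
  steps; amplitude is the summed displacement of the run. A jump can span
  more than one 5-min frame, so merging runs is the default; a switch
  (`merge_runs=False`) treats every step as its own event for sensitivity
  analysis.
* **average speed** — total path length divided by elapsed time. Path-based
  (not net-based): straightness is reported separately as
  **directionality** = net start-to-end displacement / path length
  (0/0 defined as 0).
* **instantaneous speeds** — `d_i/Δt` over non-pause intervals. Pause
  intervals are excluded by default because the surrogate model samples
  pausing and moving from separate distributions; including near-zero pause
  speeds would count pausing twice. `include_pauses=True` gives the
  alternative.

Group models pool per-cell pause durations and moving speeds into
fixed-width, left-closed/right-open histograms (defaults: 5 min — one
frame — and 0.2 μm/min) and record the population mean pausing-time
fraction `f`. Histogram bin widths are artifact choices.

## Synthetic trajectory generator

The generator emulates two-stroke migration as an alternating renewal
process at frame resolution:

* pause and move bout durations are exponential with configurable means,
  rounded **up** to whole frames (the memoryless family is the simplest
  defensible stand-in; real pause-duration distributions are known only
  empirically);
* within a move bout, per-frame speeds are i.i.d. log-normal
  (positive, right-skewed) with configurable mean and CV;
* a configurable fraction of move bouts are **sliding** bouts: their
  speeds are rescaled so no frame exceeds 0.9 × θ. The 0.9 margin keeps
  slide frames out of the noise-flip band just below the event threshold;
* jump bouts can be tied to a target mean amplitude `A`
  (`jump_amp_mean_um`): per-frame speeds are scaled by
  `A / (v̄·Δt·E[frames per bout])`, so the expected bout displacement is
  `A`. With `jump_amp_mean_um=None` the amplitude simply emerges as
  speed × duration;
* step directions are von Mises about a mean migration direction with
  concentration κ (`persistence`); positions receive isotropic Gaussian
  noise (default SD 0.2 μm, sub-resolution jitter) after path construction;
* the initial segment type is drawn with the frame-level stationary pause
  probability, so short recordings are not biased toward either phase.

Every generated cell carries a ground-truth log of phase segments
(kind, interval, true per-frame displacements), which is what the detector
tests score against.

### Study presets

Two presets encode the qualitative wild-type vs deglutamylase-mutant
contrast. They are engineered artifact choices, **not** fitted parameters:

| parameter | WT-like | cKO-like | rationale |
| --- | --- | --- | --- |
| pause mean | 15 min | 7.77 min | mutant pausing-time fraction 13% lower |
| move-bout mean | 5 min | 4 min | mutant bout rate raised |
| speed mean | 1.8 μm/min | 0.68 μm/min | calibrated: equal average speed |
| jump amplitude | 14.2 μm | 0.87 × WT | mutant jumps 13% smaller |
| sliding fraction | 0.05 | 0.35 | mutant slides instead of jumping |
| persistence κ | 2 | 20 | steady gliding is near-straight |

The mutant speed was calibrated by simulation so the population mean
average speed matches the wild-type preset (measured gap −0.05% at
n = 1500 cells per group). The persistence contrast expresses the mutant's
steady monophasic movement as straighter paths; it is the mechanism by
which the mutant population's displacement frontier exceeds the wild-type
frontier at matched average speed — a pause-driven dispersion difference
alone cannot separate lower-quartile order statistics at realistic cohort
sizes (n ≈ 40), as the order-statistic standard error exceeds the
achievable quartile shift.

What the generator does **not** emulate: leading-process morphology and
branching, 3-D motion, cell–cell interaction, drift or rotation of the
field, heterogeneous per-cell speed levels (speeds are i.i.d. across
frames), and non-exponential bout-duration shapes. Passing tests therefore
certify the pipeline's statistics and detectors, not any claim about real
trajectories.

## Surrogate race

Surrogates are 1-D walkers: per frame they are either paused (displacement
increment 0) or moving (increment = speed × Δt, speed i.i.d. from the
group's speed histogram; bin chosen by mass, value uniform within the
bin). Pause durations are drawn the same way from the pause histogram and
rounded up to frames. Move-bout durations are geometric (the discrete
exponential) with mean fixed by the renewal identity: in continuous time
`m = E[P](1−f)/f` (`enforce_pause_fraction`); internally the identity is
applied to the *ceil-discretized* mean pause length, and the geometric
mean is matched exactly in frames, so the realized frame-level pause
fraction is unbiased. The phase process starts stationary: initial type
with probability `f`, initial pause length from the residual-life
distribution `P(R=r) = P(N≥r)/E[N]` (the geometric move length is
memoryless and needs no correction). This makes the expected pause
fraction exact over any window, which the pause:movement constraint
requires.

Analysis conventions:

* thresholds: `k` values (default 10) equally spaced from the pooled
  minimum to the pooled maximum of both groups' final displacements,
  endpoints included. The lowest threshold is therefore crossed by 100% of
  both groups by construction and its comparison is degenerate (p = 1).
* "crossed" means final displacement ≥ threshold.
* per threshold, a two-sided Student t test compares the per-realization
  crossing percentages (20 vs 20 by default); Welch is available via
  `equal_var=False`. If both samples are constant the p value is defined
  as 1 for equal means and 0 otherwise.
* the q-frontier at a frame is the `⌈qn⌉`-th largest displacement — the
  largest value attained by at least a fraction q of the population. No
  interpolation: the frontier is a displacement actually attained.
* phase-density output orders surrogates by total moving time (ties by
  index) and annotates each moving frame with the length of its maximal
  moving run, in minutes.

`preset_models()` provides a built-in group pair for the race: the
saltatory group A (pausing fraction 0.69) has an exponential(15 min)
pause body truncated at 1 h plus a 6% "prolonged stalling" tail spread
over 1–7.5 h (cells that park for hours, visible as almost entirely
non-moving rows in the phase-density plot), with log-normal speeds
(mean 1.4 μm/min, CV 0.45). The steady group B (pausing fraction 0.60,
exponential 7.8 min pauses) has lower-mean, right-skewed speeds
(CV 1.95) scaled so both groups share the same expected final
displacement. The stalling tail gives group A its heavy low-displacement
tail (the low-threshold deficit), and the matched sparse upper tails keep
the top thresholds in the noisy few-crossers regime where the t test is
inconclusive — the regime the threshold ladder's upper end probes. These
shapes are artifact choices playing the role of empirically measured
distributions.

## Device (MFD) race analysis

Cells in corridors do not move along a perfectly straight line, so each
cell gets its own motion axis: the principal axis of its centered position
cloud (total least squares — minimizes summed squared *perpendicular*
distances, which is what makes `along² + perp² = ‖x − x₀‖²` exact).
Ordinary y-on-x regression is available behind a flag for sensitivity
checks. The axis is oriented so net displacement projects positively; an
isotropic cloud falls back to the net-displacement direction (+x if that
is zero, logged). The projection origin is the first position, so
`along[0] = perp[0] = 0`; the cell's **final displacement** is the
along-axis value at the last common frame. Cells leaving the field before
the end of the grid are excluded with a log message. Perpendicular
displacements are computed and reported but enter no statistic.

The group comparison permutes group membership: pooled final displacements
are reshuffled (default 10,000 times), each shuffle reassigning `n_A` and
`n_B` values and recording the frontier difference B − A at level q. The
p value uses the add-one correction `(#{null ≥ observed}+1)/(n_perm+1)`,
one-sided toward B > A by default — the directional hypothesis that the
steady group's frontier is higher; the two-sided and lower-tail options
are exposed. The sweep covers `levels` interior percentage points
`i/(levels+1)`: 19 levels give 5%, 10%, …, 95%; one level gives the
median.

## Numerical choices and degenerate inputs

* All stochastic stages are driven by numpy Generators; populations and
  simulations spawn independent child streams per cell and per
  (realization, group) from a root `SeedSequence`, so results are
  reproducible from `(config, seed)` and robust to reordering.
* Histogram masses must sum to 1 within 1e-9; pause-fraction targets must
  lie strictly in (0, 1).
* A pause-fraction target whose implied move-bout length falls below one
  frame is clamped to one-frame bouts with a warning.
* Zero-variance t-test samples, zero-net-displacement axes, frozen cells
  (directionality 0/0 → 0) and empty event lists are all defined, not
  errors; truly degenerate inputs (identical positions, min == max
  thresholds, empty groups) raise validation errors.
* Tie-breaks: phase-density ordering is stable by surrogate index;
  "crossed" uses ≥ so ties at a threshold count as crossings.

## Known limitations

* The surrogate model is 1-D and interaction-free by design; it cannot
  express crowding, guidance cues or corridor geometry.
* Histogram-mediated resampling (bin by mass, uniform within bin,
  re-discretized to frames) smooths the pause-duration distribution by up
  to one bin width; the pause-fraction constraint compensates in the mean
  but not in higher moments.
* Under tracking noise, ~20% of true pause intervals exceed ε = 0.5 μm and
  are labelled slides, fragmenting long pauses; group *contrasts* of
  pausing time are preserved (both groups are attenuated by the same
  factor), but absolute pausing fractions are underestimated relative to
  ground truth. Raising ε trades this against slide sensitivity.
* Per-cell axis fitting slightly inflates along-axis displacements for
  short, wiggly tracks (the axis adapts to the realized path); group
  comparisons use identically processed groups, so the bias is shared.
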