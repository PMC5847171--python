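# saltatrack

Kinematic analysis and cohort simulation of **saltatory neuronal migration**
from cell-tracking trajectories.

Migrating cortical interneurons move in a two-stroke cycle: the nucleus
pauses, then jumps forward in a discrete **nucleokinesis** event. Loss of
this rhythm converts saltatory migration into slow, steady "sliding"
movement — a phenotype that leaves the *average* speed unchanged while
redistributing movement in time. `saltatrack` quantifies this regime from
tracking data and asks the population-level question: *when two groups of
cells migrate with equal average speed but different pause/jump statistics,
which cohort invades a target territory faster?*

The package provides four composable stages:

1. **Kinematics** — from a trajectory sampled every Δt (default 5 min),
   the per-interval displacement `d_i = ‖x_{i+1} − x_i‖` is labelled
   *pause* (`d_i ≤ ε`, default ε = 0.5 μm), *nucleokinesis step*
   (`d_i > θ`, default θ = 5 μm) or *slide* (in between). A maximal run of
   supra-threshold steps is one nucleokinesis event with amplitude
   `Σ d_i`. Per cell: average speed (path length / elapsed time),
   pausing-time fraction, event frequency and amplitude, instantaneous
   speeds, directionality (net / path).
2. **Synthetic tracks** — a two-stroke trajectory generator with
   exponential pause/move bouts, log-normal moving speeds, von Mises step
   directions and Gaussian tracking noise. Every track ships with a
   ground-truth event log, so the detectors above can be scored exactly.
3. **Surrogate race** — unidirectional surrogate cells whose pause
   durations and per-frame speeds are sampled from empirical (histogram)
   group models, with move-bout durations set by the renewal identity
   `m = E[P](1−f)/f` so the long-run pause fraction matches the observed
   `f`. Two groups (100 surrogates × 20 realizations × 10 h by default) are
   compared by the percentage of cells whose final displacement crosses
   each of 10 thresholds spanning the pooled range (unpaired t test per
   threshold), by the q-frontier (largest displacement reached by ≥ q of
   the population, q = 0.75) and by phase-density matrices.
4. **MFD race** — for cells tracked in microfluidic-device corridors, a
   total-least-squares motion axis is fitted per cell, displacements are
   decomposed along/perpendicular to it, and the group difference in the
   75%-frontier of final along-axis displacements is tested by permuting
   group membership (10,000 shuffles, swept over 19 percentage levels).

## Worked example

```bash
$ saltatrack synth --seed 7 --out tracks.csv --n-per-group 40 --duration-min 600
wrote 80 tracks to tracks.csv

$ saltatrack kinematics tracks.csv --out features.csv
wrote features for 80 cells to features.csv

$ head -3 features.csv
cell_id,group,average_speed_um_min,pausing_time_fraction,nk_count,nk_frequency_per_hr,mean_nk_amplitude_um,directionality
WT_0000,WT,0.58074464452,0.55,21,2.1,14.1459861731,0.542155557257
WT_0001,WT,0.631440661814,0.525,22,2.2,15.5516380536,0.684148711425
```

Each row is one cell: `WT_0000` migrated at 0.58 μm/min, spent 55% of the
recording pausing, and produced 21 nucleokinesis events (2.1 per hour,
mean jump 14.1 μm) with directionality 0.54. The command also writes
per-group model JSONs (`features_model_WT.json`, `features_model_cKO.json`)
holding the pooled pause-duration and speed histograms plus the pausing
target `f` — the inputs of the surrogate race:

```bash
$ saltatrack surrogate-race --presets --seed 7 --out race
6/10 thresholds significant at alpha=0.05

$ head -4 race_thresholds.csv
threshold_um,pct_a_mean,pct_b_mean,t_stat,p_value
5.68362937868,100,100,0,1
74.6865972591,96.75,100,-9.16829273219,3.60212552132e-11
143.689565139,83.95,98.4,-16.5480918617,5.8494560542e-19
```

At the low displacement thresholds the steady group B crosses
significantly more often than the saltatory group A (98.4% vs 84.0% at
144 μm, p ≈ 6e-19), even though both groups share the same average speed —
reduced pausing recruits more cells at short range. The lowest threshold is
the pooled minimum, crossed by every surrogate of both groups by
construction. At the top thresholds the comparison loses significance:
only rare outlier cells reach them.

```bash
$ saltatrack mfd-race tracks.csv --seed 7 --out mfd
q=0.75: observed diff 109.11 um, p=0.0001
```

The highest displacement crossed by 75% of the steady population exceeds
the saltatory group's frontier by 109 μm after 10 h, and the permutation
test places this difference far in the tail of the label-shuffled null.
Every output table carries a `.provenance.json` sidecar (seed, full
configuration, package version) so any run can be replayed exactly.

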