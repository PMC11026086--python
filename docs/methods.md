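# Methods

## Signal model and extraction procedure

A session contains three bridging tasks — bilateral (BB), unilateral
right (URB), unilateral left (ULB) — each repeated six times with 10 s
holds, recorded on four pressure channels (RK, RB, LK, LB) at 28 Hz.
The stable pressure of a trial is defined operationally as the plateau
held during the bridge, and extracted as follows:

1. **Filtering.** The raw trace is low-pass filtered with a Butterworth
   filter applied forward and backward (zero phase). The cutoff is
   2 Hz; the order is 2 per pass by default (the dual pass squares the
   magnitude response, so the cutoff frequency is attenuated to exactly
   1/2 in amplitude). Edges are handled by scipy's odd-reflection
   padding; a minimum trace length is enforced accordingly.
2. **Velocity.** The pressure rate of change (mmHg/s) via central
   differences on interior samples and one-sided differences at the
   edges (exact for linear and quadratic trajectories).
3. **Movement detection.** Within 2 s of the cue, the signed velocity
   extremum: the maximum for increasing channels (knees), the minimum
   for decreasing channels (back). Trials whose peak |velocity| falls
   below 1 mmHg/s are flagged `no_movement` — the threshold is a
   package default, chosen as the smallest rate distinguishable from
   filtered sensor noise at the default noise level; it is configurable.
4. **Ramp end.** The first sample after the extremum where velocity
   changes sign (exact zeros count as crossings). The reported time is
   the grid time of that sample; no sub-sample interpolation is used
   because the subsequent 1 s delay + 4 s average makes sub-sample
   precision immaterial. By default the search runs to the end of the
   trial window; `zc_search_limit_s` can restrict it to a fixed horizon
   after the peak for stricter event definitions.
5. **Plateau average.** Pressure averaged over 4 s beginning 1 s after
   the zero-crossing. If that window does not fit inside the trial
   window and the trace, the trial is flagged `window_truncated` (a
   10 s hold accommodates it comfortably; a 3 s hold cannot).
6. **Aggregation.** Valid trials are averaged per task × channel; cells
   with zero valid trials are reported as missing, never as zero.

Trial windows span cue onset to the end of the hold; the movement ramp
occurs inside the window, consistent with a protocol in which the
participant rises into the bridge on an auditory cue and relaxes on the
next cue.

### Direction handling for the unloaded knee

In a unilateral bridge the opposite knee typically *unloads* slightly
(its pressure drops a few mmHg). A strict per-channel convention
(knees = increase) would classify those trials as `no_movement` and
leave the corresponding task × sensor cells empty. `extract_session`
therefore defaults to `direction="auto"`: the extremum of |velocity|
decides each trial's direction from the data. The strict convention
remains available (`direction_mode="convention"`) and both behaviours
are tested.

## Simulator

The generator produces the study conditions the extraction and validity
analyses are designed for.

**Underlying trajectory.** Per channel: baseline + a per-trial
smoothstep bump (C¹ sigmoid `3x² − 2x³` over a 1.5 s ramp — smooth
transitions with a single well-defined velocity peak) to the plateau and
back + optional drift (integrated Gaussian random walk, default scale 0;
exposed for robustness tests only).

**Calibration.** Noiseless plateaus default to representative stable
pressures per task × channel (e.g. BB: RK 50.84, RB 10.60, LK 50.77,
LB 9.30 mmHg). Resting baselines are RK 44.99, LK 46.18, RB 20, LB 20
mmHg, chosen so pressed knees rise, back channels always fall by
7–11 mmHg, and the unloaded knee in a unilateral bridge drops ~4 mmHg —
the sign structure the compliance patterns assume.

**Variability.** Three scales, chosen once as realistic for this class
of recording:

| parameter | default | emulates |
|---|---|---|
| `participant_sd_mmHg` | knees 5.5, backs 6.5 | between-participant spread of resting pressure (offset applied to baseline *and* plateau, so task deltas are preserved); rejection-sampled so no plateau falls below 0.5 mmHg |
| `trial_jitter_sd_mmHg` | 0.75 | within-participant trial-to-trial plateau variability (in the trajectory, hence seen identically by both readouts) |
| `noise_sd_mmHg` | 0.5 | i.i.d. digital sensor noise per 28 Hz sample |
| `analog_read_sd_mmHg` | 1.3 | observer error reading the dial, before 2 mmHg quantization |

With these defaults the trial-level digital − analog difference SD is
≈ 1.45 mmHg and trial-level rank correlations per cell land in the
mid-0.9s for a 23-participant cohort — the regime in which the
acceptability rule (ρ ≥ 0.9, |bias| < 3 mmHg) is meaningful to test.

**Readouts.** Digital: the trajectory sampled at 28 Hz plus sensor
noise. Analog: one reading per trial — the trajectory averaged over the
middle 4 s of the plateau, plus observer noise, rounded to the nearest
multiple of the gauge precision (2 mmHg). The 30 Hz analog video rate is
carried as metadata only; the video/observer process itself is not
modelled.

**Seeding.** All randomness derives from a single seed through
`numpy.random.SeedSequence` substreams keyed by (participant, channel,
stream, trial), so adding a channel or participant never perturbs the
noise of the others, and identical seeds give bit-identical sessions.

**What the simulator does not emulate.** Air-bladder dynamics, hose
transmission delays, MRI-related artefacts, baseline re-pressurization
between tasks, non-Gaussian observer behaviour (e.g. digit preference in
gauge reading), and task-order randomization (tasks are generated in a
fixed order; the analysis is order-agnostic). Passing tests on synthetic
sessions therefore demonstrate correctness of the algorithms under the
stated signal model, not hardware performance.

## Compliance classification

Per trial, each channel's change is the stable value minus a local
baseline (mean filtered pressure over the 2 s before the cue — local, so
slow drift does not bias it). Patterns: BB requires RK/LK to increase
and RB/LB to decrease; URB requires RK up, LK *not up*, RB/LB down; ULB
is the exact left-right mirror. A change counts as an increase at
≥ +3 mmHg and a decrease at ≤ −3 mmHg; `no_increase` passes strictly
below +3 mmHg. The 3 mmHg default matches the scale of digital–analog
agreement, so compliance is never asserted on changes smaller than the
two readouts' agreement; it is configurable. Trials with a missing
channel are *non-assessable*, a distinct outcome from non-compliant.
Because the report builder takes pre-filtered input tables, summaries
can be produced over all trials or over compliant trials only.

## Validity statistics

- **Normality screen:** Shapiro–Wilk at α = 0.05; constant input returns
  a degenerate flag instead of raising.
- **Spearman ρ** with average ranks for ties; 95% CI by Fisher z with
  the Bonett–Wright standard error `sqrt((1 + ρ²/2)/(n − 3))`,
  back-transformed. At |ρ| = 1 the interval degenerates to a point (the
  z-transform diverges); a seeded percentile bootstrap is available as
  an alternative (`method="bootstrap"`). Cells need n ≥ 4 and nonzero
  rank variance.
- **Bland–Altman:** differences fixed as digital − analog throughout;
  bias = mean difference, limits of agreement bias ± 1.96·SD (sample SD,
  n − 1); proportional bias from a straight-line fit of differences
  against pair means.
- **Power analysis:** Fisher-z approximation for detecting ρ₁ against
  ρ₀: `n = ceil(((z_crit + z_power)/(atanh ρ₁ − atanh ρ₀))² + 3)`. The
  default is **one-tailed** (z_crit = z₀.₉₅): with ρ₁ = 0.9, ρ₀ = 0.7,
  power 0.80, α = 0.05 this gives n = 20; the two-tailed variant gives
  25.
- **Pairing level:** trial-level by default (each repetition contributes
  a pair, 138 pairs for 23 participants × 6 trials), which is the regime
  where narrow CIs arise; participant-level pairing (six-trial averages,
  one pair per participant) is available via `pairing_level`.
- **Multiplicity:** no correction is applied across the 12 cells;
  p-values are reported raw and the report records the number of tests.
- **Acceptability rule:** cells with ρ < 0.9 are flagged; the report
  also carries the reference correlations from the original validation
  experiment of this system class for context (their minimum, squared,
  corresponds to ~88% variance explained).

## Numerical and design choices

- Time is seconds from session start as floats; cue onsets are stored
  explicitly, never inferred from a trial grid.
- CSV is comma-separated UTF-8 with a header and "." decimals; floats
  are re-read with round-trip precision so write→read is exact.
- Sampling-rate inference on read checks timestamp uniformity to 1 part
  in 10³ and names the offending row on failure.
- Alignment errors in the validity report list the unmatched keys;
  whole cells missing from one modality are marked missing rather than
  failing the report.
- Simulated problem sizes in tests (cohorts of 3–23 participants,
  10⁴-sample agreement simulations, exhaustive rank-permutation checks
  up to n = 6) were chosen as the smallest sizes at which the tested
  statistical properties are stable.

## Known limitations

- The analog reading rule is a stylized model (trajectory average +
  Gaussian error + rounding); real observers may show digit preference
  or timing bias.
- The movement threshold and compliance threshold are pragmatic defaults
  with physical units, not estimated from data.
- Trial-level pairing treats repetitions of one participant as
  exchangeable pairs; their errors are independent in the simulator but
  may be correlated in real data, which would narrow the CIs
  artificially. Participant-level pairing avoids this at the cost of n.
- Zero-crossing localization is grid-resolution (≈ 36 ms at 28 Hz);
  adequate here because of the delayed 4 s average, but too coarse for
  onset-latency studies.
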