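# Methods

This note documents the models, estimators, parameters and numerical choices
the package implements, what the synthetic sessions do and do not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Task and data model

A session is one recording day on a single millisecond-resolution clock.
Trials of the direction task run fixation (500 ms) → color cue → variable
delay (uniform 800–1200 ms) → step-ramp target motion (750 ms; step sizes
4°/2°/1° for 20/10/5 °/s, so the ramp re-crosses the center 200 ms after
onset) → still period (uniform 500–700 ms) → reward on success. Trials carry
absolute event times; spike trains are never pre-cut, because the
cross-correlogram and event-triggered analyses need spikes across window
boundaries. Failed trials are retained in the container but excluded from all
analyses by default (`select_trials(success_only=True)`): reward delivery is
undefined on them, so exclusion is the conservative choice; a flag exposes
the alternative for cue-period analyses.

All count windows are half-open `[start, end)` in ms relative to the
alignment event. The quoted analysis windows ("100–300 ms") carry no endpoint
convention; half-open intervals make adjacent windows partition time exactly,
which in turn makes the moving-bin timecourse at one point coincide exactly
with the fixed-window classification.

## Rate estimation

PSTHs are histograms at 1 ms resolution: per-bin rate = count /
(n_trials × 0.001 s). Smoothing uses a Gaussian kernel with SD 10 ms for
spikes (5 ms for eye traces), **truncated at ±6 SD and renormalized to unit
mass**, computed on a window extended by max(100 ms, kernel half-width) per
side and trimmed back. With ±6 SD the truncated mass is ~2·10⁻⁹, so the
smoothed peak of an isolated spike equals the analytic kernel value
1/(σ√(2π)) ≈ 39.894 spikes/s at σ = 10 ms to better than 10⁻⁶, and the
unsmoothed integral identity (Σrate × n_trials × 1 ms = spike count) carries
over to the smoothed trace away from the window edges. A ±4 SD truncation
would bias that peak by ~2.5·10⁻³ of its value; the wider support costs
nothing at these kernel widths.

The Cspk-triggered cross-correlogram is returned **unsmoothed by default**
(1 ms bins): its diagnostic structure — the [−1, +2] ms blank window that
removes spikelet-contaminated simple spikes, and the post-Cspk pause — lives
at a scale the 10 ms kernel would smear. Triggers must sit ≥100 ms from both
trial edges (fixation onset → trial end); inter-trial Cspks never trigger.

The event-contribution reconstruction tiles the event-triggered PETH
(conditions pooled, as the control requires) around every event of every
trial, treats times beyond the PETH's ±300 ms span as missing, **averages**
overlapping copies (keeping the prediction in rate units; identical to
summation whenever events do not overlap), and takes a missing-data-aware
mean per condition. Timepoints with zero coverage stay missing, never zero.

## Statistics

* **Rank-sum** (Wilcoxon–Mann–Whitney): exact enumeration when the combined
  sample has ≤12 observations and no ties, otherwise mid-ranks with the
  tie-corrected normal approximation and continuity correction (via
  `scipy.stats.mannwhitneyu`). Spike counts in 200 ms windows at ~1 spike/s
  baselines are heavily tied; the tie correction keeps the empirical type-I
  rate at the nominal 5% (measured ≈ 4–5% over 10³–10⁴ null replicates).
* **Tuning criterion**: Kruskal–Wallis across 8 directions (χ² approximation,
  tie-corrected), rank-sum for the 2-direction speed task; α = 0.05.
* **Preferred direction**: the task direction circularly nearest the angle of
  Σ rate·(cos θ, sin θ); ties break toward the smaller angle; an all-equal
  curve (zero-length vector) leaves the PD undefined and raises.
* **Permutation test** for a reward effect on tuning: per-condition curves on
  the PD-aligned relative-direction grid; statistic T = mean over levels of
  the squared distance between the two population curves. Each (cell, level)
  pair swaps labels independently with probability ½ — "choose a random
  subset of pairs" made maximal-entropy and configurable; pairs missing one
  condition are never swapped. p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm)
  (add-one, never exactly zero); n_perm defaults to 2000. The statistic is
  computed on the population curves (a per-cell variant is a flag), without
  baseline subtraction.
* **No multiple-comparison correction** anywhere: per-cell tests are used
  only as classification criteria, population conclusions rest on a handful
  of tests.

## Eye-trace processing

Positions are smoothed (5 ms SD Gaussian) before central-difference
differentiation; acceleration is the derivative of the component velocities;
speed is the Euclidean norm (signed projection available). Saccades: a sample
is saccadic if |a| > 1000 °/s², or speed > 15 °/s during fixation, or
speed > 50 °/s during target motion. "Pursuit" extends from motion onset to
motion end **plus 200 ms**: the eye's velocity decays exponentially after the
target stops and would otherwise cross the 15 °/s fixation threshold without
any saccade. Contiguous saccadic samples merge; events closer than 10 ms
fuse; excision pads each event ±5 ms because threshold crossings lag true
onsets. Trial averaging treats excised samples as missing (normalized
convolution for the final smoothing, so gaps do not bleed zeros).

The drift model regresses each position axis on pupil size (OLS) and
subtracts the prediction from every sample, so corrected + predicted
reconstructs the original bit-exactly and the corrected trace is orthogonal
to pupil within the fitted scope. The quoted procedure fits "the averages of
each recording session", which is ambiguous about alignment; the
implementation fits cue-aligned session-average traces when trials are
supplied and the raw trace otherwise, and reports per-axis R² of the fit.

## Synthetic sessions

The generator's purpose is to produce data in which every analysis has known
ground truth. Spike trains come from an additive inhomogeneous-Poisson rate:
baseline + condition-dependent cue transient (window [100, 300) ms) +
von-Mises direction term gain·exp(κ(cos(θ−PD)−1)) during motion (optionally
scaled per condition) + lick-locked bumps, clipped at zero (clipping logged;
>20% clipped samples raises). Sampling is by thinning against the rate
supremum, rounded to integer ms; collisions keep the earlier spike. At 50
spikes/s the rounding collisions remove ~2.5% of spikes — a refractory-like
bias every test tolerance accounts for. A hard post-Cspk pause (default
15 ms) deletes simple spikes after each complex spike.

Defaults are the study conditions: Cspk baseline ~1 /s with a
large-reward-only cue transient of 2 spikes/s in a discriminating subset
(weak U(0, 0.3) elsewhere — most cells respond slightly more after the
large-reward cue, but only a subset is individually significant); Sspk baseline 40–70 /s with
a per-cell cue change common to both conditions (N(2, 5) sp/s) plus a signed
reward difference in half the cells, so the population difference washes out;
direction tuning in ~40% of cells with the Cspk PD anti-phase to the Sspk PD;
reward never scales the direction term. Eye traces: pupil is a slow AR(1)
(coefficient 0.9995/ms); vertical position is strongly pupil-coupled
(1 °/unit) and horizontal weakly (0.1 °/unit), mirroring the asymmetric R²
seen in recordings; white measurement noise 0.01° RMS. Pursuit velocity rises
exponentially toward gain × target speed (gains 0.95/0.85 for large/small,
latency 100 ms, τ = 45 ms — chosen so pursuit-onset acceleration
(gain·speed/τ ≈ 420 °/s²) stays clearly below the 1000 °/s² saccade
threshold; the +250 ms readout is then ≈18.4 vs ≈16.4 °/s). Saccades are
Gaussian velocity pulses; ground truth marks onset/offset at center ± 3.5 σ
(>99.9% of the displacement). Licks are a renewal process whose rate dips
after the cue (×0.3 for 600 ms) and surges after reward (×4 for 800 ms); no
quantitative lick or drift magnitudes are reported for the recordings, so
these are order-of-magnitude choices.

Seeding: every stage and every cell draws from a child stream derived from
the master seed by a counter-based spawn key, so identical configurations are
bit-identical and adding a cell does not perturb the others.

What the generator does **not** emulate: biophysics (rates are
phenomenological), Cspk waveform structure and spike sorting, serial
correlations across trials, slow drift in excitability, the choice task, and
realistic saccade main-sequence kinematics. Passing tests therefore validate
the estimators and their calibration — not claims about biological recordings.
One emulated coupling deserves note: the post-Cspk pause mechanically removes
~0.75 Sspk/s per extra Cspk/s, so cue-period Cspk and Sspk modulations are
weakly negatively coupled by construction; at the study's scale and with the
heterogeneous Sspk cue responses this stays non-significant, matching the
recordings' slightly negative but null correlation estimates.

## Scale of the shipped analyses

The study-like configuration used by the drivers, the end-to-end test and the
acceptance script is 40 cells × 15 trials per condition × direction (240
trials, ~14 min of session time), which gives the population tests clear
resolution while keeping any single run under a few seconds. Calibration
checks (permutation type-I, discrimination power and false-positive rate)
simulate per-trial Poisson window counts — the exact quantity those tests
consume — with 200–1000 replicates.

## Known limitations

* The speed task is supported by the data model, statistics and generator
  (levels = direction × speed) but the shipped drivers analyze the direction
  task; the speed-task permutation swaps (cell, direction, speed) triples via
  the same flattened-level interface, with missing levels never swapped.
* The moving-window timecourse recomputes counts per time point; at very fine
  steps this is the dominant cost of the pipeline.
* `pupil_drift_correction` assumes a linear, session-stationary
  pupil-position relationship; slow nonstationarities alias into the
  correction.
* Lick onset and offset reconstructions are exposed as separate runs of the
  same PETH machinery; the shipped driver uses onsets.
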