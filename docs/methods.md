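# Methods

## The three-state promoter model

A repressed gene is modelled with three promoter states: a long-lived
**deep OFF** state, a **permissive** state during which transcription
can occur, and **ON periods** (bursts) nested within permissive
periods. The quantities the package measures or simulates are:

- *P*<sub>O>P</sub> (`p_op`): probability that an allele exits the deep
  OFF state into a permissive period at a cell-cycle-onset draw. Each
  allele draws at the start of cycle 1 and redraws once at the start of
  cycle 2; the partial desynchronisation cycle inherits the cycle-2
  state.
- λ_ON (`lambda_on`): Poisson mean number of ON periods per permissive
  period (default 9, the scale recovered by the window-sampling
  inference below).
- Inter-ON intervals (`intervals_min`): an empirical sample of gaps
  between consecutive ON periods, resampled during simulation. The
  default sample spans 12–56 min: values are bounded above by the
  60-min permissive-gap rule (longer gaps would by definition split the
  permissive period) and below by the movie's 4-min frame interval plus
  the nascent-signal decay flank.
- ON-period amplitude: a zero-truncated mixture of a negative binomial
  and a Poisson (`AmplitudeModel`), defaults w_nb = 0.35,
  size = 2, prob = 0.35, Poisson mean = 2 — a mean of ≈ 2.6 transcripts
  per burst with a heavy tail, typical of lowly expressed
  Polycomb-class genes.
- Transcript half-life (`half_life_h`, default 2.5 h): survival of each
  transcript is evaluated **once at simulation end** as
  exp(−ln2 · age / t₁/₂), matching a protocol in which degradation is
  applied to accumulated transcripts by age rather than as a
  continuous-time death process. With age-independent rates the two are
  equivalent in distribution at the evaluation time; the once-at-end
  form is simpler and is what the simulation tests pin down.
- Cell cycle: two full 12-h cycles, each ended by a division that
  retains each transcript independently with probability 0.5, followed
  by a desynchronising partial cycle of Uniform(0, 12) h. Production
  during the partial cycle is on by default with the Poisson mean
  scaled by its duration (switchable off via `cycle3_production`,
  used by the deterministic accounting tests).

Population fitting (`fit_p_op` / `PermissiveEntrySearch`) simulates
populations over a *P*<sub>O>P</sub> grid and minimises the sum of
absolute normalized-frequency differences between histograms (a proper
metric, bounded by 2). Replicate seeds are shared across grid points so
profiles are paired; ties break toward the smaller probability. The
acute-derepression protocol appends an extra production window
(4 h / 2.5 h by default) with allele states redrawn at a raised
probability and the allele number redrawn from {2, 3, 4} to reflect
mixed cell-cycle stages, then degrades once at the very end.

## ON-period calling

The caller works on bleach-corrected trajectories calibrated by the
unitary (single-transcript) intensity:

1. Frames with zero intensity (no detected spot) are global minima.
2. Other frames are classified as candidate maxima/minima at three
   strengths: strength *k* ∈ {1,2,3} means the frame dominates (or is
   dominated by) every frame within ±*k*. A maximal plateau is
   represented by its first frame (where the steep rise stops), a
   minimal plateau by its last frame (from which the next rise starts).
   "Three degrees of strength" is qualitative in origin; this window
   definition is the package's own concrete reading.
3. Each maximum is paired with the nearest preceding minimum; maxima
   encountered before a minimum is found ("intermediate maxima") are
   discarded, the latest maximum of a group superseding earlier ones.
4. The maximum is repositioned among its five preceding frames to the
   latest frame whose rise over its predecessor is at least 0.5 unitary
   intensities — a threshold stated in transcript units that converts
   "where the steep signal increase stops" into a deterministic rule.
5. Amplitude = (intensity at max − intensity at the paired minimum) /
   unitary mean, so stacked consecutive bursts measure correctly from
   their own baseline; duration = (max − min) · frame interval.
   Re-initiation rates (least-squares slope of the rising flank, and
   its reciprocal as minutes between initiations) are reported only for
   amplitudes above 2.5 transcripts — below that, 4-min sampling cannot
   resolve a slope meaningfully.

Manual-inspection steps of the original workflow are replaced by these
deterministic rules; discarded intermediate maxima are available as a
QC list on the caller.

Photobleaching correction multiplies frame *i* by exp(rate·i)
(default rate 0.05/frame). A printed formula of the form
"1/−exp(0.05·i)" can only be meant as division by exp(−0.05·i):
a literal negative factor would make intensities negative.

## Spot following

`follow_site` picks, at every multi-spot frame, the spot with the
shortest 3D Euclidean distance to the last followed spot; the chosen
position becomes the new reference, and an ambiguous first frame
requires an explicit initial choice (the counterpart of assigning the
site manually). A nearest spot farther than `max_jump_um` (default
5 µm) is not adopted: while the site is dark the only detections are
diffusing single pre-mRNAs elsewhere in the nucleus, and an ungated
follower would permanently migrate onto them. The gate records such
frames as empty and keeps the reference, which is what makes recovery
of the generating trajectory exact in the synthetic tests.

## Allele occupancy and the permissive time fraction

Cells whose alleles never fire during a movie are invisible to
trajectory analysis. With *n* independent alleles each permissive with
probability *q*, the zero class has probability *f*₀ = (1−*q*)ⁿ;
`invert_zero_class` computes *q* = 1 − *f*₀^(1/n). Although the
original description labels the allele-count distribution "negative
binomial", the printed probabilities are reproduced (to input rounding)
by this Binomial(n, q) zero-class inversion, which is what the package
implements; the naming discrepancy is surfaced by
`check_zero_class_consistency`, which flags — and never alters —
reported values that do not follow from their zero fractions.

`fraction_time_permissive` sums observed per-allele permissive
durations and divides by total allele-time after imputing silent
alleles: the Binomial(n, q) allele-count distribution is simulated over
`n_sim` cells, the silent:permissive ratio scaled to the observed
allele count (rounded to a whole number of alleles), and each imputed
silent allele contributes a full movie of OFF time. Uncertainty is a
bootstrap s.d. over the observed durations.

## λ_ON window inference

An 8-h movie may capture only part of a permissive period. For each
candidate λ, permissive periods are simulated (zero-truncated
Poisson(λ) ON periods at empirically resampled spacings), an 8-h window
is placed uniformly over each period extended by one window length (so
partial overlaps occur; placement is independent per period), and the
captured ON-period counts are histogrammed. The distance of this
distribution to the observed one is minimised via a cubic polynomial
fit over the candidate grid; a minimum falling outside the grid raises
a warning and falls back to the discrete argmin. The distance is the
same sum-of-absolute-frequency-differences used for population fitting.

## SPT kinetics

Track linking is greedy nearest-neighbour within `max_jump_nm`
(192/288 nm at slow rates, 768 nm at fast rates), one frame gap
bridged, candidate pairs assigned in order of increasing distance, ties
by track then detection order — the assignment rule is the package's
own, as such rules are rarely published. A track's duration counts both
end frames.

Bound-molecule survival (complementary cumulative distribution of track
durations, normalized to 1 at the first timepoint t₁) is fitted by
nonlinear least squares with
y = A·e^(−t/τ₁)/e^(−t₁/τ₁) + (1−A)·e^(−t/τ₂)/e^(−t₁/τ₂),
A ∈ [0,1], τ > 0, initialized from a log-linear head/tail split.
Collapsed components (|log τ₂/τ₁| < 0.05) trigger a single-exponential
refit with a warning. Fitting the cumulative curve follows the original
presentation; the tests cross-check against the closed-form censored
MLE on an exponential sample. The H2B control is fitted with the
single-exponential variant and the stable binding time corrected as
τ_bound = τ_H2B·τ_dwell/(τ_H2B − τ_dwell), which is exact when
photobleaching is an independent exponential censoring process — the
composition identity the tests verify analytically.

Diffusion coefficients use the lag-1 MSD, D = MSD(Δt)/(4Δt) (2D),
restricted to strictly consecutive frame pairs and to tracks of at
least four frames. Mobility fractions are the weights of a
two-component Gaussian mixture over log₁₀(D) (EM with restarts,
components ordered by mean). Three-state jump-length kinetic modelling
of the kind done by external SPT tools is out of scope.

## Synthetic data: what it emulates, what it does not

Generators emulate: 8-h movies at 4-min frames; unitary intensities
Normal(330, 120) a.u.; pulsatile trajectories whose ON periods initiate
one transcript per frame (re-initiation every 4 min, the observed
scale); detection noise floored at zero; exponential photobleaching;
diffusing-pre-mRNA distractor spots with unitary-scale intensities;
bi-exponential dwell times censored by an independent bleaching clock
and discretized to the frame grid (minimum one frame); 2D Brownian
localizations with Gaussian localization error; mono-exponential decay
series with multiplicative noise.

Nascent transcripts accumulate during an ON period and are all released
`signal_persistence_min` (default 6 min) after the last initiation, so
persistence shapes only the decay flank. A literal fixed per-transcript
residence window starting at initiation cannot reproduce multi-
transcript amplitudes at 4-min spacing (the signal would plateau near
two transcripts); the accumulate-then-release form is the simplest
model consistent with amplitudes measured at the peak. The 6-min
default is a placeholder — elongation/termination kinetics for these
genes are not established — and only affects the flank.

Not emulated: pixel-level images and PSFs, camera noise, spot-detection
failures, cell movement or division during movies, transcript-state
blinking in SPT, axial (z) effects, and the slow drift of real
microscopes. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not robustness to
every artefact of real microscopy data.

## Numerical choices and problem sizes

- Amplitude mixture EM: responsibilities in log space; the NB shape is
  re-estimated each M step by a bounded 1-D search on log-size with the
  success probability tied to the weighted mean; degenerate (all-equal)
  samples fall back to a single Poisson component with a warning.
  Zero-truncated sampling is by rejection with a cap, degenerating to 1
  (the correct limit) when the mixture mass at zero approaches 1.
- All simulation randomness flows from `numpy` `SeedSequence` spawning:
  per-cell substreams are derived deterministically, and population
  fits share replicate streams across grid points.
- Recovery test sizes (2000-cell populations, 5 replicates per grid
  point, 2000 window simulations per candidate λ, 10⁴ SPT tracks) were
  chosen as the smallest sizes at which the statistical tolerances of
  the recovery checks are comfortably met on a single CPU.
- Degenerate inputs: empty spot tables are valid (empty trajectory);
  all-zero trajectories call no ON periods; a survival sample whose
  durations all equal t₁ yields a step curve; `half_life_h = inf`
  disables decay; `extra_h = 0` reduces derepression to the untreated
  protocol.

## Known limitations

- The ON-period caller's extremum strengths and repositioning threshold
  are concrete substitutes for qualitative criteria; they are validated
  against synthetic truth, not against manually curated real traces.
- `fraction_time_permissive` imputes silent alleles in expectation
  (scaled simulated ratio); it does not model cell-to-cell variation in
  allele number.
- The window-sampling inference places windows independently per
  permissive period rather than sliding over a concatenated timeline;
  with windows much longer than typical periods the two differ only in
  edge effects.
- Survival fitting weights all curve points equally; very long, sparse
  tails can bias τ₂ slightly for small samples.
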