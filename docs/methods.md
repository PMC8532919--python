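# Methods

This note documents the models and numerical choices behind roamkit, what
the synthetic generators do and do not emulate, and the design decisions
that were genuinely open.

## Event logs and the dark phase

The observational unit is an antenna contact `(timestamp, antenna_id,
animal_id)`. Timestamps are naive local times — the emulated facility runs a
single clock, and seasonal lighting changes are expressed as dated regimes
in the light-schedule table (no sub-day transitions, no timezone math).
All intervals are half-open `[start, end)`, and a *night* is labelled by the
calendar date of lights-off, so the nightly slices plus the light-phase
remainders partition the log exactly once.

Ring antennas re-read a stationary animal, so the contact stream can be
debounced: within each `(animal, antenna)` stream an event is kept only if
it falls at least `refractory_s` (default 1 s) after the previously *kept*
event of that stream. The chain rule makes deduplication idempotent.
Whether spatial-usage probabilities should be built from raw reads or
debounced contacts is a genuine modelling choice; both modes are exposed
(`refractory_s = 0` is the raw mode) and the nightly-RE driver uses 1 s.

## Roaming entropy

`RE_{i,t} = −Σ_j p_{i,j,t} log p_{i,j,t} / log k` with `0·log 0 := 0`.
Natural logarithms are used internally; the value is base-invariant because
numerator and denominator share the base. `k` is the number of *installed*
antennas from the layout (27 here), not the number contacted — an animal
that never visits the upper levels genuinely has lower roaming entropy.
The final ratio is clamped to `[0, 1]`: mathematically the entropy of a
probability vector lies in `[0, log k]`, and the clamp only removes
float-rounding residue of order 1e-16 (e.g. for the uniform vector at
k = 27).

Nights with zero contacts leave RE undefined. They are flagged missing,
excluded from group summaries, and contribute 0 to the cumulative sum
(cRE is a plain sum, so a missing night neither interpolates nor breaks the
series).

Group summaries report mean ± sd (sample sd, n−1), CV = 100·sd/mean, max,
min and n, matching the reporting convention of home-cage phenotyping
tables. Rounding happens only at presentation.

## Activity rule and heatmap

A 15-minute bin is *active* for an animal when ≥ 2 distinct antennas were
contacted in it. Bins are aligned to the wall clock (00:00, 00:15, …),
half-open, 96 per day; distinct-antenna counting is insensitive to
same-antenna re-reads, so the rule runs on raw events. The colony heatmap
is the day × bin sum of the boolean matrix.

## Repeatability

Per 4-week window, repeatability is the one-way ANOVA intraclass
correlation with animal as the grouping factor:
`σ²_within = MS_W`, `σ²_among = (MS_A − MS_W)/n₀` with
`n₀ = (N − Σn_i²/N)/(a − 1)` for unbalanced groups, negative among-group
components truncated to 0, so `R ∈ [0, 1]`. The classical closed form was
chosen over a likelihood-fit mixed model because it is exactly testable
against a brute-force variance-components computation (and against an
independent ICC(1,1) implementation); for fully degenerate data
(`MS_A = MS_W = 0`) R is defined as 0.

Uncertainty: a cluster bootstrap resamples whole animals with replacement
(animals are the exchangeable units for a between-animal variance ratio);
resamples consisting of clones of a single animal carry no
between/within structure and are excluded. Significance: observations are
permuted across animals with group sizes preserved,
`p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm)` — the +1 keeps finite
permutation counts from reporting p = 0. The pooled vector is sorted before
permuting so the seeded permutation stream does not depend on animal
ordering. Every resampling routine requires an explicit seed; there is no
global RNG state.

Windows are anchored to the first night of the series, advance exactly one
week, span exactly four, and partial trailing weeks are dropped; a 20-week
series yields 17 windows. The analysed span is an input, not inferred from
the data.

## Resting metabolic rate

The cumulative-frequency curve plots, against each distinct V̇O₂ value, the
percentage of samples at or below it (ties share the highest rank). A
resting/active bimodal trace makes this curve S-shaped, and the continuous
two-segment fit `y = β₀ + β₁x + β₂(x−ψ)₊` places its breakpoint ψ where the
steep resting rise gives way to the shallow active tail. ψ is found by RSS
grid search over 200 interior x-quantiles (2nd–98th percentile, ≥ 3 points
per side) followed by golden-section refinement between the best
candidate's neighbours; ties break to the smaller ψ. Grid-plus-refinement
was preferred over iterative linearisation because it is deterministic,
needs no starting value, and cannot be trapped by the S-curve's second
bend; the two agree on well-separated breakpoints. The two-segment RSS can
never exceed the single-line RSS (nesting); when it improves on it by less
than 1% the fit is flagged as having no material breakpoint.

RMR is the arithmetic mean of samples strictly below ψ, in mL min⁻¹ kg⁻¹
(absolute flows are converted with body mass). Degenerate traces (too few
distinct values for any admissible breakpoint, e.g. constant V̇O₂) return
the trace mean flagged `degenerate` rather than an error, so a batch over
many animals completes with the problem cases marked. On simulated
two-state traces with modes ≥ 4 within-mode sd apart the recovered RMR sits
within 2% of the generating rest mean; the residual bias is the truncation
of the rest mode's upper tail at ψ and is < 0.5% for the default geometry.

## Trend statistics

All reported trends are simple OLS of one response on one predictor (fitted
via statsmodels), printed as slope, F(1, n−2), two-sided p and adjusted R².
Correlation is Pearson's r with the t-test on n−2 df. Following the
exploratory-design convention of the emulated study, **no multiple-testing
correction is applied**; pairwise-correlation tables carry raw p-values and
an explicit `*uncorrected*` flag. Degenerate corner cases are pinned down:
a constant response reports F = 0, p = 1, R² = 0; a numerically perfect fit
reports F = ∞, p = 0.

## Synthetic colony

The generator stands in for undeposited raw recordings; its defaults are
the emulated study's conditions — 20 mice, 27 antennas on 5 levels, 12/12 h
light cycle (summer 08:00/20:00), months-long span.

* **Antenna graph.** 27 nodes in 5 level-clusters (6,6,5,5,5), chained
  within a level, single "tube" edges between consecutive levels. This is a
  documented approximation of a multi-level enclosure's topology, not a
  reconstruction of any particular wiring; alternative layouts load from an
  edge list.
* **Movement.** Each mouse is a biased one-step random walk on the graph:
  from antenna *a* the next contact is drawn from the closed neighbourhood
  of *a* with weights given by the mouse's preference vector. Contact times
  come from a piecewise-constant-rate Poisson process (hourly segments),
  exact rather than thinned, with rate
  `base_i · circadian(h) · aging^day · night_i,day`. The circadian profile
  is indexed by hours since lights-off (so it follows the seasonal schedule)
  and defaults to dark 1.0 / light 0.15 with 2.0 peaks in the first and last
  dark hours; `night_i,day` is a per-night lognormal effect (σ = 0.3)
  carrying the generating within-animal variance.
* **Home ranges.** A mouse's preference puts `1 − roam_share` of its mass on
  a home antenna and spreads the rest with exponential decay in graph
  distance. Roaming shares are lognormal across mice
  (median 0.10, σ = 0.25); aging multiplies both the event rate and the
  roaming share by 0.997 per day, so the effective range contracts with age
  and nightly RE genuinely declines. These defaults were calibrated once
  against the published plausibility ranges of the emulated system
  (first-night RE ≈ 0.08 with ~20% CV, cRE accumulating ≈ 0.07 per night)
  and then frozen. Raw Dirichlet preferences were rejected: they produce
  colonies whose between-animal RE spread is an order of magnitude too wide.
* **Ground truth.** For each mouse the sidecar records its base rate, home,
  roaming share, day-0 preference, the walk's stationary distribution
  (eigen-analysis of the transition matrix) and the implied asymptotic RE —
  the oracle the empirical RE is tested against.

What the simulator does **not** emulate: social interaction, dominance,
nesting and feeding structure, body-mass dynamics, cage-cleaning
disturbances, post-procedure activity dips, or any fitting to real
trajectories. Passing recovery tests therefore shows the *estimators* are
correct at the study's scale and noise structure, not that real colonies
satisfy the generator's assumptions. One known divergence: with a purely
multiplicative aging decline the between-animal RE spread compresses over
months, so windowed repeatability drifts slightly *down* in long default
runs; rising individual consistency is a separate scenario (constructed by
growing the animal-effect scale over time) and is exercised as such in the
tests.

Because mapping event-level rate effects to an RE-scale intraclass
correlation has no closed form, ICC parameter-recovery uses a direct
Gaussian random-intercept panel generator (`simulate_re_panel`): nightly
values `mean + a_i + e_it` with the variance split chosen so the generating
ICC is exact. V̇O₂ traces come from a two-state Markov-modulated Gaussian
(stationary rest probability 0.8, mean bout scale 10 samples, rest 40 /
active 80 mL min⁻¹ kg⁻¹, σ = 2) with the generating rest mean exported.

## Problem sizes used in the checks

Recovery suites run at the emulated study's scale: 19 animals × 28 nights
for ICC (200 replicates per condition, ±0.05 tolerance on the mean), 200
replicates at n = 500, σ = 0.5 for breakpoint recovery (|ψ̂ − ψ| < 0.5 in
≥ 95%), 600-sample calorimetry traces, and one seeded 20-mouse × 28-night
colony for the qualitative phenomena (RE decline, cRE variance growth).
The analysis drivers use the full 140-night span. The entropy stress suite
is 10,000 Dirichlet(1,…,1) vectors plus all degenerate cases at k = 27.

## Known limitations

* The ICC is the unadjusted, original-scale one-way estimator; no
  covariate-conditional or link-scale repeatability.
* The breakpoint model allows exactly one kink; traces whose
  cumulative-frequency curve has no shallow middle section (heavily
  overlapping modes) yield a threshold inside the merged mode and a biased
  RMR — flagged only indirectly via the RSS-improvement diagnostic.
* The activity rule is blind to movement that stays within one antenna's
  field, and the 15-min clock alignment makes bin membership sensitive to
  clock offset.
* Mixed/nested random-effects modelling and behavioural-observation
  analysis are out of scope; behaviour frequencies enter only as plain
  per-animal numbers in the correlation table.
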