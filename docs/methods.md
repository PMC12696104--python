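# Methods

This note records the models, conventions, numerical choices and known
limitations behind `openfieldkit`, in the order the pipeline applies them.

## Track standardization

Tracker exports are reduced to a common representation (cm, seconds,
arena-centered, uniformly sampled, gap-free) by a fixed pipeline: unit
conversion → zero-centering → smoothing → subsampling → interpolation.

* **Arena center.** An explicit center from file metadata is used when
  present; otherwise the center of the minimal enclosing circle of the
  observed points (Welzl's algorithm). For near-collinear degenerate tracks
  the bounding-box center is used with a warning. The half-disc case (an
  animal that only visited half the arena) recovers the center to within
  about a tenth of the radius.
* **Smoothing.** Some trackers export pre-smoothed coordinates; dialects
  marked pre-smoothed are left untouched, all others get a centered moving
  average over `round(sample_freq/6)` samples (forced odd, minimum 3),
  applied to x and y independently. The window is a declared convention, not
  a claim of equivalence to any vendor's filter; it is configurable
  (`smoothing_window`).
* **Subsampling.** The frame nearest each target time `k·time_bin_size` is
  *selected*, not averaged — averaging would shrink step lengths and defeat
  the `inactivity_threshold` semantics. When the target period is an integer
  multiple of the native period this keeps every k-th frame exactly.
* **Interpolation.** Interior runs of missing samples are filled linearly in
  x and y; leading/trailing gaps are trimmed, never extrapolated. Tracks
  with more than 50% missing samples or fewer than 3 samples after
  subsampling are rejected; tracks whose radius exceeds the arena radius by
  more than 5% are rejected as calibration errors.

## Measures

* **Activity.** ΔD_i is the Euclidean step beginning at sample i (n samples
  → n−1 steps). Steps below `inactivity_threshold` (cm) are set to exactly
  zero; the thresholded series feeds *everything* downstream, so the
  threshold defines what "ΔD = 0" means in the turn taxonomy.
* **Sectors and visits.** The boundary is divided into M = 360/`node_size`
  equal sectors (default 0.1° → 3600 sectors; check the arc length against
  the subject's body length). A *visit* is an entry event: a sample in the
  edge band (r ≥ R − `edge_dist_cm`) whose sector differs from the previous
  in-band sample's sector. Lingering adds nothing. When consecutive in-band
  samples land in non-adjacent sectors, every intermediate sector on the
  shorter angular arc is credited once (the animal necessarily passed
  through); an exact half-circle tie is imputed counterclockwise — an
  arbitrary, documented convention, exempted from the rotation-invariance
  property at exactly 180°. Imputation applies only between consecutive
  in-band samples: an animal that leaves the band radially and re-enters in
  a different sector is credited the new sector only, and re-entering the
  *same* sector after a radial dip is the same visit unless another sector
  intervened (prevents radial jitter from inflating counts). The first
  in-band sample of a track counts as a visit. Setting
  `edge_dist_cm = arena_radius_cm` disables the edge restriction.
* **Coverage.** C(t) = v_min(t) + (1/M)·#{v(i,t) > v_min(t)}, evaluated by
  carrying visit counts forward at `coverage_sample_period` (default 1 s).
  It is bracketed by v_min ≤ C < v_min + 1 and non-decreasing. The
  individual coverage asymptote is extracted by a bounded least-squares fit
  of the asymptotic increase form a(e^{bt}−1) (a<0, b<0); the asymptote −a
  is the number of visits per sector needed for full habituation. PICA
  divides coverage by the individual's asymptote, PGCA by the group mean of
  individual asymptotes (computed only after every track is measured).
  Non-converged asymptote fits exclude that individual from PICA with a
  warning.
* **Turns.** For three consecutive samples the turn magnitude is
  θ = 180° − φ with φ the law-of-cosines interior angle at the middle
  point (cosine clamped to [−1, 1] before arccos). θ ≤ 90° counts as
  continuing — the boundary case is assigned to the positive class. A turn
  is undefined whenever either adjacent thresholded step is zero; those
  decisions are classified by step lengths alone (stop, restart, stay).
  Decisions taken outside the edge band are recorded as missing.
* **Motion probabilities.** Three denominators for the five outcomes at
  each decision time across a group: *given-previous* conditions on the
  precondition class (movers: ++/+−/+0; resters: 0+/00), so the two
  conservation identities hold exactly wherever defined; *given-any*
  conditions on any classified decision (all five sum to 1); *raw* divides
  by group size (sums to the in-edge fraction). Averaging an individual's
  conditional 1/0/NaN series across a group reproduces the group
  probability exactly, which is what the group summaries and the
  individual-level model fits rely on.

## Group summaries

Temporal relationships share a sampling grid, so mean and SEM are taken per
time point over non-missing individuals (SEM is sample SD/√n, missing when
n = 1). Coverage-domain relationships pool the raw (x, y) tuples of all
individuals — averaging the series would pair average activity with average
coverage at a time point, not activity at a coverage level — sort by x
(ties broken by individual index then time, for determinism) and bin either
by tuple count (`n_points`, default 50; used for coverage/PICA/PGCA) or by
equal-width ranges (`n_bins`, default 50; used for percent coverage, whose
fixed [0, 1] support suits fixed ranges). Both methods are exposed; the
defaults follow which domain each handles well. The 50/50 defaults give a
10-min, 1 Hz cohort of a few dozen individuals on the order of 30+ occupied
bins.

## Model fitting

Six registered forms (exponential decay a·e^{bx}+c; asymptotic increase
a(e^{bx}−1); linear decrease/increase ax+b; sigmoidal decay/increase
a/(1+e^{−b(x+c)})) with sign constraints per parameter; users can register
more. Defaults per y-family: exponential decay for activity, P++ and P+0;
asymptotic increase for coverage, P+−, P0+ and P00. The stopping
probability P+0 admits either reading (it rises in some species, falls in
others), so its default is a deliberate choice exposed for override; the
restart probability P0+ mirrors the stay probability's complement.

* **Solver.** scipy trust-region reflective bounded least squares,
  tolerances 1e-10, `max_f_eval` 5000. Data-driven initial guesses (e.g.
  for exponential decay: c from the series minimum, a from the early mean,
  b from −3/x-span); starts are nudged strictly inside bounds.
* **Naive pass.** Bounds are the form's sign constraints only (e.g.
  b ∈ (−∞, 0]) — wide enough to be honest, tight enough to exclude
  wrong-sign solutions.
* **Bounds pass.** Per (x, y, form) and per group: mean ± `bound_level`
  (default 2) sample SDs of the converged naive parameters, epsilon-widened
  when the SD is 0, and intersected with the sign constraints so the refit
  box cannot cross zero (preserving the parameters' interpretation).
  Bounds are derived within each group separately.
* **Refit pass.** Constrained least squares in the box. When the naive
  optimum already lies inside the box it is returned directly — it is the
  constrained optimum, and skipping the solver keeps large replicate
  experiments fast. Outliers land on the box boundary by construction.
  Non-converged individuals are excluded from bounds, refits and statistics,
  with a log entry.
* **Group fits** apply the same constrained fit to the binned group means.
* **Individual motion-probability fits** use the individual's conditional
  1/0/NaN outcome series as y. These are noisy binary series; least squares
  on them estimates the underlying probability trend, and relationship
  defaults that do not match a cohort's actual trend shape produce
  degenerate (boundary) parameters — harmless for null-calibration but
  worth overriding when the trend is visible in the component plots.

## Statistics

One-way MANOVA (statsmodels; Wilks' lambda with Rao's F approximation,
reported alongside Pillai's trace) over all parameters when group sizes
support it; per-relationship MANOVA sub-tests otherwise and always; with a
single dependent variable the sub-test reduces analytically to the one-way
ANOVA. Per-parameter one-way ANOVAs and pairwise two-sided pooled-variance
t-tests (Welch by flag) with Holm–Šidák step-down adjustment across the
pairs of each parameter (`pvalue-hs`). α defaults to 0.05. The significance
chain — a parameter is *interpreted* as significant only when its
relationship sub-test and its own ANOVA are both below α — gates
interpretation, never computation; untestable cells print NA.

## Synthetic explorer

The generator emulates an edge-dwelling habituating walker at the study
conditions used throughout the tests: 10-minute tracks at 1 Hz in a 4.2 cm
radius arena with a 1 cm edge band. Defaults: a0 = 1.5 cm, b0 = −0.008 /s,
c0 = 0.06 cm (mean nonzero step length a0·e^{b0 t}+c0, gamma-distributed
with shape 4); persistence half-life 150 s (the probability of continuing
in the same tangential direction decays from 1 toward 0.5 with this
half-life, and the pause probability ramps from 0 toward
`pause_prob_final` = 0.3 on the same clock); edge-band occupancy 0.9 via a
two-state radial Markov chain whose stationary distribution equals the
affinity. Direction re-draws restore a per-individual preferred circling
direction with probability 0.75 (`handedness_bias`): without it the angular
motion is purely diffusive and the walker never accumulates the several
full boundary circuits that real thigmotactic subjects make, leaving the
per-sector minimum visit count near zero. With it, cohort coverage
asymptotes land in the realistic several-visits-per-sector regime. Pauses
are exact zero steps so the inactivity threshold can be tested at 0 and at
positive values; an optional jitter adds sub-threshold wobble. Cohorts draw
a0, b0, c0 and the half-life per individual with multiplicative factors
1 + SD·z (default SD 0.15), one seeded generator per track
(seed = cohort seed + index) for reproducibility under parallelism.

What the generator does *not* emulate: body posture and orientation,
wall-following curvature within a step, species-specific pause-bout
structure, lighting or circadian effects, or tracker segmentation noise.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis*, not biological fidelity of any particular dataset.

## Validation experiments and problem sizes

* The split-population experiment simulates one 110-individual cohort
  (600 s at 1 Hz), splits it into two random halves 100 times, and runs the
  sub-test → ANOVA chain on the default grid each time. The default grid is
  x ∈ {time, percent coverage} with activity, coverage-vs-time and the five
  given-previous motion probabilities: 13 relationships, 32 parameters —
  the scale at which the method is meant to operate. Naive fits are
  computed once per individual and reused across splits; only bounds,
  refits and tests are replicated. The mean fraction of parameters
  significant in both tests stays inside a binomial band around the nominal
  0.05.
* Parameter recovery uses noiseless and 5%-noise data at 50–200 x-points,
  100 noise seeds per form; brute-force oracles re-derive activity, visit
  counts, turn classes and binned summaries on 100 random 200-sample
  tracks.

## Known limitations

* Circular arenas only; rectangular fields would need a boundary
  re-parameterization first.
* One-way designs only; two-factor experiments should export
  `individual_params.csv` and run two-way MANOVA/ANOVA/Tukey externally.
* The MANOVA F approximations assume approximately multivariate-normal
  parameters; heavily misspecified model forms produce boundary-clustered
  parameter distributions for which the sub-test p-values are approximate
  (the chain remains null-calibrated in the split-population experiment).
* Dialect parsers cover one generic delimited format per tracker family,
  not every proprietary export variant; reformat exotic files to the
  generic time/x/y layout.
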