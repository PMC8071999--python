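# Methods

## The task being modelled

A navigator learns the locations of three hidden targets inside a ~5 × 5 m
navigable arena embedded in a 750 × 750 m virtual world whose only
orientation cues are four unevenly spaced distal mountains. A session has
77 trials: three acquisition blocks of 16 trials (one target per block,
four start locations) each closed by a single probe from a novel start; a
block of 8 visible-target control trials; 15 delayed probe trials; and 3
cue-conflict probes in which one mountain is rotated 20° clockwise or
counter-clockwise about the target. The navigator is disoriented between
trials, so responses must rest on the visible cue array, not on an
inertial bearing.

All geometry uses one frame: arena-centred Cartesian metres, x east,
y north; yaw and bearings in degrees counter-clockwise from north. The
coordinate frame is a package convention — the analyses are invariant to
it, and the cue-weighting index is tested for invariance under global
rotations and translations.

## Trial metrics

- *Distance error* — ‖response − target‖ (m).
- *Total path* — sum of distances between consecutive trajectory samples.
  Because sampling is discrete (~10 Hz) this slightly under-measures a
  curved walk; no smoothing or outlier rejection is applied.
- *Optimal path* — the straight start→target distance; *excess path* is
  total − optimal. Simulated trajectories cover the full trial (walk to
  the response, then to the revealed target), so excess path is
  non-negative by the triangle inequality.
- *Total rotation* — unsigned accumulation of yaw increments, each wrapped
  to (−180°, 180°] before taking absolute values. Unsigned accumulation is
  what yields cumulative totals on the order of a thousand degrees per
  probe block.
- *Excess rotation* — total rotation minus the single initial turn needed
  to face the target from the start heading. "Excess" has no canonical
  baseline; a zero baseline is available via
  `compute_trial_metrics(..., rotation_baseline="zero")`, and the window
  can be restricted to samples before the response
  (`rotation_window="response"`) since it is ambiguous whether reported
  rotation totals include the post-response walk.
- *Median containment radius* — the median of a set of distance errors:
  with all targets centralised at the origin, the radius containing half
  the responses.
- Summaries aggregate trials to subject means within each (group,
  condition) cell before any group statistic, because the subject is the
  random unit of the mixed design. Single-subject cells report SD = SE = 0
  by convention. Missing yaw leaves rotation metrics undefined (flagged,
  never imputed).

## Cue-weighting geometry

A mountain move is a rotation of the mountain's position by a signed angle
about the target, which preserves the mountain–target distance. The
*implied moved target* — where the target "would be" had it moved with the
mountain — is defined through the mountain's bearing shift Δφ as seen from
the arena centre: the target is rotated by Δφ about the centre. For a
distal cue (≥100 m) rotated 20° about a target within ~2 m of the centre,
Δφ is within 0.2° of the nominal angle, and the implied target stays at
the target's radius inside the arena. The literal alternative — applying
the mountain's translation vector to the target — would put the implied
target ~100 m outside a 5 m arena for a 20° rotation of a 300 m-distant
cue, which cannot describe where a navigator inside the arena responds; it
is retained behind `implied_moved_target(..., mode="translation")` for
comparison.

The per-trial index W = EMM/(EMM+E3M) equals 1 at the static target and 0
at the implied moved target, and increases monotonically along the segment
between them. A subject's weighting value is the mean of W over their
three moved trials, and those subject values feed the group tests.

Under the generative response model r = w·T_static + (1−w)·T_moved + ε
with isotropic noise, the *mean* of per-trial W is biased toward 0.5
(symmetric noise inflates whichever distance is smaller in relative
terms), so it does not recover w except at w ∈ {0, 1}. The estimator of
record for generative parameters is `fit_agent_params`: the pooled
least-squares projection of responses onto the implied→static segment,
clipped to [0, 1], with σ̂ the RMS residual distance divided by √2. This
bias also means that with realistic noise levels the observed group-mean W
sits closer to 0.5 than the generative w — a caveat for interpreting W in
real data as much as in simulation.

## Synthetic navigator agents

The generator's defaults are the study conditions the analyses assume:
12 younger and 15 older subjects; response noise σ_young = 0.6 m,
σ_old = 0.9 m (a 1.5× ratio); generative weights w_young = 0.46,
w_old = 0.40 (both near the equal-weighting region, the older group
leaning slightly more on the moved beacon); walking speed 0.5 m/s
(a deliberate, conservative pace for head-mounted-display navigation);
sampling at 10 Hz. Responses are the target (or the moved-trial mixture
centre) plus isotropic Gaussian noise, resampled until inside the arena —
truncation, not clipping, so no probability mass piles up on the walls.
Trajectories are piecewise-linear walks through 0–3 uniform via points
(Poisson(1), capped), sampled at the trial's rate with yaw facing the
motion direction; they exist so path metrics have realistic inputs, and
their shape is cosmetic. Trial counts follow the 77-trial schedule; the
delayed block marks repeated target–viewpoint pairings as `same` and
never-seen pairings as `different` by a first-seen rule, and places the
matched-pair trials at overall indices 65/70 (same) and 66/67 (different).

Mountain bearings (uneven, ≥30° apart, 250–400 m) are seeded random;
target and start coordinates are fixed defaults (three pedestals ~1.8 m
from the centre; eight equally spaced perimeter starts) and fully
configurable, since the real environment's coordinates are not published.

The generator deliberately omits: learning across blocks (acquisition
precision is stationary), perceptual/motor error on visible trials
(responses are exact contacts), per-trial correlation, fatigue, and
individual differences beyond group membership (per-subject w jitter is
not enabled by default). Passing tests on this data therefore validate the
*analysis machinery* — geometry, metrics, estimators, test statistics —
not any claim about human behaviour; in particular the generator's group
contrast is stronger and cleaner than real cohorts, which is why the
power check at these defaults rejects in essentially every replicate.
Z-scores are drawn per test from the older-cohort battery means/SDs
(younger adults from the standard normal), so a minority of simulated
older subjects legitimately fail the screen.

## Inference

- t tests and the rank-sum statistic are delegated to scipy behind the
  module surface; Cohen's d is t/√n for one-sample tests and
  |Δmean|/pooled SD (n−1 weights) for Welch tests. The Welch-d definition
  is documented rather than matched to any published table, since
  trial-level vs subject-level aggregation changes it.
- The rank-sum W is the first sample's rank sum minus n₁(n₁+1)/2
  (Mann–Whitney U of the first sample); the p-value is the exact
  permutation distribution when the combined n ≤ 20 with no ties, else the
  tie-corrected normal approximation with continuity correction.
- The 2×2 mixed ANOVA is computed from sums of squares with subject nested
  in group: the between-group effect is tested against subjects-within-
  group, the condition and interaction effects against condition × subject.
  With unequal groups the main-effect tests are Type III (unweighted cell
  means), chosen for invariance to group-size imbalance; for this design
  they reduce to exact pooled-t identities (group F = t² on subject means,
  interaction F = t² on difference scores), which is how the
  implementation computes them and how the tests verify them against a
  projection-matrix oracle. Degenerate all-equal data defines F = 0.
- The JZS Bayes factor integrates the Cauchy scale mixture by adaptive
  quadrature (scipy `quad`) on the log-transformed mixture variable over
  [−30, 30] (e^±30 ≈ 10±13, far past any mass), with the integrand
  peak-normalised in log space so large |t| cannot underflow; relative
  tolerance 1e-9, and the implementation is cross-checked in tests against
  an independent port of the reference package and a Monte-Carlo oracle.
  Effective N is n for one-sample and n₁n₂/(n₁+n₂) for two-sample designs;
  the default prior scale √2/2 ("medium") is configurable. Evidence labels
  use the conventional 1–3 / 3–10 / >10 bands applied to max(BF₁₀, BF₀₁).

## Pipeline

One call (or `watermaze simulate`/`analyze`) produces metrics.csv,
weighting.csv, screening.csv, stats_report.json/md and a run log carrying
the seed, a config hash, and the n per analysis cell — the last because
with trial tables in hand either trials or subjects could be the unit of
analysis, and the choice (always subjects here) should be auditable.
The delayed-probe ANOVA uses the matched-pair scheme (trials 65/70 vs
66/67 by default) as a configurable trial-index mapping. All randomness
flows from a single seed through spawned generators, and identical
seed + config reproduce every output byte-for-byte.

## Known limitations

- The implied-target construction assumes the navigator re-anchors to the
  arena centre; other plausible anchors (the response-time self-position)
  are not modelled.
- The mixed ANOVA is specialised to the 2×2 design the analyses need; it
  is not a general unbalanced mixed-model engine, and mixed-design Bayes
  factors (which require Monte-Carlo over random-effect priors) are out of
  scope.
- The per-subject weighting value averages only three moved trials, so its
  sampling noise is large; group tests on it inherit that.
- The generator's noise model is isotropic and stationary; real response
  errors are positively skewed and target-anisotropic.
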