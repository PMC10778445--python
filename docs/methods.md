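# Methods

This note documents the statistical procedures, the synthetic-cohort
model, and the numerical and design choices behind `stancemcid`. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Outcome measures

A four-quadrant stance platform reports percent body weight per limb
per trial. Sessions of `min_trials` (default 20) trials are averaged
per limb; trials beyond the minimum are all used. Each trial is
validated against two contracts before aggregation: every load in
[0, 100], and the four-limb sum within 100 ± `sum_tol` (default ±2
percent points). Out-of-tolerance trials are rejected with the trial
index named, never renormalised: a bad sum usually means a paw off its
quadrant, which re-scaling would silently launder.

**Deviation** is `|20 − wb_mean|` for a hind limb. The absolute value
(rather than signed `20 − wb`) is a deliberate choice: cohorts with
bilateral disease contain limbs loading above 20% (compensation), and a
signed definition would let over- and under-loading cancel in cohort
means, while "improvement = reduction" only makes sense for a
magnitude. **Symmetry index** is
`|(WBR − WBL)/((WBR + WBL)/2)| × 100`, symmetric in its arguments,
invariant under common scaling of the two loads, in [0, 200] and
undefined (an explicit error) only when both hind loads are zero.

SI is a per-dog quantity (one left–right pair). For limb-level
analysis tables the dog's SI is replicated onto both limbs so the SI
rows have the same n as the deviation rows; the replication is flagged
in the table metadata and in the report footer. Forelimb loads are
carried through I/O but not analysed.

## Anchor grouping

The anchor is a five-level ordinal global quality-of-life response at
baseline and day 15. Classification is a total function on the 25
ordered pairs: unchanged → "the same" (5 pairs), exactly one level
better → "somewhat better" (4 pairs), everything else → excluded
(16 pairs). Exclusions are counted and logged, not silently dropped;
the two-group design does not define strata for worsening or
multi-level jumps, and inventing them would change the estimand.
Parsing accepts the verbal labels case-insensitively and the numeric
codes 1–5.

## MCID estimators

Signs follow the clinical convention: anchor-based estimates are
reported signed (negative = improvement), distribution-based ones as ±
magnitudes. Report rounding is one decimal for anchor-based and two
for distribution-based estimates (three for the AUC); internal
computation is full precision.

- **AC** — arithmetic mean of the "somewhat better" group's change
  scores.
- **CD** — `AC(better) − mean change(same)`.
- **MDC** — `mean − t((1+γ)/2, n−1) · sd/√n` over "the same" group's
  changes, γ = 0.95 by default. The Student-t quantile is standard for
  a sample mean with estimated variance; at n = 100 it differs from the
  normal quantile by < 1%, and a z option (`use_z`) is provided.
  Degenerate variance (all changes equal) yields a zero-width interval,
  i.e. the constant itself.
- **ROC cutoff / AUC** — see below.
- **Effect size** — `0.2 × SD`, 0.2 being the conventional small
  effect. The SD source is configurable among baseline, follow-up and
  change-score SD (computed over all analysed units of the
  measurement) and defaults to the baseline SD; the report footer
  states which source was used, because published values of this
  estimator are not always reproducible from printed baseline SDs and
  the choice materially changes the estimate.
- **SEM** — `SD × √(1 − r)`. The reliability `r` is an instrument
  property measured by external repeatability studies; no default is
  shipped and the value (with its source tag) must be supplied by the
  user. When absent, the SEM column is reported as n/a rather than
  silently substituted.

## ROC analysis

Positive class = "somewhat better"; a more negative change is the
stronger improvement signal, so the rule is
`change ≤ threshold ⇒ predicted improved`. Candidate thresholds are
midpoints between consecutive distinct pooled change values plus one
sentinel below the minimum and one above the maximum, so reported
cutoffs never sit on an observation. The AUC uses the rank
(Mann–Whitney) method with midranks, i.e. ties count one half; the test
suite verifies exact equality with brute-force pairwise counting and
with the trapezoidal area under the (1−specificity, sensitivity)
polyline on ~1000 random small instances.

The optimal cutoff maximises Youden's J = sensitivity + specificity − 1.
Ties on J are broken toward the highest sensitivity, then toward the
most negative threshold; both tie-breaks are deterministic and the scan
is verified against exhaustive threshold evaluation. Degenerate inputs
(all changes identical) return AUC 0.5 with the cutoff flagged
undefined; a raw AUC below 0.5 is flagged `inverted` rather than
silently flipped, so a measure pointing the wrong way is visible. AUC
bands are labelled unacceptable (< 0.7), acceptable [0.7, 0.8),
excellent [0.8, 0.9), outstanding (≥ 0.9). No confidence interval is
attached to the AUC (point estimate only).

## Hypothesis tests

Mann–Whitney U (between groups), Wilcoxon signed-rank (paired
T0 → D15; zero differences dropped, tied magnitudes midranked) and
Fisher's exact test (2×2), all two-sided, delegated to scipy with the
exact-vs-approximate regime pinned by this package: exact null
distributions for tie-free samples up to n = 20 per group
(Mann–Whitney) and n = 25 nonzero pairs (Wilcoxon), tie-corrected
normal approximation otherwise. Enumeration oracles (all group
assignments, all sign patterns, all tables with fixed margins) verify
the exact regimes in the test suite. Limb-level tests treat limbs as
independent although dogs contribute two limbs each; the report footer
carries this clustering caveat. No multiple-testing correction is
applied.

## Synthetic cohort model

Defaults emulate the study conditions the pipeline targets: 80 dogs /
160 pelvic limbs, 20 trials per limb per session, baseline hind loads
below the 20% norm (deviation mean 3.5, SI mean ≈ 28 at T0), partial
improvement at day 15, and a 37.5% responder fraction whose anchor
response improves exactly one level.

Per dog *i*, with one seeded `numpy` generator and no module-level
reseeding:

1. severity `u_i ~ Gamma(mean 3.5, sd 1.8)` (mean = 20 −
   `baseline_hind_mean`; units percent points of hind off-loading);
2. asymmetry split `c_i ~ Beta(b, b)` with `b = 0.57`; baseline limb
   deviations are `2·u_i·c_i` and `2·u_i·(1−c_i)` (capped at 20 so
   loads stay non-negative). This construction keeps the expected
   per-limb deviation equal to the mean severity *exactly* while the
   Beta concentration drives the symmetry index. An additive
   normal between-limb offset cannot do this: the absolute value in
   `|20 − load|` folds the offset and inflates the deviation mean by
   10–30% at the offset variance an SI of ~28 requires. `b = 0.57` and
   the severity SD are documented constants calibrated once so the
   default cohort's T0 deviation and SI means land on 3.5 and ≈ 28.1;
3. responder status with marginal probability `p_responder = 0.375`
   through a logistic link in severity (scale `responder_selectivity`
   = 1.0 percent points; the intercept is solved per cohort so the
   realized marginal matches). Worse dogs are more likely to respond,
   reproducing the worse-at-baseline responder group seen in treated
   cohorts; the link scale tunes that separation;
4. recovery: each limb's day-15 deviation is `(1 − ρ_i)` times its
   baseline deviation, `ρ_i ~ N(effect_group, effect_sd)` clipped to
   [0, 1], with `effect_same = 0.50` and `effect_better = 0.65`.
   Fractional (rather than additive) recovery is the model choice that
   lets deviation and SI improve together — equal additive load gains
   on both limbs would leave the left–right difference, and hence SI,
   almost unchanged, which is not what treated cohorts show;
5. trials: hind loads `20 − deviation`, forelimbs absorb the
   complement; per-trial noise (`trial_noise_sd = 1.0` percent point
   per limb, a typical stance-analyzer trial-to-trial wobble) is
   projected onto the sum-zero subspace so every trial sums to exactly
   100; loads are truncated at [0, 100] with the residual absorbed by
   the forelimbs, and truncation events are counted (rare, < 0.1% under
   defaults, asserted in tests);
6. anchors: every dog starts at level 3 ("Good"); responders report
   one level better at day 15. An optional `anchor_noise` probability
   flips recorded transitions to study estimator degradation; it is 0
   by default because the anchor is treated as ground truth.

The truth record (latent severities, splits, responder flags,
noise-free deviations and SIs per timepoint) travels with the cohort
but is never fed to the estimators; `true_parameters` exposes the
per-group latent mean changes for parameter-recovery assertions.

**What the generator does not emulate:** treatment arms (labels only,
no arm-specific effects), biomechanically realistic gait or
center-of-pressure dynamics, anchor baseline heterogeneity (all dogs
start at "Good"), within-session learning or fatigue trends, and
real-world anchor misclassification (off by default). Passing
calibration and recovery tests therefore demonstrates that the
*estimators* are correct and that the pipeline recovers known truth
under realistic dispersion — not that the generator reproduces every
feature of clinical records.

## Problem sizes

The test suite and acceptance script use the cohort sizes the defaults
describe (80 dogs; 10 seeds for calibration checks) plus one 1000-dog
cohort for parameter recovery, 1000 random small instances for the ROC
oracles, and 2000 simulated stable groups for MDC coverage — sizes at
which Monte-Carlo error is small against the tolerances being asserted
while the whole suite stays fast.

## Known limitations

- Limb-level inference ignores within-dog correlation (two limbs per
  dog); p-values and SEs are anti-conservative to that extent. The
  report says so rather than modelling it.
- MCID triangulation — choosing one working threshold from the six
  estimates — is a clinical judgment; the pipeline prints the range
  and leaves the choice to the user.
- The SEM estimate is only as good as the user-supplied reliability;
  back-solving r from published SEMs can yield measurement-specific
  values, which is why none is bundled.
- Generator calibration targets cohort *means*; higher moments (e.g.
  the SI SD) follow from the model rather than being fitted.
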