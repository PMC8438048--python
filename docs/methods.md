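# Methods

This note records the models, conventions and design decisions behind
`seroscreen`, in the order the pipeline runs them.  Everything stated here
is implemented and exercised by the test suite; no empirical claim is made
beyond what the tests and the acceptance script themselves compute.

## Planar-array screening

Each pooled planar array is standardized over all of its antigens,
`times SD = (X − mean(X)) / SD(X)`, and an antigen is selected when its
standardized signal is **at or above** the threshold (default 8) in at
least one pool.  Conventions the source procedure leaves open:

* **SD denominator** — sample SD (n − 1), the default of the R environment
  such analyses are usually run in.  At tens of thousands of antigens per
  array the choice is numerically irrelevant; it is stated for exactness.
* **Standardization set** — all antigens on the array; no control-spot or
  outlier exclusion is applied before computing mean and SD.  Selection is
  therefore slightly conservative: planted hits inflate the pool SD, which
  the pool generator compensates by displacing hits 15+ SD.

## Bead-array normalization and the score scale

Per sample, `xMAD = (MFI − median(MFI)) / mad(MFI)` with median and MAD
taken over that sample's antigens.  The MAD carries the normal-consistency
factor 1.4826 by default (a config switch exposes the unscaled reading,
since the source formula writes only `mad`); with it, xMAD behaves as a
robust z-score against the sample's own background.  A sample with MAD = 0
is degenerate and raises an error naming the sample.  No background-bead
subtraction precedes normalization.

Scores discretize xMAD onto 16 levels {0, 0.1, …, 1.5}: negative values
score 0, each band of 5 xMAD units adds one step, 70 and above scores 1.5.
Bins are closed below, open above (0 scores 0.1; 5.0 scores 0.2).  Scores
are handled as exact tenths, so cutoff comparisons never hit float bin-edge
artifacts.

## Detection cutoffs

Per antigen, a Gaussian KDE of the cohort's score vector with Silverman
bandwidth, evaluated on 512 equally spaced points spanning the data range
padded by three bandwidths (kernel, bandwidth rule, and grid are
conventions, all configurable — the source names none of them).  From the
tallest peak the algorithm walks toward higher scores if the peak lies at
0.75 or below, otherwise toward lower scores, and stops at the first grid
point where the **directional slope** — density change per unit score along
the traversal, estimated by first differences — falls below −0.5.  That
position is rounded up to the nearest 0.1 and clamped to [0, 1.5].
Individuals scoring at or above the cutoff are seropositive.

Two deliberate readings:

* *Slope along the traversal* rather than with respect to x, which makes
  the downward walk symmetric with the upward one.
* *The peak itself is not an eligible stopping point*: the walk starts one
  grid step past the peak.  Score vectors are near-atomic (most mass on
  one or two adjacent levels), and at a sharp atom the discrete slope
  exceeds |0.5| already at the argmax grid point; admitting the peak would
  let the cutoff collapse onto the background atom — calling essentially
  the whole cohort positive — depending on which side of a score level the
  argmax lands, i.e. on floating-point luck.  Starting past the peak makes
  the cutoff land one step above the background atom, which is the
  behavior the procedure's description implies.

Degenerate cases: a constant score vector has no density curve; its cutoff
is placed one step above the constant (all seronegative, logged), and
deliberately not clamped so a constant 1.5 also yields zero positives.  A
walk that exhausts the grid uses the grid end, logged.

## Autoantibody counts and strata

The autoantibody count is the number of antigens an individual is
seropositive for.  Strata thresholds use linear interpolation between
order statistics (`numpy.percentile`'s default, type 7) at the 5th and
95th percentiles; membership is strict (fewer than / more than), so
boundary ties belong to neither stratum.  The convention is configurable
and the computed thresholds are always reported rather than assumed,
because percentile conventions differ across environments and published
threshold values for the same percentile can disagree.

Strata are characterized against a targeted set of clinical variables and
cytokines with two-sided exact 2×2 tests, stratum versus all remaining
individuals.  Cytokines are median-dichotomized with the median in the
lower interval.  Tables are pairwise-complete: missing values drop the
individual from that test only.  No multiplicity correction is applied —
this characterization is explorative by design.

Profile clustering is complete-linkage agglomerative clustering on
Euclidean distances with scipy's deterministic index-based tie-break;
merge heights are validated against an O(n³) re-implementation in tests.

## Exact 2×2 machinery

All association statistics reduce to one primitive: two-sided Fisher exact
p, conditional-MLE odds ratio (the maximizer of the noncentral
hypergeometric likelihood), and an exact central 95% CI, with zero cells
yielding 0/Inf estimates and bounds.  The estimate and CI come from
scipy's conditional odds-ratio machinery; p-values in the mass screen use
an own vectorized log-gamma hypergeometric summation (the customary
1 + 1e-7 tie guard) that agrees with `scipy.stats.fisher_exact` to float
precision but runs ~100× faster, which keeps the ~60,000-pair screen in
seconds.  Both routes are validated in the tests against an
integer-arithmetic enumeration oracle and an independent
conditional-likelihood bisection.

A note on confidence intervals: published tables produced with the
`minlike` two-sided method (the default of R's `exact2x2`) print narrower
intervals than the central method used here; the two methods share the
same p-value and the same conditional-MLE estimate, so odds ratios are
comparable across methods while CI bounds are not.

## Three-criterion selection and FDR

For every (antigen, symptom) pair: group size n(Pos) ≥ 10, symptom
prevalence among seropositive ≥ 0.85, and prevalence at least 25% higher
in the seropositive group — read as the ratio P(Sx|Pos)/P(Sx|Neg) ≥ 1.25,
consistent with a tabulated "PR" column; a config switch provides the
alternative ≥ 25-percentage-point reading.  Criteria are evaluated on
exact fractions; prevalences are only rounded for display.  The
Benjamini–Hochberg family is all pairs passing the group-size criterion
(the widest defensible family that still uses the criteria as
pre-filters), and the significance gate is q < 0.05.  Symptom columns
constant in the cohort are untestable and skipped.

## Sensitivity analysis

One parameter at a time: count-stratum percentiles
{(2.5, 97.5), (5, 95), (10, 90)}, min positives {5, 10, 15}, min prevalence
{0.80, 0.85, 0.90}, PR {1.15, 1.25, 1.35}, and all score cutoffs shifted
±1 step.  Only the affected downstream stages are re-run (p-values are
cached keyed by the call matrix; correctness of the shortcut is tested
against a full re-run), each baseline finding is recorded as
retained/lost/not-evaluable per grid point, and the baseline grid point
must reproduce the primary analysis exactly.

## Synthetic cohort generator

The generator emulates the *structure* of bead-array serology in a
461 × 380 psychosis cohort; its defaults are the study conditions, chosen
once:

* **Background**: per-sample level ~ LogNormal(log 800, 0.3) and scale ~
  LogNormal(log 120, 0.25) in fluorescence units; per-antigen baseline
  reactivity ~ Normal(0, 1) in sample-scale units; within-antigen noise
  sd 0.08.  The wide between-antigen spread relative to within-antigen
  noise is the load-bearing choice: after per-sample median centering it
  makes each antigen's score vector near-atomic, so the cutoff algorithm
  separates background from spikes, and it reproduces the left-skewed
  per-antigen carrier distribution seen in real panels (antigens whose
  baseline straddles the sample median become the rare near-ubiquitous
  reactivities; antigens far below it are never detected).  The
  distributional families themselves are conventions — the pipeline only
  assumes median and MAD are meaningful — not claims about the assay.
* **Seropositive spikes**: per-antigen rates with an 18% point mass at
  zero (never-reactive antigens) and a LogNormal(σ = 1.25) spread over the
  rest, rescaled so the expected per-individual count is
  `spike_rate × n_antigens` = 25; per-individual counts are then sums of
  independent Bernoullis, hence approximately normal around 25.  Spike
  displacement is 5 + Lomax(1.5, scale 8) sample-scale units: support
  starts at the detection band's edge and the tail is heavy enough that a
  few percent of spikes saturate the score scale.  A minimum-displacement
  spike can land just under the xMAD = 5 bin edge through per-sample MAD
  noise; the association stage is insensitive to losing a spike or two,
  and tests assert separation accordingly.
* **Planted associations** (default 6): planted antigens get a mid-bin
  baseline (+0.7) so their realized calls equal their truth, and a spike
  rate of 0.08 keeping group sizes comfortably above the planted margins
  (≥ 12 positives, prevalence ≥ 0.95, PR ≥ 2 — each strictly inside the
  selection thresholds).  Symptom status is assigned *deterministically*
  from truth (⌈0.95 · n⌉ of the positives, ⌊0.475 · m⌋ of the negatives),
  so the realized table satisfies the margins by construction; genuinely
  infeasible margins raise instead of retrying.
* **Distractor symptoms**: independent Bernoulli with prevalence ~
  U(0.05, 0.70), then adjusted minimally to honor the generator's
  contract that no distractor pair meets the symptom-prevalence margin:
  across ~60,000 pairs, a ≈ 4–5σ fluke pushing a distractor's prevalence
  inside some truth-positive group past 0.85 *and* under the BH gate is
  expected a fraction of a time per cohort, so the few offending entries
  are flipped to zero (capping within-group prevalence at 0.80, leaving
  slack for missingness).  Flips only lower prevalences, so one pass
  converges and the null behavior of everything else is untouched.
* **Missingness**: MCAR at 2% on distractor symptoms, clinical variables
  and cytokines.  Planted symptom columns stay complete so the planted
  margins hold exactly on pairwise-complete tables.
* **Covariates**: sex (39% female) and clinical variables are independent
  of the spikes by default; `sex_count_effect` plants a higher female
  spike rate for count-stratification tests.

What the generator does **not** emulate: optical/bead-level physics, batch
and plate effects, antigen cross-reactivity, correlated symptom clusters,
and informative missingness.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that real cohort data
meets those assumptions.

## Problem sizes and runtime

The default synthetic cohort runs the full pipeline in ~10 s: cutoff
detection is 380 KDE evaluations, and the association screen tests
~60,000 pairs with the vectorized exact test.  The test suite uses a
reduced cohort (180 × 90, 40 symptoms, 3 planted pairs) for fixtures,
exhaustive exact-test enumeration up to table total 30 with a seeded
sample up to 60, and a 100-antigen cutoff battery; the planar screen is
exercised at its full 8 × 42,100 scale, which is cheap.

## Known limitations

* The cutoff algorithm is deliberately faithful to its published
  description, quirks included: with atomic score data its result depends
  on which score atom carries the tallest KDE peak, so antigens whose
  background straddles a score boundary flip between "background included"
  and "background excluded" cutoffs.  The sensitivity stage exists to make
  exactly this visible.
* Reconstructing 2×2 cells from rounded published percentages carries
  rounding error of order 1/n(Pos); recomputed odds ratios match printed
  ones to ~1–2%, not exactly.
* The conditional-MLE OR bisection oracle and the central CI convention
  are documented above; intervals from `minlike`-type methods will differ.
* The characterization surface distinguishes only dichotomous and
  continuous variables (the latter median-dichotomized); multi-level
  categorical variables would need a data dictionary and a generalized
  exact test and are not currently handled.
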