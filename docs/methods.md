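# Methods

This package implements the scoring rule, completion-error quality control
and validation statistics of the WELSH ("Walking Estimated Limitation
Stated by History") pictorial walking-capacity questionnaire, together with
a calibrated synthetic-cohort generator that reproduces the statistical
structure of the community validation study the instrument was tested in
(1723 adults, eight sex-by-education strata, 6-minute walk test as the
field reference).

## The instrument and its scoring rule

The WELSH has four items. Items 1–3 ask for the maximum time (whole
minutes, marked on a clock dial capped at 60) the respondent can walk at a
slow ("turtle"), usual ("human") and fast ("rabbit") pace. Item 4 asks for
the usual walking pace relative to peers: snail, turtle, human or rabbit.

Each timed item is converted to points by completed-interval counting: one
point per 5-minute interval up to 20 minutes, then one point per 10-minute
interval up to 60 minutes, so the default point sequence over the intervals
(0,5], (5,10], …, (50,60] is 0–7. Item 4 maps to a coefficient 1 (snail) to
4 (rabbit). The total score is

    S = (1 + p_turtle + p_human + p_rabbit) × c,

minimum 1 (unable to walk at any pace, "much slower" self-rating).

**Boundary convention.** The interval rule does not itself say where exact
boundary marks fall; we fix lower-open/upper-closed intervals (exactly 5
minutes → 0 points, exactly 25 minutes → 4 points), the completed-interval
reading. The convention is isolated inside `ScoreTable` so an alternative
convention is one configuration away.

**Zero marks.** A declared time of 0 minutes is accepted as "unable at this
pace" and scores 0 points; without it the stated minimum score of 1 would
be unattainable.

**Score range discrepancy.** With 0–7 item points the maximum is
(21+1)×4 = 88, yet the instrument's verbal description says the score runs
"to one hundred". Both cannot hold; the explicit per-item rule wins and the
default table tops out at 88. A second preset (`ONE_TO_HUNDRED_TABLE`,
points 1–8 per answered interval) reaching exactly 100 is shipped for users
who want the verbal range.

## Completion-error QC

An error is a double or missing answer on any item, or a *paradoxical*
answer: a strictly longer declared duration at a faster pace. Ties are
legal. Paradox is evaluated on all three ordered pace pairs (human vs
turtle, rabbit vs human, rabbit vs turtle), since the inconsistency is
defined for any faster/slower pair; one paradoxical *answer* may violate
two pairs, so error counts are tallied over distinct flagged items, which
is how erroneous answers are counted on a sheet.

Sheets flow through two explanation rounds (self-completed on the first
round, possibly with interviewer-corrected errors; a second oral
explanation otherwise; a residual "unable" state). Participants still
unable after round two are retained and scored with the interviewer's help
by default; an analysis switch (`include_unable=False`) excludes them from
the correlation analysis instead, since the source report is not explicit
about their handling.

## Validation statistics

* **Proportions** carry Wilson score 95% intervals (no continuity
  correction). The Wilson method was identified by matching the published
  intervals exactly (e.g. 113/524 → 18.3–25.3%); Wald and Clopper–Pearson
  do not match. Two published upper bounds (21/533 → 6.0 vs Wilson 5.9;
  1146/1156 → 99.6 vs Wilson 99.5) differ by one final-digit rounding step
  and are treated as source-side inconsistencies, as is the published
  "99.2%" for 1146/1156 (99.13% by division). Bounds at k=0 and k=n are
  snapped to their exact values 0 and 1.
* **Correlation** is Spearman's rank correlation with average ranks for
  ties; two-sided p via the t approximation on n−2 degrees of freedom
  (adequate for the stratum sizes here; exact permutation p is out of
  scope). The study's abstract says "Pearson's r" while its methods and
  results say Spearman; the pipeline computes Spearman and reports Pearson
  alongside, labelled.
* **Comparison of correlations** uses the Fisher r-to-z two-sample test,
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.
  Feeding it the published per-stratum (r, n) pairs reproduces the four
  published education-contrast p values (0.001, <0.001, 0.008, 0.011).
* **Multiple testing** uses Benjamini–Hochberg, applied as two separate
  families — the eight per-stratum correlation p values, and the four
  Fisher-z contrasts — because the source does not define the families;
  both families are computed in the report and the split is visible there.
* **Group differences** use Welch t tests (continuous) and Pearson
  chi-square without continuity correction (categorical); the pooled-
  variance t is available behind `equal_var=True` since the source does not
  state which form was used.
* **Sample-size planning** for a target correlation r uses
  n = ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉, which gives the study's 47 per
  subgroup at r = 0.40, α = 0.05, power 0.80.
* Normal/chi-square/t tails come from scipy (relative accuracy far beyond
  the 1e−10 needed here).

The four education contrasts are anchored on the university stratum with
the larger n and compared against the opposite-sex university stratum and
the same-sex lower-education strata — the family reported by the study.

## Synthetic cohort generator

The generator defines the study conditions every end-to-end test runs
under; its defaults are the published values, not tuning knobs.

* **Strata.** Eight `StratumSpec`s with the published n, MWD mean ± SD,
  score mean ± SD, within-stratum Spearman r, and per-stratum calibration
  lines. **Sex-label conflict:** in the source, the subgroup table's block
  labelled "Females" carries the stratum sizes 216/125/242/386 that the
  characteristics table attributes to males, and that block's n-weighted
  MWD mean (419 m) equals the male pooled MWD. The two tables cannot both
  be right; the generator keys sex by the stratum sizes (216-block = male),
  which is the internally consistent reading, without asserting which
  label was misprinted.
* **Dependence.** Gaussian copula: latent bivariate normal with Pearson
  correlation 2·sin(π·ρ_S/6), the exact inverse of the normal
  Spearman–Pearson relation, so the latent pair has the stratum's target
  rank correlation. The dependence family is a modelling choice — the
  source gives only marginal moments and rank correlations.
* **Margins and boundary calibration.** Scores are affinely matched to the
  target mean/SD and snapped to the nearest attainable WELSH score; MWD is
  normal, truncated at 0 m by resampling (bounded at 100 attempts). Both
  boundary treatments shift the realized mean (snapping censors at the
  attainable extremes; truncation lifts low-mean strata), so the latent
  mean is solved (Brent's method on the censored/truncated-normal mean) so
  that realized stratum means are centred on their targets; measured
  residual bias is below 0.15 score points and 1.3 m.
* **Raw sheets.** Each assigned score is back-solved into item marks by a
  deterministic preference (maximize turtle points, then human, then
  rabbit; slowest admissible pace breaks remaining ties), giving
  paradox-free sheets whose rescoring reproduces the stored score exactly.
  Declared times are the upper bound of the first interval worth the
  required points, so each item's mark is a legal dial position.
* **Completion errors.** Each sheet is errored with its education stratum's
  published rate (113/524, 32/233, 40/433, 21/533). Conditional on being
  errored, the sheet lands in a flow category with probabilities
  (42, 7, 94, 25, 16, 5)/189 — round-1 with one/two errors, round-2 with
  one/two/three errors, unable; conditional on clean, it was round-1
  self-completed with probability 1474/1534. This conditional
  parametrization is forced: the source gives no per-education flow split,
  and its per-education error counts (sum 206) and flow counts (sum 189)
  are not mutually consistent, so the per-education rates calibrate the
  rates and the flow counts calibrate the conditional split. Error kinds
  are drawn as missing/double/paradoxical with weights 0.5/0.2/0.3 (the
  source does not report a kind breakdown; missing marks are the dominant
  completion failure in pencil-and-paper instruments). "Unable" sheets
  come back fully blank. Corruptions touch the first-attempt sheet only;
  the final response and score model investigator correction.
* **Demographics.** Age, weight, height (normals truncated at plausible
  floors; age ≥ 20 per the inclusion criterion), smoking and comorbidity
  flags (Bernoulli) follow the per-sex published marginals. They are
  realistic plumbing only: no dependence with score or MWD is modelled.

**What the generator does not emulate:** the 102 pre-analysis exclusions;
interviewer identity effects; any real dependence of walking capacity on
age, BMI or comorbidity; non-normal MWD shapes (skew, digit preference);
within-interviewer clustering. Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under the published summary
structure, not that the instrument is valid in new field data.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  config or call site; identical seed + config gives a byte-identical
  cohort and report.
* Score snapping breaks distance ties toward the smaller attainable score
  (first-match on the sorted attainable set).
* Display rounding is half-up (decimal arithmetic) to one decimal for
  percentages, three decimals for correlations, integers for means —
  matching the study's reporting style; JSON reports keep full precision.
* Strata below `min_stratum_n` (default 10) are marked insufficient rather
  than estimated; constant samples raise rather than return NaN.

## Problem sizes in the test suite

The scoring oracle enumerates the full 61³×4 input grid vectorized. The
recovery suite generates 20 full-size cohorts (n = 1723); with the Fisher-z
standard error of a single cohort's pooled correlation at ≈ 0.017, the
20-seed mean pins the generator's pooled Spearman to ± 0.01, comfortably
resolving the ± 0.05 acceptance envelope around the published 0.567.

## Known limitations

* The per-education completion-error process is independent of the score
  and MWD margins; in the field, error propensity may correlate with
  capacity and age within education strata.
* The back-solved sheets use a canonical mark per point value; real dials
  show every minute. Rank statistics are unaffected (scores, not minutes,
  enter the analysis), but minute-level mark distributions are not
  realistic.
* The optional spreadsheet loader returns the deposited file raw; column
  mapping onto the record dictionary is left to the user because the
  deposited column names are not standardized.
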