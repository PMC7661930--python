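# Methods

## Scope and model

`tbipanel` implements a high-sensitivity prognostication workflow for
CT-positive traumatic brain injury: an integer head-CT score (the Helsinki
CT Score, HCTS), single-marker ROC evaluation restricted to the 90–100 %
sensitivity band, and multi-marker threshold panels optimized under a
sensitivity floor. The package is organised around a statsmodels-style
pair: `ThresholdPanelModel` (data + search configuration) and
`PanelResults` (estimates, uncertainties, `summary()`), over a functional
core (`roc`, `panel`, `hcts`, `stats`, `simulate`, `pipeline`).

## Helsinki CT Score

The score is a plain sum of component weights: subdural hematoma +2,
epidural hematoma −3, intracerebral hematoma/contusion +2, mass lesion
> 25 cm³ +2, intraventricular hemorrhage +3, suprasellar cisterns
normal 0 / compressed +1 / obliterated +5. Over all findings combinations
the sum spans exactly [−3, 14]. The weights are shipped as versioned JSON
(`data/hcts_weights.json`) citing the original publication, so a corrected
or alternative table can be swapped in without touching code; the file's
`note` field flags that any future erratum to the source must be reflected
there. Dichotomisation is strictly greater-than (`HCTS > 1` style cuts),
and the internal consistency check (a >25 cm³ mass lesion without any
mass-lesion type) warns rather than rejects, because lesion types and
lesion size are tallied independently in practice.

## Partial AUC on the sensitivity band

All scores are summarised by the partial area under the empirical ROC
curve over the 90–100 % sensitivity band, defined on the sensitivity axis:
specificity integrated as a function of sensitivity, trapezoidal
interpolation between attained operating points, exact partial trapezoids
at the band edges, no McClish normalisation, reported as per cent of the
unit square (ceiling 10 %, uninformative limit 0.5 %). Empirical curves
use strict thresholding (`positive if score > t`, mirrored for
negative-direction markers), collapse tied scores to one operating point,
and always include the trivial endpoints; attained sensitivities and
specificities therefore lie on the k/n₊ and j/n₋ grids. The implementation
is cross-checked in the test suite against scikit-learn (full band) and R
pROC (band-restricted), both independent code paths.

Operating points are chosen as: among attained points with sensitivity at
or above the floor, maximise specificity; ties break toward higher
sensitivity, then the more conservative threshold. A score that reaches
the floor only at zero specificity is reported with threshold "–"
(sensitivity 100 %, specificity 0 %).

## Confidence intervals

The reference data for this design publish 95 % CIs without naming a
method, so CIs here are stratified-bootstrap percentile intervals
(resampling with replacement within each outcome class, class sizes
preserved; default 2000 replicates; seeded). They are reported as
uncertainty, never matched against external values exactly.

## Threshold panels

A panel is 1–3 strict per-marker rules plus a min-positive-count cut
(searched, not assumed, since published panels do not report it). The
rule-count is an ordinal score, so panel ROC curves and pAUC follow the
single-marker machinery. Optimization is an exhaustive, deterministic
search over marker subsets (≤ 3), per-marker candidate thresholds, both
directions, and every decision cut, under sensitivity ≥ 90 %; the
objective ordering is specificity → pAUC → parsimony → fixed lexicographic
order. Specificity leads because at a fixed high-sensitivity working
point the clinically relevant gain of adding markers is specificity. The
search is vectorised over the threshold grid; with 8–9 markers and
19-point quantile grids a full run takes seconds on one CPU. If no panel
attains the floor, the sensitivity-maximizing panel is returned flagged
`constraint_met=False` — never silently. A greedy forward search
(`engine="greedy"`) exists for larger pools and is labelled heuristic.

Candidate thresholds come from either midpoints of consecutive distinct
values (exhaustive; used for small cohorts and for oracle comparisons) or
`grid_size` quantile cuts (default 19 → ventile boundaries; the economical
grid for cohort-sized problems). Records missing any panel marker are
excluded listwise per panel with logged counts; during a multi-marker
search the exclusion is taken once over the candidate pool so that all
panels are compared on the same records.

## Group statistics

Biomarkers and ordinal severity scores use the Mann–Whitney U-test
(midrank ties; exact null distribution when combined n ≤ 12 and untied,
otherwise normal approximation with tie-corrected variance and continuity
correction, via scipy). Normally distributed demographics use the Welch
two-sample t-test (no pooled-variance assumption; the variant is surfaced
in output metadata), categorical variables a two-sample proportion test.
The variable→test mapping is declared in `stats.DEFAULT_VARIABLES`, not
inferred, and normality screening never switches tests. The test suite
verifies the exact branch against full permutation enumeration and checks
type-I calibration (rejection rate within [0.03, 0.07] at α = 0.05 over
2000 null simulations at n = 49/33).

## Synthetic cohort generator

The generator emulates the *printed* structure of a two-centre TBI cohort:

- **Sizes:** 137 patients = 82 CT-positive (49 favorable / 33 unfavorable
  by GOSE 5–8 vs 1–4) + 55 CT-negative (51 / 4).
- **Markers:** lognormal per group, the family chosen because it is
  strictly positive, right-skewed and exactly identifiable from a
  median/IQR pair: location = ln(median) and scale
  σ = asinh(IQR/(2·median)) / z₀.₇₅ (the closed form of the quartile
  equation; a root-finder is unnecessary since sinh is monotone). NF-L
  (favorable 36.9/57.6, unfavorable 99.9/120.0 pg/ml) and Aβ42 (16.9/16.4,
  21.9/40.6) encode published per-group summaries
  (`provenance="published"`); the other six markers' per-group summaries
  were published only in supplementary material not available here, so
  their defaults are plausible placeholders (`provenance="assumed"`)
  chosen once to echo the published single-marker threshold scale — they
  define test conditions and must not be read as reference values.
- **CT findings:** sampled independently per feature given outcome group
  from the published per-group prevalences (exact fractions, e.g. SDH
  26/33 among unfavorable); no lesion–lesion correlation is imposed
  because none is published (config hooks exist). CT-negative rows carry
  all-negative findings and HCTS 0. The HCTS column is computed from the
  drawn findings, so generated sums always lie in [−3, 14].
- **Outcome detail:** GOSE within the favorable stratum is uniform on 5–7
  with the GOSE-8 share matched to the published complete-recovery
  fractions (10/49 CT-positive, 23/51 CT-negative); unfavorable is uniform
  on 1–4. S100B below the assay detection limit is floored at 1 pg/ml.
  Sampling delay is truncated normal (13.1 ± 10.4 h, floor 0) for
  interface completeness and enters no statistic.

What passing tests on this generator do and do not show: they validate the
pipeline's arithmetic, search optimality, calibration and determinism
under realistic group sizes and skew; they say nothing about real-data
effect sizes, marker correlations (drawn independently here), missingness
mechanisms beyond MCAR, or assay noise.

## Numerical choices

- Reporting rounding is half-up to one decimal in per cent, applied only
  at the formatting layer.
- Sensitivity-floor comparisons use a 1e−12 tolerance so k/n grid points
  at the floor are never lost to floating point.
- Specificity ties during search are resolved by exact float equality
  (both sides are j/n₋ rationals), then pAUC, then smaller panel, then
  lexicographic (marker names, thresholds, directions, min_positive) — the
  search result is therefore a deterministic function of the data and
  grid; seeds affect only bootstrap intervals.
- Degenerate inputs: single-class cohorts raise `DegenerateCohortError`;
  constant markers yield empty threshold grids and are logged and skipped;
  a constant statistic bootstraps to a collapsed interval.

## Problem sizes used in the checks

The acceptance script and test suite run the optimizer-vs-enumeration
comparison on cohorts of ≤ 12 patients × 3 markers (where full enumeration
is exact and fast), planted-panel recovery on 40-patient two-marker
cohorts across 20 seeds, generator fidelity at 10⁵ draws per group, and
Mann–Whitney calibration over 2000 null simulations — sizes chosen so each
property is measured with comfortable statistical resolution while the
whole suite stays quick on a single CPU.

## Known limitations

- Printed headline performance values from the motivating study design
  (e.g. a specific panel's pAUC on real patients) depend on unpublished
  patient-level data and cannot be reproduced by construction; the package
  reproduces the *arithmetic* and *method*, and demonstrates the panel
  specificity gain on synthetic cohorts.
- The exhaustive engine is exponential in panel size; it is intended for
  ≤ 3 rules and ≤ ~9 markers (the design space of this workflow). Use the
  greedy engine beyond that.
- Panels use strict inequalities throughout; scores with heavy ties (like
  the integer HCTS) are handled correctly but quantile grids on them can
  produce non-integer cuts (e.g. `hcts_sum > 3.3`), which are equivalent
  to the integer cut `> 3`.
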