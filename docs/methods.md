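# Methods

This note documents the models, conventions and numerical choices behind
`rapscore`, in the order the pipeline applies them.

## The register and the control strata

A trophy register row carries species, age (years), cohort label, per-side
brow-tine and main-beam lengths (cm), per-side pedicle axes (mm), an
optional harvest age and free-text register marks. Rows are validated
individually; a failing row is reported with its row number and reason and
never silently dropped. Records marked "deformed", "injured pedicle" or
"diseased pedicle" are excluded before any control statistics are built;
the kept/excluded lists always partition the input.

The control register holds one stratum per (age, side, metric), each a
sorted vector of lengths. The quantile is the empirical inverse CDF — the
smallest observed value whose cumulative frequency reaches `q` — chosen over
interpolating definitions because it is reproducible without interpolation
conventions and makes the strict-below flagging rule self-calibrating: at
most a fraction `q` of a stratum can fall strictly below its own
`q`-quantile. Strata with fewer than `min_stratum` observations (default
10) pool with the nearest ages (±1, then ±2, …) before the quantile is
taken; a stratum that stays empty after full widening raises an error
rather than returning a degenerate threshold.

Axis-order violations (pedicle d > D) are rejected in the default strict
mode because the axes are defined as major/minor, so inversion signals a
data-entry error; lenient mode swaps them instead, for bulk imports known
to contain transpositions.

Units are declared per column in the schema and normalized on read
(tine/beam to cm, pedicle axes to mm); register exports with local headers
load via the column-name map without editing the file.

## RAPS scoring

The schema is fixed: 3 rose, 6 antler, 7 pedicle and 6 skull features,
22 in all, each graded I–IV. Two grade-table variants are provided because
the published grade rows double-list one skull code while omitting another:
the default `resolved` table follows the feature-frequency text (S4 = skull
fistula, grade III; S5 = cortical-plate separation, grade IV); the
`literal` variant swaps the two. All other codes agree between variants.

The trophy-level grade is the maximum grade among features present on
either side. The underlying grading is per-feature; max is the natural
"severity of the worst lesion" semantics, is monotone (adding a finding
never lowers the grade), and is the only aggregation implemented — profile-
or consensus-based grading would need expert input the data do not carry.

Constraints are enforced at scoring time, not silently repaired: R1∧R2 on
one side raises an error naming the trophy and side; A2/A3 are mirrored to
both sides when present on either. Missing assessments stay missing and are
excluded from prevalence denominators; completeness is reported so that
slot-count arithmetic (44 per trophy) stays auditable.

The derived flags use `q_brow = 0.20` and `q_beam = 0.05` by default. The
looser brow threshold reflects that register brow-tine distributions are
skewed, which makes a bottom-5% cut insensitive for that metric; both
quantiles are settable per call and on the CLI.

## Pedicle morphometrics

Focal distance is `c = sqrt((D/2)² − (d/2)²)` in mm. The square root is
always applied: a squared-millimetre "distance" is dimensionally wrong,
and the descriptor is meant to be comparable across pedicle sizes in linear
units. Eccentricity defaults to the standard ellipse definition
`e = c/(D/2) = 2c/D`, reading "foci distance" as the inter-focal distance;
the literal `c/D` reading differs only by a factor 2 and is available via
`definition="literal"` since the two cannot be distinguished from printed
group p-values alone. The deformity flag is strict: `D − d > 4 mm`, so a
difference of exactly 4 mm is not flagged.

Rank tests (here and in the length comparisons) follow one fixed policy:
exact null distribution when both groups have ≤ 50 observations and the
pooled sample is tie-free, otherwise the continuity-corrected normal
approximation with midrank ties. The policy depends only on the data, so
repeated runs give identical p-values.

## Cohort statistics

* **Overall Fisher**: two-sided exact test on the pooled 2×2 table
  (anomalous vs normal slots, control vs aberrant), computed via the
  log-space hypergeometric implementation so register-scale counts are safe.
* **Per-feature chi-square**: Pearson without continuity correction by
  default (Yates optional), one side-aggregated 2×2 per feature. The default
  unit is the trophy (ANY_SIDE); BY_SIDE doubles the denominators. Features
  with a zero margin are reported untestable instead of producing NaN
  p-values that could be miscounted as non-significant.
* **Co-occurrence**: AND-counts over units, symmetric, diagonal = presence
  counts. Because A2/A3 are bilateral by construction, BY_SIDE counting
  doubles every pairing that involves them; `bilateral_once` counts those
  codes once per trophy (left slot) to remove that structural inflation.
* **Holm correction**: the family is exactly the set of pairwise
  comparisons requested in one call; raw p-values are always returned so a
  different family can be re-adjusted downstream.
* **Survival**: harvest age is the event time and, absent explicit
  censoring indicators, every observation is an event — the register
  records harvested animals, so there is no natural censoring mechanism in
  these data. Product-limit curves and the 1-df log-rank test come from
  lifelines.
* **Incidence ratios**: raw ratios of case counts relative to a declared
  reference species; density-adjusted ratios divide each count by its
  population density first. Densities are inputs, never constants —
  regional density tables are management data outside the scoring system.

## The synthetic generator

The generator's defaults are the study conditions: a 2924-sheet register
with exactly 12 marked sheets; 24 control and 50 aberrant trophies (1056
and 2200 feature slots); control anomaly rate 0.0152 per slot; aberrant
per-feature prevalences set to the published values. Three features (R1,
A1, P7) have no published rate; each is set to 0.16 so the 22-feature sum
is 9.89, making the expected positive-slot fraction exactly 44.95%. Mean
ages are 9.0 (control, rounded normal sd 2.0, clipped 4–14) and 7.74
(aberrant, sd 2.0, clipped 2–14).

**Correlated features.** Each trophy draws one latent severity score
`z ~ N(0,1)`; its grade I–IV is the quantile cut of `z` under the severity
mixture (0.15, 0.30, 0.35, 0.20). A feature with marginal prevalence `p`
is present on a side iff `ρz + sqrt(1−ρ²)ε > Φ⁻¹(1−p)` with independent
noise `ε` — a Gaussian copula whose marginals equal `p` exactly for any
coupling `ρ` (default 0.4; 0 gives independent features). A hard
"eligible only at or below the latent grade" gating model was considered
and rejected: with the published prevalences it is infeasible (a grade-III
feature at prevalence 0.92 cannot be reached when only 55% of trophies
have grade ≥ III), whereas the copula needs no per-feature calibration at
all. The structural constraints are built in without disturbing marginals:

* R1, R2 and P2 share one per-side uniform. R2 occupies the top `p_R2`
  window and R1 the adjacent disjoint window, so they are mutually
  exclusive; P2 occupies the top `p_P2` window, so `p_P2 ≥ p_R2` makes R2
  imply P2 (the rose deformity reflects the underlying pedicle deformity).
  Configurations violating `p_P2 ≥ p_R2` or `p_R1 + p_R2 ≤ 1` are rejected
  with errors naming the offending features.
* A2 and A3 reuse one trophy-level noise term for both sides, so they are
  bilateral whenever present.

**Lengths.** Log-normal per (age, side, metric) with saturating,
age-increasing location (brow mean 10 + 1.2·min(age, 10) cm, beam
30 + 4.5·min(age, 10) cm; log-sd 0.25 and 0.18). The family is
right-skewed, matching how register length distributions behave relative
to quantile thresholds. For trophies whose A2.1/A3.1 entries are set, the
length is drawn from the corresponding tail of its stratum distribution
(inverse-CDF conditioning at the model quantile), so deriving the flags
from the generated measurements reproduces the matrix exactly against the
model quantile and up to quantile-estimation noise against a finite
register.

**Geometry.** D − d is log-normal; D is normal, floored at
diff + 1 mm so the minor axis stays positive. The means are the published
3.12 mm (healthy, D ≈ 44) and 10.78 mm (abnormal, D ≈ 64.4). The log-sds
(0.3731 and 0.6356) are solved analytically from two published facts per
group: the mean and the 4 mm threshold-crossing rate (13/66 healthy
antlers above, 3/28 abnormal below). Zero dispersion pins every pair at
the configured means exactly. Record-attached axis pairs are drawn
conditionally on the trophy's P2 entry so flag and geometry cohere.

One seeded generator per table drives all draws in a fixed, documented
order (latent scores, rose/P2 block left then right, bilateral features,
remaining features in schema order, then ages, lengths, axes), so
identical seed + config give bit-identical tables and adding a field
appends draws rather than reshuffling earlier columns.

**What the generator does not emulate.** Real registers carry measurement
rounding, observer effects, species mixtures, within-trophy left/right
length correlation beyond the shared age, and the unknown true
co-occurrence strengths (the coupling ρ is a free parameter, not an
estimate). Passing recovery tests therefore shows the pipeline's
statistics are correct and adequately powered at the study's sizes — not
that the biological effect sizes are as simulated.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the study's own
sizes (24/50 trophies, 2924-sheet register, 66/28 antlers), with calibration
checks at 5,000–20,000 draws and power studies over 200 seeded replicates;
the whole suite completes in well under a minute of compute per module
group. All randomness flows from explicit integer seeds (replicate seeds
derived via `SeedSequence`), so every reported number is reproducible
bit-for-bit.

## Known limitations

* Visual features must be supplied; there is no image analysis.
* The grade aggregation (max) is declared, not validated against expert
  trophy-level grading, which is not available in tabular form.
* The Holm family is per call; cross-call multiplicity is the caller's
  responsibility.
* Incidence-ratio inference is descriptive (no confidence intervals), as
  the per-species collection effort behind the case counts is unknown.
* The censoring-free survival convention is an assumption; if register
  sheets ever carry censoring indicators they are accepted but untested
  against real usage.
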