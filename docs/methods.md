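# Methods

## The grading model

The unit of annotation is the *vessel segment*: an individually
distinguishable stretch of microvessel in the field of view, carrying a
centerline polyline (µm, image coordinates, origin top-left), a diameter
and one of four ordinal flow categories — absent < intermittent <
sluggish < continuous — the semi-quantitative vocabulary also used for
the microcirculatory flow index.

Per clip, the *stopped fraction* is the per-segment (not length-weighted)
share of segments whose category is in the configured stopped set.
Intermittent flow is stopped part of the time, so the default stopped set
is {absent, intermittent, sluggish}; a stricter reading is available via
`ScoringConfig.stopped_categories`. The flow bands are `< 0.25` normal,
`[0.25, 0.50]` impaired, `> 0.50` critically impaired — the boundary
values 25 % and 50 % grade as impaired, matching the band wording
("less than 25 %", "25–50 %", "more than 50 %").

Heterogeneity is asked only of normal-flow clips and is *present* when
strictly more than 5 segments show flow different from the remainder.
"Different from the remainder" is operationalized as differing from the
modal flow category; the deviant count `n − max(category counts)` is
independent of how plurality ties are broken, so no tie rule is needed.
Impaired and critically impaired clips carry heterogeneity by definition
(it was universally present in such clips during the score's design), and
the `ClipAssessment` type enforces that invariant.

Exactly four clips — no rescaling for 3- or 5-clip sets — aggregate as:
score 1 if ≥ 2 clips are critically impaired; else score 2 if ≥ 2 clips
are impaired *or worse*; otherwise (≥ 3 normal clips) score 3/4/5 for
4 / {2, 3} / ≤ 1 heterogeneous clips. The published branch for exactly
one critically impaired plus one impaired clip is not stated; counting
the critically impaired clip toward the impaired tally (score 2) is this
package's choice, the most conservative reading consistent with the
severity ordering, and is covered by an exhaustive monotonicity test:
over all 256 clip-state combinations, degrading any single clip never
raises the overall score.

## Consensus parameters

TVD and PVD use the length-density convention: small-vessel (diameter
≤ 20 µm, configurable) centerline length divided by field area, in
mm/mm². The grid-crossing density variant is deliberately out of scope.
"Perfused" defaults to {sluggish, continuous}. PPV is a segment-count
ratio over small vessels and is undefined (raises) when no segment passes
the diameter cutoff. The quadrant MFI assigns each segment to the
quadrant containing its centerline's arc-length midpoint (boundary points
go to the right/lower quadrant); each non-empty quadrant scores its
predominant category's flow score, with count ties broken toward the
lower score (conservative grading); empty quadrants are excluded from the
mean rather than scored 0, to avoid penalizing sparse fields. MHI is
computed across the four clip MFIs of a sequence (the per-time-point
unit), not across quadrants within a clip, and is undefined when the mean
MFI is zero — an all-stopped time point; the CLI reports `null` for such
sequences and the sweep analyses exclude them.

## Agreement statistics

The ICC uses the two-way ANOVA decomposition with items and raters both
random. With MSR, MSC, MSE the item, rater and residual mean squares
(n items, k raters):

* consistency, single: `(MSR − MSE) / (MSR + (k−1) MSE)`
* agreement, single: `(MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n)`

Confidence intervals are the exact F bounds (consistency) and the
Satterthwaite-degrees approximation (agreement), at a fixed 95 % level;
average-measures forms are the Spearman–Brown step-up. The implementation
is written from the mean squares directly rather than delegated to a
reliability library, because the estimate must satisfy
`ci_low ≤ estimate ≤ ci_high` at full precision; tests cross-check it
against both a plain-loop ANOVA oracle and pingouin to 1e-10. Whether
single- or average-measures is "the" reported form is genuinely open for
bedside scores; single-measures is the default here because the clinical
unit of interest is one rater's score, and average-measures remains
selectable. A constant matrix (zero between-item variance) raises a
degenerate-statistics error. On anti-reliable data negative variance
components can push the *average*-measures estimators outside [−1, 1];
the single-measures forms are bounded in (−1, 1] and that bound is
enforced.

Error-score regression subtracts the expert's score from each observed
score and fits OLS with rater and item as categorical predictors
(statsmodels, type-II ANOVA F per predictor). A zero-variance error
vector (all raters exactly right, or a uniform offset) is flagged
degenerate rather than raised. Score-vs-parameter regressions are
ordinary least squares (scipy), reporting R² and the two-sided slope p;
a constant response returns R² = 0 with p = 1.

Kruskal–Wallis H comes from scipy (tie-corrected); Dunn's pairwise z is
hand-written — no installed package provides it — using pooled mid-ranks
with tie correction `Σ(t³−t)/(12(N−1))` and two-sided normal p-values,
Bonferroni-adjusted across all pairs by default (the correction is not
prescribed with the test's name; `none` is selectable).

## The synthetic generator

The generator emulates the statistical shape of annotated sublingual
clips from shocked patients; no public deposit of such material exists.
Defaults mirror the validation design: 5 sequences × 4 clips × 32 raters,
10–40 segments per clip in a 1000 × 750 µm field, diameters lognormal
around 8 µm (capillary-dominated, clipped to 3–30 µm), centerlines
short gently-bent polylines of 50–250 µm.

Severity `s ∈ [0, 1]` tilts the category distribution by piecewise-linear
interpolation through four simplex knots, from all-continuous at `s = 0`
to all-absent at `s = 1`, calibrated so the expected stopped fraction
equals the grading band edges (0.25, 0.50) at the band knots (1/3, 2/3):
the severity axis sweeps the grading ladder at an even pace and the
expected stopped fraction is strictly increasing. Heterogeneity mixes in
a second regime one band (1/3) away — worse flow for mild clips, better
for severe ones — with categories drawn conditional on differing from the
main regime's modal category, so the mixing weight `h` maps directly onto
the deviant fraction the heterogeneity rule counts. A study draws
sequence severities evenly spaced over [0, max severity] and per-sequence
`h` uniform on [0, 0.3]: larger mixing weights would mean most of the
field deviates, which is an impaired field, not a heterogeneous-normal
one.

Rater noise acts at the clip-grade level (not the segment level),
matching how human raters err — confusion between adjacent grades: with
probability `rater_noise` (default 0.1) per clip, a rater moves the
clip's state one step along critically impaired < impaired <
normal + heterogeneity < normal (end states move inward) before the
four-clip aggregation. The expert is noiseless, so expert scores equal
ground truth and the whole pipeline returns ICC = 1 and zero error scores
at zero noise. Segment-level noise is a documented alternative left
unimplemented. All randomness flows through `numpy.random.default_rng`
seeded from the `SimulationSpec`, making outputs byte-identical across
runs and platforms.

What the generator does *not* emulate: optical artifacts and video
quality, pressure artifact, vessel tortuosity and branching, velocity
(µm/s), and any empirical correlation structure of real patient material.
Passing tests therefore demonstrate the algorithms' internal correctness
and the direction of their relationships (e.g. the ordinal score tracks
clip-mean MFI positively and MHI negatively on a severity sweep), not the
published effect sizes, which depend on the study's unavailable videos
and rater sheets.

## Problem sizes and numerics

The heavier checks use 200 replicate studies per rater-noise level
(5 × 32 each) for the noise-degradation curve and a 200-sequence sweep
for the score-vs-MFI/MHI correspondence — sizes chosen so Monte Carlo
error is well below the effects being asserted while the whole suite
runs in well under a minute. Oracle comparisons for ICC and Dunn use a
1e-10 tolerance; exact-arithmetic facts (band boundaries, the >5 rule,
the 256-combination table) are asserted exactly. Degenerate inputs are
errors, not silent values: empty clips, non-four-clip sequences,
constant rating matrices, zero-mean MFIs and constant regressors each
raise a typed exception mapped to a distinct CLI exit code (2 validation,
3 arity/usage, 4 degenerate statistics).

## Formats

Annotations travel as CSV (one row per segment; polyline as
semicolon-separated `x,y` pairs) or JSON (lossless canonical form).
The CSV carries optional `field_width_um`/`field_height_um` columns —
the in-field invariant needs the field size — defaulting to the
simulator's 1000 × 750 µm. Flow categories are normalized to lower case
on read. Rating matrices must be complete; the validation design was
complete, and missing-cell handling is deliberately out of scope.
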