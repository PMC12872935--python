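# Methods

`pvsignal` implements the standard post-marketing signal-detection
workflow for a single target drug against the background of a
spontaneous-report database, exercised end to end on a synthetic
FAERS-like generator with known ground truth.  This note records the
models, the conventions behind every tunable default, and what the
synthetic checks do and do not establish about real data.

## Data model and cleaning

A *case* is one patient-incident; it may be reported several times, each
submission carrying a report id (`primaryid`), the shared `caseid` and a
version number.  Cleaning proceeds: quarterly tables are concatenated;
deletion lists are unioned and purged by `caseid`; then one report per
case is kept - the highest `caseversion`, ties broken by latest receipt
date, then largest `primaryid`.  The public extracts do not document a
unique canonical rule, so this deterministic version-based rule (the one
regulators recommend for retaining the most recent information) is the
package's choice.  The chain is idempotent and independent of input row
order, and every child row resolves to exactly one surviving case
afterwards - all three are tested properties.

Demographics are INNER-joined to drug rows (a case without drug rows
carries no analysable exposure and is dropped); reactions and therapy
dates are LEFT-joined, so a case without coded reactions survives with an
empty event set.  Target-drug selection is a case-insensitive substring
match on the uppercased drug name, restricted by default to the
primary-suspect role; no fuzzy matching, for reproducibility.

## Counting and fourfold tables

The counting unit is the distinct (case, PT) pair.  This reconciles the
two denominators a study of this kind reports - cases for demographics,
coded reactions for term-level percentages - and makes SOC-level counts
additive: each (case, PT) pair contributes one unit to its organ class,
so a case with two PTs in one SOC counts twice there.  Duplicate PT rows
within a case collapse to one.  "Other drugs" means every report lacking
the target as primary suspect; reports where the target appears in a
non-suspect role count as background, mirroring the PS restriction on the
signal side.  For every term a+b+c+d equals the same grand total N at a
given level, and a naive double-loop count reproduces the vectorised
builder on toy data (tested).

## Disproportionality statistics

For a table (a, b, c, d), N = a+b+c+d, se = sqrt(1/a + 1/b + 1/c + 1/d):

- ROR = ad/(bc), 95% CI = exp(ln ROR +/- 1.96 se);
- PRR = a(c+d)/(c(a+b)), with the uncorrected chi-square
  (ad-bc)^2 N / ((a+b)(c+d)(a+c)(b+d));
- IC = log2(aN / ((a+b)(a+c))) bits, interval IC +/- 2 sd with the
  delta-method sd(IC) = se / ln 2;
- EBGM = aN / ((a+c)(a+b)), 95% CI = exp(ln EBGM +/- 1.96 se).

Two deliberate simplifications are documented rather than hidden.  This
EBGM is the closed-form observed/expected ratio - identically 2^IC - not
a gamma-Poisson shrinkage posterior; its interval uses the same
log-normal form as the ROR.  And the IC interval uses a delta-method
standard deviation with multiplier 2 rather than the full BCPNN
posterior.  Both match the printed formulas this pipeline reproduces;
a full-posterior BCPNN variant is out of scope.

Thresholds: ROR lower bound > 1 with n >= 3; PRR >= 2 and chi-square >= 4
with n >= 3; IC025 > 0; EBGM05 > 2 (n = a, the report count).  The >=
comparisons are inclusive, the > strict; boundary semantics are pinned by
tests.  A combined signal requires all four.  Tables with any zero cell
are non-evaluable by default (statistics missing, flags false); the
Haldane-Anscombe +0.5 correction is available behind
`zero_cell="haldane"`.  No multiplicity adjustment gates the flags.

A caution on scaled-down backgrounds: EBGM approximates the relative risk
only while the target drug is a small fraction of the database.  In the
synthetic reference-cohort scenario the target is ~12% of reports, so EBGM sits
well below the ROR for strong signals - expected behaviour of the
formula, not an implementation artefact.  The EBGM/IC monotonicity in a
likewise holds only while a stays below both margins (rare-event regime);
the property test asserts exactly that regime.

## Time to onset

Onset = event date - earliest target-drug therapy start date + 1 day,
so same-day onset is 1 day and the Weibull log-likelihood stays finite on
day-granular data.  Records missing either date, or with the event before
the start, are excluded and tallied.  Summaries use type-7 (linear
interpolation) quartiles and half-open day bins with default edges
{1, 6, 11, 16, 21, 26, 31, inf}, so the first bin is "within the first
5 days".

The Weibull MLE solves the one-dimensional profile score in the shape
(Brent bracketing, tolerance 1e-12) with the scale concentrated out;
Wald 95% intervals come from the numerically differentiated observed
information on the log-parameter scale.  The fit agrees with an
independent scipy fit and a 200x200 grid-search oracle in tests.  Shape
< 1 with the whole interval below 1 is labelled a decreasing hazard.  The
three-parameter variant profiles the location over [0, min(days)); it is
exploratory only - with shape < 1 the likelihood is unbounded as the
location approaches the minimum observation, the classic fragility that
makes the two-parameter fit the default.  Note that fitting the
continuous Weibull to day-ceiled latencies is slightly biased upward in
the shape (the ceiling removes the density spike near zero); the
recovery checks therefore fit continuous draws, and day-level fits should
be read qualitatively.

## Subgroup, period and regimen comparisons

Comparisons are within target-drug reports.  Per term, the 2x2
stratum-by-term table of (case, term) records gives a log2 odds ratio
(the volcano x-axis; +0.5 continuity correction on zero cells) and a
p-value - the uncorrected chi-square when every expected cell is >= 5,
otherwise Fisher's exact test.  The published volcano plots this
reconstructs never state their exact axes; this definition is explicit
and tested for antisymmetry, null behaviour and type-I calibration
(significant fraction within [0.02, 0.09] under stratum-independent
generation).  Age subgroup defaults use the 18-64 vs >= 65 split
(configurable; the descriptive table uses [0,18), [18,60), [60,80),
[80,inf) left-closed bands); missing ages join neither stratum.  Period
comparison splits report years at 2020 by default.  The regimen
comparison (monotherapy vs a named comedication, any role) runs at SOC
level and emits odds ratios with log-normal intervals for a forest plot.

## Adjusted reporting odds ratios

Case-level logistic regression of outcome-PT presence on comedication
exposure, adjusted for age (linear per 10 years, centred at 55), sex
(reference female, separate unknown-sex indicator), reporting year
(linear trend, centred at the earliest year) and concomitant nephrotoxins
(default list: vancomycin plus gentamicin/tobramycin/amikacin) as
severity proxies.  Missing age uses complete-case analysis by default,
with a missing-indicator alternative; both report `n_used`.  The fit is
Newton-Raphson with Wald standard errors; with no covariates it
reproduces the closed-form fourfold odds ratio to 1e-8 (tested).
Quasi-separation (|coefficient| > 15 on the logit scale) is flagged with
a warning rather than raised; a rank-deficient design raises an error
naming a collinear column.  Whether to model at case level (chosen here:
one record per case) or (case, event) level is genuinely open in this
literature; case level avoids double-counting multi-event reports.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes:
cases with demographics (male-skewed sex mix, ~63% missing age, a
country and occupation mix, report years spanning 2015-2025), one
primary-suspect drug per case (the target in a configurable share of
cases), optional comedications given target exposure, per-term event
probabilities that are drug-independent (RR = 1) except for listed
signal terms, Weibull onset latencies (default shape 0.7, scale 8 days,
ceiled to whole days, minimum 1), duplicate report versions and
quarterly deletion lists.  PRNG: numpy's default PCG64, fully seeded;
files are byte-identical across runs for a fixed seed.

Defaults are the study conditions, fixed once: the reference-cohort scenario
targets ~1,082 target-drug cases with ~2.3 reactions per case and one
relative-risk-50 term among moderate signals; the null scenario uses
20,000 cases and 200 terms with every RR = 1.  The rare-event regime
(per-term probabilities <= 2%) keeps ROR ~ PRR ~ RR so ground-truth
recovery is meaningful.

What passing these checks does *not* show about real data: the generator
draws terms independently within a case (no syndromic correlation), has
no reporting-delay or notoriety dynamics, no drug-name misspellings, no
indication channelling (its regression confounding is injected through
age/nephrotoxin use, not disease severity), and its background is four
orders of magnitude smaller than the real database - so absolute signal
strengths, especially EBGM, are not comparable to published values, only
the behaviour of the estimators is.

## Problem sizes

The calibration and recovery suites run at sizes chosen to make binomial
noise small relative to the asserted bands while keeping the whole suite
interactive: 20,000-case nulls, 100-seed coverage loops at n = 5,000 per
fit, 1,000-table formula oracles.  Coverage assertions use >= 90/100 at a
nominal 95% interval, leaving ~3 standard deviations of slack.
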