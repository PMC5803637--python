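# Methods

## The analysis model

The unit of analysis is the *potential citation path*: an ordered pair
(cited, citing) of in-network articles in which the cited article was
published strictly before the citing article was submitted.  The dependent
variable is whether the path was realized, i.e. whether the citing
article's reference list contains the cited article.  Determinants of
citation are characteristics of the cited article (study outcome, article
type, sample size, quality, specificity, funding, bibliometric and
corresponding-author attributes) and of the pair (self-citation, time to
citation, within-network authority, attribute concordance).

Because one citing article contributes many paths, paths are not
independent.  The main estimator is therefore a logistic regression with a
normally distributed random intercept per citing article,

    logit P(y_ij = 1) = beta0 + b_i + x_ij' beta,   b_i ~ N(0, sigma^2),

where i indexes citing articles (clusters) and j paths within them.  Odds
ratios are exponentiated coefficients with Wald 95% intervals on the
log-odds scale.  Univariate ("crude") models are fitted per determinant and
repeated with adjustment for the cited article's type
(empirical/narrative); article type and sample size are strongly collinear
in such networks, so they are never adjusted for simultaneously in the
default battery, and the design+sample-size adjustment is reserved for the
empirical-only sensitivity subsets.

Concordance models (does an article preferentially cite articles *like
itself*?) and the univariate self-citation model use plain fixed-effects
logistic regression.  For a single binary determinant the fixed-effects
odds ratio is identical to the 2x2 cross-product ratio ad/bc with Wald
standard error sqrt(1/a+1/b+1/c+1/d); `contingency_or` implements that
closed form and serves as the oracle in the tests.

A post-hoc Pearson chi-square (no continuity correction) cross-tabulates
the data-based conclusion (positive/negative) against the authors'
conclusion (positive vs not-positive) among empirical articles, to detect
asymmetric interpretation ("spin") of negative findings.

## Dates, matching and derived quantities

**Dates.** All dates carry year-month resolution and date arithmetic is in
whole months (time to citation = months/12).  The effective publication
date is the earlier of the electronic and print dates.  A missing
submission date is imputed as publication minus 7 months, the network-wide
average turnaround.  A boundary tie (cited published in the citing
article's submission month) is *not* a potential path: the time to citation
must be strictly positive.  A realized citation that fails the rule (the
citing authors saw the manuscript pre-publication, which happens within
research groups) is excluded and reported with reason "forward citation".

**Matching.** References are linked to candidate articles by normalized DOI
(lower-cased, resolver prefixes stripped); a reference that did not match by
DOI is tried against the composite key of surname + first initial + year +
volume + first page, all required to match exactly.  Author keys are
lower-cased, diacritic-folded "surname,f" strings; first pages are compared
after stripping leading zeros, electronic article numbers verbatim; the
reference year is compared against the print year (electronic if no print
date exists), the year a database export prints for a cited record.  Two
candidates claiming the same reference raise an error rather than an
arbitrary pick — in a well-curated small network ambiguity indicates a data
problem, not a tie to break.

**Authority.** For author a and year y, authority(a, y) is the number of
realized within-network citations to any article a co-authored, counting
citing articles published in or before y.  Inclusive counting makes
same-year citers count, which is what lets authority depend on the citing
article's publication year.  A path's authority is the maximum over the
cited article's authors in the citing article's publication year, banded
0-5 / 6-50 / >=51.  The citing article's own citation contributes to the
table like any other realized edge (no exclusion is applied).

**Research groups** are connected components (size >= 2) of the
co-authorship graph restricted to authors with >= 3 in-network
publications — simple shared-authorship linkage, deliberately not a
modularity optimization, because at this scale the communities are visible
as disconnected components.

**Category bands** follow the characteristics-table conventions: sample
size 1-199 / 200-1999 / >=2000; authors 1-2 / 3-4 / 5-6 / >=7;
affiliations 1 / 2 / >=3; references <25 / 25-40 / >=40; impact factor
0-2 / 2-4 / >=4; time to citation in yearly bands [k, k+1).  All bands are
half-open and lower-inclusive, so a boundary value (impact factor 2.0,
40 references) belongs to the upper band.

## Numerical choices

The random-intercept likelihood is integrated per cluster with adaptive
Gauss-Hermite quadrature: each cluster's integrand is centred at its
conditional mode (found by a damped Newton iteration) and scaled by the
local curvature, then evaluated at 15 Hermite nodes.  Fifteen nodes is
comfortably beyond the accuracy knee for cluster sizes in the tens; the
estimate agrees with lme4's `glmer` (nAGQ=15) to ~1e-3 on coefficients,
standard errors and sigma in the cross-check test.  Optimization is
L-BFGS-B over (beta, log sigma) with log sigma bounded below; when the
variance component hits the boundary the model has collapsed to the
fixed-effects logistic and the information matrix is computed with sigma
held fixed, which reproduces the fixed-effects standard errors.  Standard
errors otherwise come from the numerically differentiated observed
information of the full parameter vector.

Non-convergence is a first-class outcome, never silently defaulted: a
determinant with a single observed level, an outcome without variation,
perfect separation (|log OR| > 15 or SE > 100), or optimizer failure all
yield `converged=False` with a diagnostic message and no estimates.  A
covariate level that is constant within a subset is dropped from the
design (it carries no information); a constant *determinant* is reported as
non-convergence instead.  Zero cells in the 2x2 closed form are errors — no
continuity correction is applied.  Display rounding of odds ratios is one
decimal, half-up; exported CSVs keep full precision.  Reference categories
default to the conventional ones (negative conclusion, narrative type, low
sample size, low authority, Belgium, university affiliation, ...) and are
configurable per model.  No multiple-testing correction is applied; the
report states the number of models fitted.

## The synthetic generator

The generator emulates the statistical structure of a small claim-specific
network: publication months uniform over the year range, print dates
lagging electronic by 0-3 months, submission dates exactly 7 months before
publication (recorded with probability 0.7, otherwise left missing so the
imputation path is exercised — the imputed value coincides by
construction).  Authors come from a pool with optional planted
communities; community articles draw authors only from their block, and
background authors appear in at most two articles, so the planted
communities are exactly the detectable research groups.  Coded attributes
are drawn from configurable marginals whose defaults mirror a 36-article
network's published characteristics (16/10/10 positive/negative/mixed
conclusions, 14 narrative vs 22 empirical, etc.); narrative articles are
generated without sample sizes or data-based conclusions, reproducing the
article-type/sample-size collinearity that constrains adjustment in real
data.  Citations are realized from the logistic model above with
configurable coefficients (self-citation, empirical type, positive
conclusion, time to citation, specificity, conclusion concordance),
intercept and random-intercept SD; realized citations are written into
reference lists with complete composite keys and DOIs present at the
configured coverage.  Random streams are split per sub-process (dates,
authors, attributes, realization, references) under one master seed, so
outputs are byte-reproducible and marginally perturbable.

The frozen 36-article fixture (`PAPER_LIKE_CONFIG`, seed 170402) plants two
communities (12/10/14 article split), self-citation log-OR log 4.6,
empirical log 4.2, positive-conclusion log 1.4, intercept -2.0 and
random-intercept SD 0.5; it yields 575 potential paths with 33% realized.
The recovery experiments use 45-article networks (~900 paths) with a
planted self-citation log-OR of log 5.

**What passing tests do and do not show.**  The generator reproduces the
*structure* the analysis relies on — the time rule, clustering under citing
articles, imperfect DOI coverage with complete composite keys, attribute
marginals, planted communities — so tests demonstrate that the pipeline
recovers known effects under that structure.  Real exports are messier:
reference strings with typos and page ranges, homonymous authors (no
disambiguation beyond the name key is attempted), day-level dates, DOI
registration errors, and attribute coding that required human consensus.
Matching fidelity of 1.0 on synthetic fixtures therefore validates the
algorithm, not the cleanliness of any particular export.

## Problem sizes in the shipped experiments

The test suite and the acceptance script use 200 replicates per
random-intercept condition at ~900 paths per replicate for parameter
recovery, 50 random tables for the oracle-equivalence check, 2000
simulated tables for the chi-square type-I-error check, and three seeds of
30-article networks for matching fidelity.  These sizes put the Monte-Carlo
standard error of the mean recovered log-OR near 0.015, an order of
magnitude below the tolerance used to judge it.

## Known limitations

- No fuzzy reference matching or author disambiguation; the pipeline
  assumes a curated export where exact keys suffice.
- Wald intervals throughout; profile-likelihood or bootstrap intervals may
  behave better at boundary variance estimates or with few clusters.
- The random intercept captures citing-article heterogeneity only; cited
  articles also repeat across paths, and a crossed-random-effects model is
  out of scope.
- Conflicting findings at the same validity rank of the study-outcome
  hierarchy are deliberately an error (`AmbiguityError`): no tie-break rule
  is defined, and silent resolution would hide a coding problem.
- The generator does not emulate out-of-network citation behaviour beyond
  noise references, nor citation sentiment (supportive vs critical).
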