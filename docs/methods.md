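# Methods

`bipolarnet` reimplements, as a tested pipeline, a symptom-network
analysis of bipolar disorder course types: patients are classified into
three two-year longitudinal course groups from monthly life-chart
ratings, a weighted symptom network is estimated per group from QIDS-SR /
YMRS item scores at each patient's most symptomatic assessment, and the
groups are compared on network density, node strength and random-walk
betweenness with percentile-bootstrap confidence intervals.

## Course classification

The retrospective Life Chart Method rates monthly impairment from
depression and mania on 0–4 (none / mild / moderately low / moderately
high / severe). Time proportions are counts of impaired months (severity
≥ 1) divided by 24; a mixed month counts toward both poles. The three
group definitions are applied in fixed precedence **cycling → depressed →
mildly impaired**:

* *cycling*: both poles impaired > 1/4 of the time with at least one
  moderate (≥ 2) month on each pole; or both poles ≥ 1/8 of the time with
  at least one severe (4) month; or a predominantly manic/mixed pattern
  (manic ≥ 1/3, depressed < 1/4 of the time);
* *depressed*: depressive impairment > 1/3 of the time at severity ≤ 2,
  or ≥ 1/4 of the time with at least one severe month — in both cases
  with mania ≤ 1/4 of the time and never above mild;
* *mildly impaired*: euthymic (both poles 0) > 90% of the time, or only
  mild impairment ≤ 1/3 of the time per pole, or mild-to-moderate
  (≤ 3) impairment ≤ 1/4 of the time per pole.

These printed rules are not mathematically total (e.g. a chart with 40%
of months depressed at maximum severity 3 matches none of them), so a
nearest-rule fallback keeps the taxonomy exhaustive: depressed if
`dep_frac ≥ 1/4` and `dep_frac > man_frac`; else cycling if
`man_frac ≥ 1/4` or both fractions exceed 1/8; else mildly impaired.
Every fallback assignment is itemised in the run log and in the
`rule_fired` column of the classification report. The "≤ 1/3 of the
time" clauses are evaluated per pole (a combined-time reading is
conceivable; per-pole is the implemented one).

## Symptom panel preparation

**Totals.** QIDS-SR16 is scored by the published nine-domain rule
(highest of the four sleep items + highest of the four appetite/weight
items + highest of the two psychomotor items + the six single-item
domains; range 0–27). YMRS is the plain 11-item sum (four double-weighted
items 0–8, the rest 0–4; range 0–60). Missing items propagate to a
missing total — no imputation anywhere.

**Peak timepoint.** Both totals are z-scored over the pooled set of all
patient-timepoint records and summed; each patient's most symptomatic
timepoint is the argmax, with ties resolved to the earliest timepoint.
Pooling (rather than per-timepoint standardisation) is the simplest
population choice and makes the selection invariant to affine rescaling
of either total. The baseline participates despite its low variance.

**Item merging.** Overlapping QIDS/YMRS items are combined into 14
symptom variables. Each source item is z-scored over the analysis
sample, the highest z wins, and the winning z is mapped back to the
reference item's raw scale (`z·sd_ref + mean_ref`, continuous). The
back-transformation is strictly monotone, so all downstream Spearman
edges are identical with or without it (asserted exactly in the tests).
The default source map is a configurable YAML artifact, not a constant:
the quantity-type sleep items (QIDS hypersomnia, YMRS sleep) form *sleep
duration* and the disturbance-type items (sleep-onset, mid-nocturnal,
early-waking insomnia) form *sleep quality*; YMRS content (grandiosity)
joins *self-esteem*, disruptive–aggressive behaviour joins
*irritability*, and language–thought disorder joins *increased speech*,
so that every non-excluded source item is used exactly once. The exact
map used in the original analysis is not recoverable from the published
text; users with the deposited data can supply their own map.

**Screening.** An item whose zero-fraction across the analysis sample is
≥ 0.94 is dropped (rank correlations are meaningless on such
distributions); YMRS sexual interest, appearance and insight are excluded
by default on this ground. Decisions and observed zero-fractions are
logged.

## Network estimation and metrics

Edges are groupwise Spearman rank correlations (average ranks,
pairwise-complete observations, minimum three complete pairs; a constant
item is an error rather than a silent zero). With 14 items the network
has 91 edges.

* **Density** = arithmetic mean of the 91 upper-triangle signed weights.
  An absolute-value variant exists behind a flag; signed is primary.
* **Node strength** (weighted degree centrality) = sum of the node's 13
  incident signed weights.
* **Random-walk betweenness** = Newman's current-flow betweenness with
  conductance `|weight|` (conductances must be non-negative; the signed
  option is meaningless here), computed exactly via the Laplacian
  pseudoinverse and normalised by the `(n-1)(n-2)/2` source–target pairs
  that exclude the node. The implementation is vectorised over all pairs
  (needed for 10,000-replicate bootstraps) and agrees with networkx's
  `current_flow_betweenness_centrality` to 1e-10 and with a Monte-Carlo
  absorbing-walk simulation within simulation error (both asserted in
  tests).

Edges with `|ρ| < 0.2` are suppressed in exported display networks only;
every metric is always computed on the full matrix.

## Inference

Confidence intervals are percentile bootstrap (10,000 iterations, 95%
level by default), resampling **patients** with replacement at the
original group size so within-patient dependence is preserved.
Replicates in which any item is constant (undefined edges) are redrawn
and counted; if more than half of the attempted replicates are invalid
the run aborts with a diagnostic. The point estimate is the plug-in
statistic on the observed sample; a percentile interval need not contain
it. Two groups count as *distinct* on a metric when
`|CI_a ∩ CI_b| / mean(width_a, width_b) < 0.5` (strict; an arm-based
denominator is available by flag). No multiple-testing correction is
applied — the comparison is descriptive by design.

The sensitivity analysis rebuilds each group's network as the entrywise
mean of the five per-timepoint Spearman matrices; timepoints where an
edge is undefined are dropped from that edge's mean (counted and
logged). Its bootstrap variant is off by default (it is five times the
work of the primary bootstrap) and can be enabled in the config.

## Synthetic cohort

The generator provides study-shaped data for every pipeline stage.

**Life charts** follow a first-order Markov chain over the joint monthly
(dep, man) severity state, built from a constrained parametric family:
entry rates from euthymia, episode persistence, pole-switch probability
on exit, and within-episode severity distributions. The three default
models are archetypes — rare short mild episodes (mildly impaired;
entry 0.05/0.03, persistence 0.35, severities ≤ 2), persistent
depression (entry 0.32, persistence 0.82, mania rare and mild), and
alternating bilateral episodes (entries 0.18/0.24, persistence 0.65,
switch probability 0.45). Under these defaults the rule-based classifier
recovers the true type for ≈ 99% / 94% / 87% of mildly-impaired /
depressed / cycling charts (≈ 93% overall).

**Symptom items** come from a Gaussian copula: a latent normal vector
with a type-specific correlation matrix is cut at per-item thresholds
into ordinal categories, reproducing zero-inflation and heavy ties while
controlling the latent dependence. Pre-discretisation the population
Spearman of a pair with latent correlation r is `(6/π)·asin(r/2)`;
discretisation attenuates it with no closed form, so calibration uses
large-sample runs of the generator itself. Default copulas are two-pole
block matrices (within-pole / cross-pole latent correlations 0.450/0.060
mild, 0.313/0.042 depressed, 0.385/0.220 cycling — the cycling group's
relatively strong cross-pole block is its clinical hallmark), calibrated
so the population Spearman densities at the peak condition are
**0.25 / 0.19 / 0.14** (cycling / mildly impaired / depressed).
Manic-pole items are more zero-inflated than depressive ones. Raw source
items load 0.9 on their merged item's latent factor, so the max-z merge
recovers the copula structure; the three screened YMRS items are
generated ≥ 96% zero so the screen reproduces their exclusion.

Each patient has one designated post-baseline peak visit at full
severity; other visits are shifted strongly toward zero (baseline most
of all, matching the mostly-euthymic study entry). The wide severity gap
makes the empirical most-symptomatic timepoint almost always the
designed one — without it, selecting the maximum of noisy totals
conditions on the noise and visibly attenuates the selected-timepoint
correlations (a Berkson-type artifact of iid visits that real episodic
data does not share).

What the generator does **not** emulate: month-level coupling between
charts and symptom scores (coupling is type-level only; the pipeline
never joins months to timepoints), treatment effects, dropout, and the
empirical behaviour of timepoint-averaged networks — in synthetic data
the remitted visits are dominated by a few residual-symptom patients,
which *inflates* per-timepoint correlations, whereas the study observed
slightly lower averaged densities. Passing tests therefore demonstrate
correctness of the pipeline's computations on study-shaped data, not
clinical realism of every marginal.

**A known statistical limit.** With three groups of ~40 patients, the
density estimator's sampling SD is ≈ 0.04–0.06 (it cannot be much
smaller: edge estimates co-vary through the correlation structure
itself, giving SD ≳ √2·ρ̄/√n for mean correlation ρ̄). That is the same
order as the 0.05–0.06 gaps between the three generating densities, so
replicate cohorts at n = 40 recover the full density ordering only ~55–65%
of the time, whatever the copula structure. The corresponding
acceptance check is left failing by design rather than met by weakening
it; single-cohort ordering results at these sample sizes should be read
with matching caution.

## Numerical choices

* Spearman via average ranks then product-moment correlation; no
  continuity corrections, no p-values.
* Percentile CIs use linear-interpolation quantiles (`numpy.percentile`
  defaults).
* Bootstrap seeds: each group's resampling RNG is spawned
  deterministically from the run seed via `SeedSequence([seed, index])`,
  so runs are bit-reproducible and groups are independent.
* Ties in top-k tables break alphabetically and set a flag when a tie
  straddles the cut.
* Run logs contain no timestamps, so identical config + seed yields
  byte-identical output files.

## Problem sizes used in the checks

The shipped checks run the full pipeline on the default 125-patient
cohort with 10,000 bootstrap iterations; bootstrap-coverage calibration
uses 500 replicate experiments of n = 40 with 400 iterations each;
ordering recovery uses 250 replicate cohorts; label recovery uses 1,000
charts. These sizes give Monte-Carlo error well inside the asserted
tolerances.
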