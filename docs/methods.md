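# Methods

## Data model and preprocessing

The pipeline's single input is a species × trait matrix: one row per
species with its IUCN category and fifteen functional traits (see
`bryorisk.registry` for the canonical list). Preprocessing applies three
rules:

* **Status binarisation.** EX/CR/EN/VU → threatened (1); NT/LC →
  non-threatened (0); DD is held out of all fitting and kept as the
  prediction set.
* **Empty binary cells mean absent.** Taxonomic descriptions mention
  structures that are present; a missing entry for a presence-type trait
  (sporophyte presence, vegetative reproduction, persistent protonema) is
  therefore imputed as absence. Missing continuous or categorical cells
  stay missing.
* **Substrate breadth** is the count of *distinct* substrate labels a
  species is recorded on, with equal weighting. An empty substrate list is
  a missing value, not zero — unknown breadth is not breadth zero.

Continuous traits are z-scaled before modelling; scaling parameters are
estimated as mean and sample SD (n−1 denominator, the default of common
statistical software) from non-DD records only, and stored so that
raw-unit inputs can be scored later. Range-valued cells ("4–8 mm") are
parsed to the midpoint — the only parameter-free reading of a printed
range.

## Statistical core

All models are binary logistic GLMs fitted by maximum likelihood
(IRLS via statsmodels; convergence at relative log-likelihood change
< 1e-8, 100 iterations max). Inference is Wald: symmetric
estimate ± z·SE intervals, matching the ±-half-width reporting
convention of the packaged models. Complete cases are recomputed *per
model*, which is why the two minimum adequate models legitimately use
different subsets (and different scaling moments) of the same matrix.
Perfect or quasi-complete separation is surfaced as a typed
`SeparationError` rather than returning divergent estimates — small trait
tables make separation likely and silent garbage is worse than an error.

Auxiliary statistics: Pearson chi-square on 2×2 tables without continuity
correction; variance inflation factors as 1/(1−R²) from OLS regressions of
each predictor on the rest (exact collinearity reported as infinite with
the culprit pair); binned residual diagnostics with ±2 SE bands.

## Screening and model construction

Each trait is screened univariately (threat ~ trait, α = 0.05, no
multiplicity correction — the screens feed model construction, they are
not confirmatory tests). Categorical traits use the first registry
attribute as reference level. Trait pairs suspected of dependence are
screened with chi-square (binary × binary) or a logistic fit of the binary
trait on the natural log of the continuous one (log base unstated in the
field convention; natural log chosen).

The significant traits define two maximal models: model 1 = significant
non-morphology traits plus sporophyte presence (applies to all species);
model 2 = all significant traits minus sporophyte presence minus
correlation-based exclusions (seta shape is excluded as a proxy for seta
length). Each is reduced by **forward-only** stepwise AIC: from the
intercept, repeatedly add the candidate with the lowest AIC if it improves
the current AIC strictly, stop otherwise. Forward-only is the literal
reading of the selection procedure being reproduced and is the only
direction implemented; ties break by candidate registry order for
determinism. An exhaustive best-subset search exists solely as a test
oracle (the greedy result can never beat it, and tests assert exactly
that bound, not equality).

## Cutoff selection

Candidate thresholds are the observed score values plus {0, 1}, with the
rule `score ≥ threshold ⇒ threatened`; restricting to observed values
keeps the ranking finite so "the k-th best cutoff" is well defined. The
Index of Union scores each cutoff as `IU(c) = |Se(c) − AUC| +
|Sp(c) − AUC|` and ranks ascending (ties: smaller |Se − Sp|, then lower
threshold). Because the models exist to catch truly threatened species,
sensitivity takes priority: the ranking is walked from the top and the
first cutoff with Se ≥ 0.70 is chosen; when that is not rank 1 the
selection is labelled `sensitivity_override`. If no cutoff qualifies the
IU optimum is kept with a warning. AUC is trapezoidal over
(1−Sp, Se) and equals pairwise concordance with ties counted ½ — one
numerical subtlety is that tied-FPR points must be ordered by ascending
TPR before integrating.

## Scoring and triage

The two published models are shipped as versioned JSON parameter records
(raw-unit scale, with their scaling constants and cutoffs), so species can
be scored without refitting. The morphology model's printed equation is
reproduced with (seta − 14)/13.32 and (breadth − 1.8)/0.98; its baseline
risk evaluates to 16.1% from the two-decimal published coefficients (a
printed "17%" reflects unrounded coefficients — the package reports what
the published coefficients give and does not force the rounded figure).
The packaged 44-species DD table keeps the published per-species risk
scores verbatim; triaging it applies only classification and the verdict
rule. Species scoreable by neither model go to an exclusion report.

## Synthetic cohorts

The generator (`bryorisk.cohort`) emulates the real cohort's structure:

* **n = 723 species, ~22% threatened.** Threat status is Bernoulli with a
  logit linear in the published predictors (monoicy +0.54, sporophyte
  presence −1.18, substrate breadth −0.83 per SD, seta length −0.61 per
  SD). The baseline logit default is −1.0, calibrated once at large n so
  the *marginal* threatened fraction is ~0.222; the published intercept
  −0.79 is conditional on the reference profile, not the marginal rate.
* **Sex-conditional reproduction.** Monoicy probability 0.4 (marginal
  monoicy/vegetative/sporophyte frequencies are not published; these are
  package choices). Vegetative reproduction (marginal 0.35) and sporophyte
  presence (marginal 0.65) are drawn with a dioicous:monoicous odds ratio
  of 2 each, via a closed-form 2×2 margin solver.
* **Lengths log-normal.** Positive and right-skewed; seta length uses the
  published moments 14 ± 13.32 mm (a CV near 1 implies strong skew),
  other lengths use field-plausible moments. Substrate breadth is
  1 + Poisson(0.72) — a count trait with mean ≈ 1.72 and SD ≈ 0.85, near
  the published 1.69/0.94.
* **Seta shape** follows a logistic in log seta length (longer setae bend
  under the capsule's weight, hence curve), odds ratio 2 per log-mm.
* **Block missingness.** A configurable fraction (default 0.22, the
  shortfall of the morphology model's sample) of species loses all
  sporophyte-morphology traits. The mask is drawn independently of
  sporophyte presence to keep the missingness rate exactly interpretable;
  real sporophyte-absent species would of course lack morphology — a known
  simplification.

One seed sequence is split into per-trait substreams so partial
regeneration stays reproducible. The generator makes no attempt at
phylogenetic structure: related species sharing trait values (and hence
identical risks) is a feature of real data the cohorts do not emulate, so
passing recovery tests demonstrates statistical correctness of the
machinery, not robustness to phylogenetic pseudo-replication.

## Problem sizes in the test suite

Recovery and calibration tests use cohorts of 300–2,000 species and
20–200 replicates: large enough that binomial tolerance bands (3 SE) are
meaningful, small enough to keep the suite fast. Coverage of the 95% Wald
intervals is checked over 200 replicates at n = 2,000 against the exact
generating design.

## Known limitations

* Forward-only selection can miss subsets a hybrid or exhaustive search
  would find; the greedy-vs-exhaustive bound is tested but equality is not
  claimed.
* Wald intervals are first-order; profile-likelihood intervals are not
  implemented.
* No penalised (Firth) fallback for separated fits — separation is an
  error by design.
* Triage verdicts are binary/ternary screening outcomes, not IUCN
  categories; they prioritise species for full assessment and do not
  replace one.
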