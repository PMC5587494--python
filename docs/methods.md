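# Methods

This note documents the models implemented in `warblerstop`, the defaults
of the synthetic-data generator, the numerical choices, and the limits of
what the synthetic validation can show about real field data.

## Isotope assignment

Feather hydrogen-isotope values are linked to growing-season precipitation
through the linear calibration δ²H_f = 0.95·δ²H_p − 17.57 (the published
relationship for non-ground-foraging Nearctic–Neotropical passerines); the
inverse map is exact, and the round-trip identity is enforced to 1e−9 in
tests. Assignment error — measurement plus calibration, a combined SD of
5.5 ‰ — is applied on the **feather scale**: the source of the 5.5 ‰ figure
does not state the scale, so this is a package choice, configurable via
`error_sd` and the calibration coefficients. The Monte-Carlo procedure
draws `n_draws` (default 1,000, seeded) normal values around the measured
feather value, converts each to the precipitation scale, and reports the
fraction falling in each destination window; an analytic normal-CDF
counterpart (`region_probability_analytic`) serves as the oracle in tests,
and the Monte-Carlo estimate converges to it at rate 1/√n_draws.

The default classification rule is window membership of the point estimate
(the precipitation equivalent), because the study design defines fixed,
non-overlapping windows; a max-posterior rule with probability threshold is
provided for sensitivity analysis. Anything outside both windows —
including the −50…−70 ‰ gap between them — is "unassigned"; the gap exists
precisely so that windows do not overlap once error is taken into account.
With the default windows and error, a bird whose true value lies ≥1 SD
inside its window is practically never assigned to the *wrong* destination
(the gap is ≈3.5 SD wide), but ~2–3 % of boundary-adjacent birds land in
the gap; the closed-form expectation of this rate is asserted in tests.

Isoscape reclassification builds, per destination, the pooled origin
density of a set of birds (each bird contributing one normal component with
SD `error_sd`/0.95 on the precipitation scale), finds highest-density
thresholds enclosing 50/75/90 % of the mass by fine-grid quadrature, and
labels each grid cell with the smallest level whose threshold its value
exceeds. Categories are nested by construction. Grids are accepted as ESRI
ASCII (.asc, cell-center convention, longitudes −180…180) or long-format
lon/lat/value CSV.

## Condition and timing

Migratory condition is body mass minus a size-specific fat-free mass
predicted from wing chord, `0.014·wing + 2.0086`. **Caveat:** these printed
coefficients give ≈2.8–3.0 g of lean mass for realistic warbler wing
chords, far below the species' ~10 g body mass, and are almost certainly a
typo in the original source (units or digits). They are implemented exactly
as printed because no corrected values exist, and both coefficients are
arguments to `fat_free_mass` / `condition_index`. The synthetic generator
sidesteps the inconsistency by drawing condition directly and
reconstructing mass as fat-free mass + condition, so the index round-trips
exactly whatever the coefficients.

Timing classes split each year × sex × destination group's **capture-date
range** (not its count quantiles) into equal thirds — this matches the
"range of capture dates" design. Intervals are left-closed with the final
interval closed, so a date exactly on a cut point belongs to the later
class and the last day is "late". A zero-range group (all birds on one day)
is labeled entirely "middle" with a warning; the choice is neutral and the
situation cannot arise under the generator's defaults.

Food-availability trends are ordinary least squares of abundance
(arthropods per gram of dry vegetation) on day-of-year within seasons, and
a one-way ANOVA across years, both via scipy; constant-abundance and
single-year inputs are flagged as degenerate rather than erroring.

## Refueling index and two-tier model selection

Metabolite concentrations are ln(1+x)-transformed (as is bleed time, in
every model that uses it). The refueling index is the first principal
component of the **covariance** (not correlation) matrix of the transformed
pair: the two metabolites live on comparable log scales, and only
covariance PCA can produce the asymmetric loadings (≈+0.88 triglyceride /
−0.48 BOHB) characteristic of this assay pair. The sign is fixed so
triglyceride loads positively; scores are centered, so their mean is zero
and their variance equals the leading eigenvalue.

Linear models are ordinary least squares with the Gaussian **maximum
likelihood** log-likelihood (not REML), so AICc comparisons across
fixed-effect structures are valid; k counts the residual variance. AICc =
−2lnL + 2k + 2k(k+1)/(n−k−1) with n the number of rows. Categorical terms
are dummy-coded against stated reference levels (sex = F, age = SY,
destination = southeast, timing = early).

Candidate sets are all subsets of the main effects, each augmented with
every subset of the allowed two-way interactions whose parent mains are
present (interaction hierarchy). Tier 1 uses the four methodological terms
{lnBleedtime, Daytime, Season, Year}: 15 subsets + null = 16 models. The
terms of the single lowest-AICc tier-1 model are then appended to every
non-null tier-2 model. Tier 2 uses {Breeding, Timing, Condition, Age, Sex}
with the five meaningful interactions (Breeding×Timing, Breeding×Age,
Breeding×Sex, Timing×Age, Timing×Sex); the hierarchy rule yields **exactly
144 candidates** including the null and the global model, matching the
published candidate count, which supports this reading of the enumeration.
lnBleedtime is transformed everywhere it appears (the alternative — raw
bleed time in the screening tier — is not implemented).

Model-averaged coefficients use weights renormalized over the models
containing the term (within the ΔAICc ≤ 4 top set); unconditional SEs
follow Burnham & Anderson, Σw̃ᵢ·√(SEᵢ² + (βᵢ−β̄)²); relative importance
w₊(j) sums the *unrenormalized* Akaike weights of all candidates containing
the term. Predicted destination × timing group means are
population-averaged (each model predicts at the cell's mean design row) and
averaged over the top set with the same unconditional formula.

## Transient CJS and stopover quantities

The likelihood is the standard CJS conditional-on-first-capture form with
the never-seen-again χ recursion, vectorized over birds. Two
time-since-marking classes are used: φ₁ for the interval immediately after
capture and φ₂ for all later intervals; both are logit-linear in individual
covariates, as is detection p (constant over occasions within a bird; a
first-study-year indicator captures the year without resighting effort).
"Survival" is read throughout as site persistence — the design assumes no
mortality at the stopover site. Within-season time variation in φ is out of
scope by design.

Fitting is BFGS on the logit scale from five seeded starts (gradient
tolerance 1e−8); the variance-covariance matrix is the inverse of a
central-difference numerical Hessian, with singularity flagged rather than
fatal. AICc uses the number of released individuals as n — the effective
sample size for CJS models is not settled, and releases is the conservative
conventional choice. The likelihood is validated against brute-force
enumeration of all possible histories (outcome probabilities sum to 1 at
≤4 occasions, tolerance 1e−10) and against hand-computed products.

Derived quantities:

* expected stopover duration of non-transients, −1/ln(φ₂): the expected
  lifespan under constant daily persistence; SE by the delta method,
  SE(φ)/(φ·ln²φ);
* transient probability τ = 1 − φ₁/φ₂, reported as a percentage; delta
  method with gradient (−1/φ₂, φ₁/φ₂²) and the fitted covariance of
  (φ₁, φ₂). Values outside [0, 100] from sampling noise are clamped and
  flagged. Delta-method SEs agree with parametric-bootstrap SEs within 15 %
  at n = 1,000 (tested).

Model averaging across the ΔAICc ≤ 4 set is done on the **real
(probability) scale** with renormalized weights, because the reported group
quantities are real-scale: group φ₂ is averaged (unconditional SE) and then
transformed to a duration, while the transient percentage is computed per
model (it needs that model's within-model cov(φ₁, φ₂)) and the percentages
averaged with the same unconditional formula. Group estimates are
population-averaged over the group's members, with condition at its
observed values — equivalent to evaluating at the group's average
condition for the near-linear ranges involved.

Small-sample behavior worth knowing: when a group's raw first-interval
persistence estimate exceeds φ₂ (i.e. raw τ̂ < 0), the φ₁ MLE drifts to the
boundary at 1 with an enormous logit-scale SE, and the reported transient
percentage clamps to 0 with a wide real-scale SE. This mirrors how such
groups appear in published transient-model tables ("0 ± 11 %") and is
reported, not hidden.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the validation runs under.

* **Design size:** 80 birds per destination (the field study assigned 88
  southeast / 73 boreal), four years, plasma assayed for a random
  subsample of 85 birds (as in the study), nine-occasion histories for
  every bird.
* **Isotopes:** true δ²H_p uniform within the destination window
  (configurable to Gaussian in spirit — the windows are all the source
  specifies), feather-scale noise SD 5.5 ‰.
* **Arrival dates:** normal per destination × latent timing class, means
  97/105/113 (southeast) and 111/119/127 (boreal) with SD 4 d — centered on
  the reported group mean arrival days (105.0 and 119.1).
* **Transience and persistence:** transients are a point mixture (present
  only on the capture day) rather than a reduced first-day φ, which makes
  τ identifiable as exactly 1 − φ₁/φ₂. Defaults τ = 0.10 (southeast) /
  0.50 (boreal) and φ = 0.70 / 0.68 — back-solved from the published
  transient percentages and durations (duration d ⇒ φ = e^(−1/d)).
  Detection p = 0.40 in resighting years, 0.10 in the first year; an
  optional condition effect on logit φ₂ (default −0.11) reproduces the
  reported ≈ −0.26 days per unit condition at φ ≈ 0.7.
* **Metabolites:** (ln(1+trig), ln(1+BOHB)) bivariate normal. The residual
  covariance is *reconstructed from the published eigenstructure*: leading
  eigenvector (+0.88, −0.48) and a 76 % leading-axis share — which are
  mutually consistent and imply residual correlation ≈ −0.456. The overall
  scale (leading-axis residual SD 0.25) is set so that the published
  bleed-time effect (−0.21 per unit ln-bleed-time) carries the strength of
  evidence the published tier-1 selection shows (ΔAICc ≈ 6.4 for Bleedtime
  over the null corresponds to |t| ≈ 2.9 at the study's n). Covariate
  effects are specified on the *index scale* and mapped onto the pair along
  the residual leading eigenvector, so generated effect sizes are directly
  comparable to fitted index coefficients: bleed time −0.21, condition
  +0.11, and destination × timing offsets emulating the published pattern
  (southeast high-early/low-middle/high-late; boreal uniformly ≈ −0.13).
  Bleed times are gamma with mean 6 min, SD 3.4, truncated to 0.5–20 min.
* **Seeding:** one global seed; every stage draws from a named substream
  (CRC32 of the stream name mixed with the seed), so stages regenerate
  independently and fixed seeds give byte-identical files.

What the generator does **not** emulate: spatially explicit movement,
weather and phenology covariates, assay measurement error structure,
heterogeneous individual detection, age/sex effects on metabolites, or
real isoscape geometry. Passing recovery tests therefore demonstrates that
the estimators are correct and well-calibrated *under the assumed model*,
not that the assumed model captures every feature of field data.

## Problem sizes used in validation

The test suite validates at the study's own scale where that matters
(n = 85 plasma samples for refueling recovery; 100 replicates) and at
n = 1,000 histories for CJS recovery, Wald-CI coverage (200 replicates)
and delta-vs-bootstrap comparisons (200 bootstrap refits) — sizes at which
the asymptotics the tests assert are expected to hold while the whole
suite stays fast.

## Known limitations

* The full published detection structure p(breeding, timing, condition,
  year) is configurable but not the default: with ~160 histories and ~40
  re-encounters it is weakly identified, and the default pipeline uses
  p(first-year) only.
* Whether published model averaging operated on the logit or real scale is
  not stated; this package averages on the real scale (documented above).
* AICc sample size for CJS uses releases; other conventions exist.
* The refueling analysis assumes Gaussian identity-link models only.
* Boundary behavior of φ₁ (above) makes group transient SEs unreliable in
  small groups; the `singular_hessian`/clamp flags should be checked before
  interpreting them.
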