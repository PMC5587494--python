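# warblerstop

Toolkit for analyzing the **spring-stopover strategies of migratory
songbirds** in relation to breeding destination and migration timing. It was
built around the study design used for black-and-white warblers (*Mniotilta
varia*) captured at a Gulf-coast stopover site: birds are geographically
linked to a breeding destination through stable hydrogen isotopes, their
refueling performance is scored from blood-plasma metabolites, and their
stopover duration and same-day-departure (transient) probability are
estimated from daily capture/resight histories.

The package is a library first — import it from Python, or use the thin
`warblerstop` CLI for the pipeline. A synthetic-data generator with the same
statistical structure as the field study makes every stage testable
end-to-end without any field data.

## What it computes

**Isotope assignment.** Feather values δ²H_f are converted to precipitation
equivalents through the passerine calibration

    δ²H_f = 0.95 · δ²H_p − 17.57

and measurement/calibration error (SD 5.5 ‰) is propagated with 1,000
normal Monte-Carlo draws, yielding P(origin) for each destination window
(southeast −10…−50 ‰; boreal forest −70…−130 ‰). An isoscape grid can be
reclassified into nested 50/75/90 % probability-of-origin regions.

**Condition and timing.** Migratory condition = body mass − fat-free mass
(0.014·wing chord + 2.0086); each year × sex × destination group's
capture-date range is cut into equal thirds (early/middle/late), so timing
is relative to conspecifics headed for the same destination.

**Refueling index.** Plasma triglyceride (fat deposition) and
β-hydroxy-butyrate (fasting) are ln(1+x)-transformed; the first principal
component of their covariance matrix is the per-bird refueling score.
A two-tier AICc model selection explains index variation: tier 1 screens
methodological covariates (ln Bleedtime, Daytime, Season, Year; 15 subsets
+ null), tier 2 carries the tier-1 winners into 144 hierarchical candidate
models over Breeding, Timing, Condition, Age, Sex and their meaningful
interactions, with Akaike weights w_i, model-averaged coefficients,
Burnham–Anderson unconditional SEs and relative importances w₊(j).

**Stopover duration.** A Cormack–Jolly–Séber model with time-since-marking
(transient) structure is fit by maximum likelihood to day-1-collapsed,
nine-occasion encounter histories: φ₁ for the first interval after capture,
φ₂ for later intervals, detection p with a first-study-year effect. Under
no mortality at the site,

    expected stopover duration = −1 / ln(φ₂)        (expected lifespan)
    transient probability     τ = 1 − φ₁ / φ₂

with delta-method SEs, AICc model ranking and real-scale model averaging.

## Worked example

`examples/05_stopover_cjs.py` simulates 1,000 histories (40 % transients,
resident daily persistence 0.72, detection 0.4) and refits them:

```
n = 1000 histories, 9 occasions; AICc = 3348.0
apparent first-interval persistence phi1 = 0.436 (truth 0.432)
resident daily persistence        phi2 = 0.729 (truth 0.72)
detection probability                p = 0.388 (truth 0.4)
expected stopover duration = 3.16 +- 0.21 days
transient probability      = 40.2 +- 3.9 % (truth 40%)
```

The fitted φ₂ = 0.729 means a bird that stays past its arrival day remains
with 73 % probability each further day, i.e. an expected stay of ~3.2 days;
40 % of newly caught birds leave the same day they arrive.

`examples/06_full_pipeline.py` (equivalently
`warblerstop run-all --seed 1 --out out/`) runs the whole chain on the
default synthetic study (160 birds, 85 plasma samples) and prints the
report, including e.g.

```
- metabolite correlation r = -0.542 (t = -5.88, df = 83)
- PC1 variance explained = 80.3%
- loadings: triglyceride 0.88, BOHB -0.48
...
| destination=boreal | 72 | 0.685 | 2.65 | 0.48 | 49.0 | 14.2 |
| destination=southeast | 68 | 0.689 | 2.69 | 0.44 | 0.0 | 8.7 |
```

— boreal-bound birds (long distance remaining) are far more likely to
depart on the day of arrival than southeast-bound birds, and scores load
positively on triglyceride and negatively on BOHB, as the generating model
intends. The other examples cover isotope assignment, condition/timing,
the refueling index, and the two-tier model selection.

## Layout

```
src/warblerstop/
  config.py      simulation & study configuration (YAML round-trip)
  synth.py       synthetic-study generator with truth records
  isotopes.py    calibration, Monte-Carlo assignment, isoscape HDR classes
  birds.py       condition index, timing classes, arthropod trends
  metabolites.py ln+1 transforms, correlation, covariance-PCA index
  modelselect.py AICc, weights, candidate enumeration, model averaging
  refuel.py      two-tier refueling model selection
  cjs.py         transient CJS likelihood, fitting, stopover quantities
  io.py          CSV / MARK .inp / ESRI ASCII grid readers & writers
  pipeline.py    stage orchestration, validation, Markdown report
  cli.py         `warblerstop` subcommands (simulate … run-all, validate)
examples/        one narrative script per capability
docs/methods.md  model assumptions, parameter choices, limitations
```
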