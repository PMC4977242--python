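# Methods

## The problem

An operator measuring a small anatomical structure by ultrasound — here the
optic nerve sheath diameter (ONSD), a non-invasive surrogate for intracranial
pressure read to the nearest 0.1 mm — improves with practice. `plateaulc`
estimates *how many subjects an operator must examine before their measurement
error stabilises*, using a reliability definition of the learning curve: the
within-subject variance of repeated measurements falls as skill accrues and
eventually plateaus, while the per-subject means and their between-subject
spread stay put.

The key identifying assumption is that every repeated measurement on one
subject (both eyes, two imaging planes: four values) targets the same true
quantity, so all within-subject spread is measurement error. Under that
assumption the per-subject sample variance (denominator n−1), ordered by the
chronological index *I* of examination, traces the operator's error over time.

## The model

Within-subject variance is modelled as a **quadratic–plateau curve with a
smooth join**:

```
var(I) = a + b·I + c·I²   for I ≤ K      (learning phase, c > 0)
var(I) = P                for I > K      (plateau)
```

Continuity plus zero slope at the knot K force K to be the quadratic's vertex:

```
K = −b / (2c),        P = a − b² / (4c).
```

The smooth join removes one free parameter; re-parameterised around the knot
the model is

```
var(I) = P + c·(I − K)²·1[I ≤ K],
```

linear in (P, c) for fixed K. **Fitting is a profile search**: ordinary least
squares in (P, c) at every integer candidate K (default grid: the full
interior of the index range, so both segments always contain data), keep the
K with the smallest residual sum of squares, then polish K by a bounded
continuous minimisation between its grid neighbours (`xatol = 1e-9`). This
has no starting-value sensitivity and no missed local minima beyond the grid
spacing, and is verified in the test suite against an exhaustive brute-force
search. Candidates with c ≤ 0 carry no decreasing limb and are discarded.

Numerical choices:

* **Tie-break** — candidate knots whose RSS agree within 1e-10 resolve to the
  smaller K, the more conservative learning-curve claim.
* **Degeneracy** — if no candidate fits better than a flat line (within the
  same tolerance; this includes exactly constant series, where floating-point
  OLS can return a vanishing positive curvature), the fit returns the mean
  variance as a pure plateau with `degenerate=True`. The pipeline exits
  non-zero on a degenerate fit unless `--allow-degenerate` is passed, so
  automation cannot silently accept "no learning curve found".
* **Integer knot** — `knot_index` is K rounded half-away-from-zero; the
  continuous K is always reported alongside.
* **Weighting** — unweighted least squares by default. A variance estimated
  from 4 replicates is itself noisy with variance ∝ var(I)² (heteroscedastic),
  so an optional observation-weights argument exists, but the default
  reproduces the plain reading of the method.

## Validating the split

Finding a plateau certifies the operator, not the early data. The early
group (I ≤ knot_index) and late group are compared on the **per-subject
means** — one number per subject, never pooled raw measurements — with:

* **Welch's two-sample t test** (two-sided; Welch–Satterthwaite df) for
  equality of group means;
* **Levene's test** for homogeneity of the between-subject variance,
  a one-way ANOVA on absolute deviations from the group **mean** (classic
  Levene) by default; `center="median"` gives the Brown–Forsythe variant.

Both run overall and within sex strata, with raw unadjusted p-values per
stratum. Degenerate inputs (all values identical) return t = 0 / W = 0 with
p = 1 by convention and a `flagged` marker. Equivalence (TOST) testing would
arguably be the right tool for a "no difference" claim; it is deliberately
out of scope and the p-values should be read descriptively.

## Units and the scale factor

Means are always in mm. Variances are computed after multiplying values by
`scale_factor`, default **10** — a tenths-of-mm scale. With population means
near 3.7 mm and between-subject sd near 0.38 mm, tenths-of-mm units put the
between-subject variance near 14 and the error plateau near 3, i.e. variance
magnitudes of order 1–20 rather than 0.01–0.2; it is also the scale at which
the instrument reads. Variance scales with the square of the factor
(`scale_factor=1` recovers mm² throughout), and the same switch feeds the
regression, the reported between-subject variances, and the simulator.

## What the simulator emulates

`simulate_dataset` reproduces the study design the method assumes:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 120 | chronologically indexed subjects |
| `n_measurements` | 4 | sites per subject ({left,right} × {horizontal,sagittal}) |
| `population_mean` | 3.68 mm | population mean of the true quantity |
| `between_subject_sd` | 0.38 mm | anatomical spread of true values |
| `curve` | P=2.78, c=0.03843, K=21 | error-variance learning curve (scaled units) |
| `sex_fraction_male` | 65/120 | exact male count, labels shuffled |
| `sex_mean_offset` | 0 mm | optional male−female mean shift (≈0.3 echoes real data) |

Each subject draws a true mean from Normal(population_mean ± offset/2,
between_subject_sd); each measurement adds independent Gaussian error with
sd = √(curve(I))/scale_factor mm, redrawn while non-positive (lengths cannot
be negative; with the defaults the truncation probability is < 1e-10, so
moment checks ignore it). The between-subject sd of 0.38 mm is an
interpretation: it is back-solved from reading the reported population
interval 2.85–4.40 mm as mean ± ~1.96 sd, since no sd is given directly.
`simulate_variance_series` skips the measurement level and draws the
regression response directly, var(I) = max(0, curve(I) + Normal(0, sd)) —
the right tool for exercising the fitter alone.

What the generator does **not** emulate: correlated errors across the four
sites (the identity assumption treats them as independent), operator drift
or fatigue beyond the monotone curve, heteroscedastic sampling noise of the
4-replicate variance estimate (the series generator uses homoscedastic
Gaussian noise), digit-quantised readings, or true left/right anatomical
differences. Passing tests therefore show the machinery is correct under the
model's own assumptions, not that real data satisfy them.

## Problem sizes in the checks

The reproduction script (`scripts/acceptance.py`) works at the study's own
scale: series of 120 subjects, 200 noisy replicates at noise sd 0.5 for the
median-knot experiment. The test suite uses 10 000 subjects for
law-of-large-numbers moment checks (3–5% tolerance), 1000 seeded replicates
for type-I-error calibration of the Welch/Levene machinery (acceptance band
0.03–0.07 at α = 0.05), and 200 replicates for knot-recovery rates.

## Known limitations

* **Knot precision degrades quickly with noise.** With the reference
  curvature, ±2-subject recovery of the knot holds in ≥99% of replicates at
  noise sd up to ~5% of the curve's range, but collapses (≈43%) by 20% —
  an information limit, not an optimisation failure: the fitter provably
  attains the global least-squares optimum, and absolute noise grows with
  the knot position while the curvature that localises it stays fixed.
  Single noisy realisations should be read with that uncertainty in mind;
  bootstrap intervals for K are a natural extension, not implemented.
* The method presumes the variance is non-increasing toward a plateau; skill
  decay, retraining gaps, or multi-phase learning violate the single-knot
  form and will surface as a poor fit or a degenerate flag, not a warning.
* One operator, one curve: no mixed-effects pooling across operators.
* The early/late validation uses plain null-hypothesis tests; a
  non-significant p is weak evidence of equivalence, especially in the
  small early group (~21 subjects).
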