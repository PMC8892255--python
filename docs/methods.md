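# Methods

## The model

glykit represents a 5-point oral glucose tolerance test (OGTT) with paired
insulinemia measurements as the output of a five-compartment ordinary
differential equation system.  Glucose amounts sit in the stomach S, the
jejunum J and the ileum L (mmol); concentrations in blood are glycemia G (mM)
and insulinemia I (pM):

    dS/dt = -k_js S
    dJ/dt =  k_js S - J/tau - k_gj J
    dL/dt =  J/tau - k_lg L
    dG/dt =  eta (k_gj J + k_lg L) + P0 - k_xg G - k_xgi G I
             + k_lambda max(G_b - G, 0) - gamma max(G - G_b, 0)
    dI/dt =  beta max(G - G_b, 0) (1 + f_gi (J + L)) - k_xi (I - I_b)

with basal endogenous production P0 = k_xg G_b + k_xgi G_b I_b, chosen so
that (0, 0, 0, G_b, I_b) is an exact equilibrium: with no dose, nothing moves.
The initial state places the whole dose D in the stomach.  The right-hand
side is pluggable (`simulate_ogtt(..., rhs=...)`): every downstream statistic
consumes only the parameter vector, so an alternative functional form can be
swapped in without touching the rest of the package.

Parameters, with units on the canonical scales (mM, pM, min, mmol):
gastric emptying k_js (min⁻¹), jejunal transit time tau (min), jejunal and
ileal absorption k_gj / k_lg (min⁻¹), gut-to-blood distribution factor eta
(mM per mmol absorbed; its tabulated unit string "L⁻³" is stored as printed),
insulin-independent and insulin-dependent glucose uptake k_xg (min⁻¹) and
k_xgi (min⁻¹ pM⁻¹), hepatic release/uptake responsiveness k_lambda / gamma
(min⁻¹), incretin potentiation f_gi (per mmol of gut glucose), pancreatic
responsiveness beta (pM min⁻¹ mM⁻¹), insulin turnover k_xi (min⁻¹), and the
basal levels G_b, I_b.  Unit conversions use the clinical factors
180 mg/dL = 10 mM and 1 uU/mL = 6.945 pM exactly (so a 75 g dose is
75/0.18 = 416.67 mmol); the glucose factor is the conventional clinical one,
not the 180.16 g/mol molar mass.

## Dimensionless numbers

Each physiological subsystem is summarised by one dimensionless Pi number,
built from the parameters and the natural scales of the problem (G_b, I_b, D,
and the glucose turnover time t_c = 1/(k_xg + k_xgi I_b)):

| number | subsystem           | formula              |
|--------|---------------------|----------------------|
| Pi_S   | digestive motility  | k_js tau             |
| Pi_N   | incretin load       | f_gi D               |
| Pi_D   | glucose distribution| eta D / G_b          |
| Pi_B   | basal uptake ratio  | k_xgi I_b / k_xg     |
| Pi_X   | insulin activity    | k_xgi I_b t_c        |
| Pi_I   | pancreatic response | beta G_b t_c / I_b   |
| Pi_R   | hepatic response    | (k_lambda + gamma) t_c |

Pi_X lies in (0, 1) by construction and all numbers are invariant under any
consistent rescaling of units.  The mapping is a named registry entry
("reference"); alternative formula sets can be registered and selected
without changing range classification or risk scoring, which consume values,
not formulas.

## Per-patient estimation

`GlucoseInsulinModel(record).fit(seed=...)` estimates parameters from the ten
measurements of one record.  Choices that matter:

* **Fixed quantities.** G_b and I_b are read off the basal sample; D comes
  from the protocol.  The structural closures k_gj, f_gi, k_xi and the
  hepatic rates k_lambda, gamma are held at population values by default.
  The hepatic pair is structurally confounded on OGTT data: above basal the
  endogenous-production closure makes k_xg and gamma act only through their
  sum, and k_lambda acts only below basal, which a 2-hour test barely
  samples.  Freeing both left a flat direction in the loss and 30–60% errors
  on tau and k_lg at numerically zero loss.
* **Free parameters** (default): k_js, tau, k_lg, eta, k_xg, k_xgi, beta,
  optimised on the natural-log scale inside bounds spanning the tabulated
  abnormal-to-healthy extent widened tenfold.
* **Loss.** Residuals on G and I at the sample times, normalised by the
  subject's basal values and by assumed assay CVs (3% glycemia, 7%
  insulinemia), so the data term is a chi-square when the noise assumption
  matches.
* **Ridge.** Five points per curve leave the 7-parameter problem sloppy;
  at 2% measurement noise an unregularised fit wandered 35–100% along the
  flat directions.  The objective therefore adds a weak log-normal ridge
  toward the population centres, sd 1.5 on the ln scale (a one-sigma band of
  roughly x/÷ 4.5).  This is a maximum-a-posteriori estimator with a very
  diffuse prior: it leaves well-identified directions essentially untouched
  (noiseless recovery of k_js, tau, k_xgi is exact to <0.1%) while keeping
  sloppy directions physiological.  `prior_sigma=None` disables it.  The
  reported `loss` is the full objective; `data_loss` is the curve term.
* **Multi-start.** Bounded trust-region-reflective least squares from 24
  Latin-hypercube starts in log-bound space plus the population centre
  (fewer starts are routinely sufficient; the test-suite protocols use 8
  and a 1-minute integration step).  Best run wins; all runs are retained;
  everything is deterministic given the seed.
* **Fast simulator.** Fitting uses closed-form gut kinetics (the S→J→L chain
  is linear) plus a fixed-step RK4 on (G, I); it agrees with the adaptive
  LSODA reference integration (rtol 1e-8, atol 1e-10) to ~1e-4 relative,
  far below measurement noise.

### Sensitivity protocols

* `repeat_fit_consistency` repeats the whole multi-start fit (default five
  seeds) and flags a parameter non-unique when its across-run CV exceeds 1%.
* `measurement_sensitivity` perturbs each of the ten measurements ±10%
  (20 warm-started refits per record) and labels a parameter
  measurement-sensitive when its maximum relative deviation exceeds 20%.
* `curve_shape_sensitivity` perturbs each parameter ±10% and reports the
  normalised L2 change of the basal-normalised (G, I) excursions; parameters
  above 5% are curve-shaping ("sensitive").  The 20%, 5% and 1% thresholds
  are configuration values reported alongside results, not claims of
  universal constants.

## Diagnostic ranges

Per-index positive, right-skewed cohort distributions are modelled as
two-parameter log-logistic laws (location 0), Q(p) = alpha (p/(1-p))^(1/beta),
fitted by maximum likelihood.  For each index the construction follows the
cohort-study recipe: a two-sample Kolmogorov–Smirnov test decides whether the
healthy and non-healthy cohorts differ (indices that do not are reported
"not discriminative"); the tail-occupancy comparison (fractions of each
cohort inside the healthy 90% left- and right-tail ranges, compared with a
pooled two-proportion statistic referred to Student t, as the recipe
specifies, rather than the more conventional z) fixes the shift direction;
the healthy central 90% interval bounds the healthy domain; and the crossing
point of the two fitted densities splits it into a normal and an undesirable
zone, with abnormal beyond the interval.  The Youden-optimal ROC threshold is
computed alongside as a diagnostic (the two closely coincide for
well-separated cohorts) but the equal-density point defines the boundary.
Values exactly on a boundary take the healthier category, since the printed
table shares endpoints between zones.  KS p-values get Benjamini–Hochberg
q-values across indices in the construction report; the raw p at alpha = 0.05
drives the discriminative decision, matching the original single-index
procedure.  Degenerate cases (identical densities, a crossing outside the
healthy interval, constant columns) yield non-discriminative rows rather than
errors.

The packaged reference table (14 rows: k_js, tau, Pi_S, k_lg, Pi_N, eta,
Pi_D, k_xgi, Pi_B, Pi_X, Pi_I, Pi_R, G_b, I_b) ships as a JSON resource on
the canonical scales.

## Risk model

The published fixed-coefficient logistic score

    z = 0.5310 eta + 0.1960 Pi_X + 1.2799 G_b + 0.0330 I_b
        - 0.0187 tau - 798.2059 k_xgi - 6.0103,   P = e^z / (1 + e^z)

is evaluated on the canonical table scales (the magnitude of the k_xgi
coefficient only makes sense against min⁻¹ pM⁻¹ values of order 10⁻⁴).
P ≥ 0.60 labels a subject non-healthy, boundary inclusive; the threshold is a
configuration value.  De-novo model building uses maximum-likelihood logistic
regression (Newton scoring, equivalent to IRLS) with Wald backward
elimination: repeatedly drop the non-intercept predictor with the largest
Wald p until all survive at alpha.  Design builders provide the pairwise-
interaction ("full") and squared-term ("quadratic") variants.  AIC = 2k - 2logL
is reported per model; selection direction is the caller's choice, with
smaller-is-better the package default.  Classifier metrics (sensitivity,
specificity, diagnostic odds ratio with a flagged Haldane 0.5-cell correction
when a confusion cell is empty, MCC) are computed at any threshold.

## Coordination

Pairwise Pearson correlations between per-subject indices are computed on the
log10 scale by default — the indices span orders of magnitude, and raw-scale
Pearson would be dominated by leverage points; `transform="raw"` restores the
untransformed version.  Pairs with |r| > 0.4 (strict) become weighted edges;
Louvain community detection (weighted modularity, resolution 1, seeded) groups
the coordinated subsystems, isolated nodes becoming singletons.  Cohort
graphs over the same node set are compared edge-by-edge, and a seeded
subject-label permutation test assesses whether the non-healthy cohort's
total correlation weight genuinely exceeds the healthy one's.

## Intervention assessment

A crossover study gives every subject a control OGTT and one OGTT per
pre-prandial dose.  Cohort-level dose effects are paired t-tests of each dose
arm against control (the design is within-subject; an unpaired mode exists
behind a flag), starred * p ≤ 0.1, ** p ≤ 0.05, *** p ≤ 0.01, **** p ≤ 0.001
on raw p-values, with BH-adjusted values available to callers.  Patient-level
trajectories track per-arm risk, dose-monotonicity, the best dose (minimum
risk, ties to the lowest dose) and diagnostic-category transitions.
Responders are subjects whose best-dose risk undercuts control by at least
0.05 (configurable; 0 makes any strict decrease count).

## Synthetic data

The generator is the package's test bed and defines its study conditions:

* **Healthy template.** Tabulated indices are drawn log-logistically with
  centres at the geometric midpoints of their healthy diagnostic ranges and
  shapes chosen so the central 90% mass spans those ranges; basal levels use
  the healthy cohort's reported medians (86.4 mg/dL, 4.32 uU/mL) and 95%
  intervals.  Untabulated rates (k_xg 0.015, gamma 0.04, beta 1.8) were
  chosen once so the population centre produces a textbook healthy OGTT
  (peak ~138 mg/dL at 30 min, return to ~94 mg/dL at 2 h, insulin peak
  ~20 uU/mL); structural closures (k_gj, k_xi) and the weakly identified
  k_lambda, f_gi are population constants, mirroring the fitting convention.
* **Non-healthy template.** Slower gastric emptying and transit (k_js, tau
  centred in their undesirable bands), weaker insulin-dependent uptake
  (k_xgi ~3e-6), stronger insulin-independent reliance (k_xg 0.025), reduced
  incretin potentiation and pancreatic responsiveness, and elevated basal
  levels (91.0 mg/dL, 8.30 uU/mL with the reported non-healthy spreads).  A
  shared latent factor (log-normal, loadings 0.2–0.5 on k_js, tau, k_xgi,
  beta) couples the subsystems, reproducing the stronger between-subsystem
  correlations of dysglycemic cohorts.
* **Noise.** Multiplicative mean-one log-normal on every measurement,
  default CV 3% (glycemia) and 7% (insulinemia) — typical routine assay
  precision.  Draws whose simulated glycemia leaves the physiological range
  (> 60 mM) are resampled, at most ten times.
* **Crossover studies.** Dose effects are multiplicative parameter shifts;
  every arm (control included) receives independent log-normal day-to-day
  jitter (default CV 10%) on the spread parameters, so paired contrasts see
  realistic within-subject variability.

What the generator does **not** emulate: assay drift and autocorrelated
errors, missing or mistimed samples, the joint (copula) structure of real
parameter distributions beyond the single latent factor, demographic
covariates, and any real cohort's exact marginals.  Passing recovery and
power checks on these synthetics therefore validates the machinery — the
estimator, the statistics, the pipeline plumbing — not the clinical accuracy
of any specific fitted value on real patients.

## Problem sizes and numerical choices

The validation protocols use sizes a reviewer can rerun casually: 20
subjects at 2% noise for recovery (8 optimisation starts, 1-minute RK4
step), 36-subject crossover studies over 20 seeds for dose-effect power
(on ground-truth parameters, isolating the statistical pipeline from
fitting cost), 250 subjects per cohort for range construction, and
10,000 draws for distribution-fit recovery.  Equal-density thresholds
are bracketed on a 4001-point grid between the medians and bisected to
1e-12; Youden thresholds enumerate all pooled midpoints in both
orientations with ties broken toward the healthy median; the reference
integrator is LSODA at rtol 1e-8 / atol 1e-10.

## Known limitations

* The ridge estimator trades a small bias for variance; parameters far
  outside the population priors (rare pathologies) will be shrunk toward
  them.  Turn the ridge off and raise the start count for such cases.
* k_xg/gamma and beta/f_gi/k_xi are only jointly identified from 5-point
  data; per-subject values of the fixed closures inherit population defaults.
* The two-proportion "t-test" for tail shifts is implemented as specified by
  the original recipe; a z-test or Fisher exact test would be the textbook
  choice at these sample sizes (the difference is negligible above ~50
  subjects).
* Range construction assumes one-sided cohort shifts; genuinely two-sided
  alternatives are flagged through the tail test returning the dominant side
  only.
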