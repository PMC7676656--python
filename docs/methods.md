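# Methods

## Model overview and assumptions

`tmbsim` treats TMB-based patient selection as the composition of three
probabilistic components: a histology-specific density Π(T) of true
(exome-wide) TMB, an assay operating characteristic Θ(T, τ, σ) giving the
probability of a TMB-high call, and a response curve Ψ(T) giving the
probability of treatment response. Every observable is an expectation over
Π: the treated fraction Z = E[Θ], the expected overall response rate
ORR = E[Ψ·Θ]/Z, and the panel-vs-truth agreement metrics.

Assumptions worth keeping in view:

* True TMB is a fixed per-patient scalar; the exome measurement is treated
  as its noiseless reference ("gold standard"). The idealized noiseless
  device (`PanelModel.noiseless()`) classifies by `T >= tau` exactly, with
  ties counted as high.
* Panel noise is content-agnostic: a panel is characterized only by its
  size L, not by which genes it tiles. Enrichment for driver/hotspot genes
  is captured in aggregate by a Poisson term.
* Response depends on T only — identical across histologies. Tissue
  dependence of outcomes then arises purely through Π and the assay noise,
  which is the phenomenon the toolkit exists to isolate.
* No modelling of sequencing depth, tumor purity, or caller error profiles
  beyond the constant noise floor; no survival-time modelling beyond the
  ORR scalar.

## The measurement model

For true burden T on a panel of size L (exome size L0 = 35.6 Mbp,
K = L/L0, exome count t = T·L0):

    t_obs = K·t + Normal(0, sigma) + Poisson(lambda_driver)
    sigma = C0 + sqrt(K·t)

then rounded to the nearest integer and clamped at zero; reported panel TMB
is `t_obs / L`. The sqrt term is the Gaussian approximation to binomial
subsampling of exome mutations onto the panel territory (each mutation
lands on-panel with probability K); the package carries the exact binomial
route (`thin_to_panel`) as an independent oracle and the two agree in mean
and variance within 10% whenever the expected panel count is ≥ 10.

Parameters, units, defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `panel_size` (L) | targeted territory | Mbp | required |
| `exome_size` (L0) | exome territory | Mbp | 35.6 |
| `c0` | panel-size-independent noise floor (e.g. germline-subtraction residue) | counts | 0.5 |
| `lambda_driver` | mean driver/hotspot count enriched regardless of size | counts | 1.0 |

The defaults are the constants recovered by the package's own grid search
on synthetic paired cohorts; both are tissue-invariant by construction.
Note that `lambda_driver` (measurement bias) and the response-curve rate
`rate_r` are unrelated parameters despite both being Poisson-flavored.

`selection_probability` evaluates Θ = P(t_obs/L > τ) analytically by
summing the Poisson mass (truncated at cumulative tail 1e-12) against the
Gaussian survival function with the half-integer continuity correction
implied by rounding; clamping cannot affect exceedance of any positive
count. A Monte-Carlo path replays the simulation and is used as the
independent check (agreement within 3 binomial standard errors at 10^6
draws in the suite). Noisy readouts use the strict ">" comparison; the
noiseless device uses ">=", so at very small panels the two conventions can
differ by one count — documented rather than hidden.

Two edge behaviors are properties of the model, not bugs:

* **Discreteness in τ.** Because counts are integers, Θ and hence Z are
  step functions of τ with jumps at multiples of 1/L. Threshold solvers
  need a smooth objective, so `PanelModel(discretize=False)` disables
  rounding/clamping; the solvers and the harmonization report are intended
  to run on this continuous variant (the discrete default would jump over a
  20% treated-fraction target by several points at L ≈ 1 Mbp).
* **Near-origin non-monotonicity.** σ grows as sqrt(K·t), so just above
  T = 0 the exceedance probability can *decrease* by up to ~1% when the
  threshold sits below the driver-count mean (widening noise momentarily
  outpaces the mean shift). At clinically relevant thresholds (≥ 6 mut/Mb,
  default noise) Θ is nondecreasing on any grid we test.

## Histology TMB densities

Per-histology Π(T) is a Gaussian kernel density with kernel mass below zero
reflected across the origin — negative burdens are impossible, and
reflection preserves total mass exactly where truncation would bias the
low-TMB histologies most. The default bandwidth is Silverman's robust rule
0.9·min(s, IQR/1.34)·n^(−1/5), chosen because TMB distributions are
strongly right-skewed and a non-robust scale over-smooths the body;
zero-spread data falls back to a fixed 0.5 mut/Mb bandwidth and flags the
result. The density lives on a grid of at least 2048 points (refined until
spacing ≤ bandwidth/4, capped at 65536) spanning [0, 1.5·max + 10·bw];
the CDF is the cumulative trapezoidal integral of the stored density, so
quantiles, tail masses, and all downstream quadrature are mutually
consistent. Sampling is inverse-CDF on that grid. Construction verifies
the raw integral equals 1 within 1e-6, then normalizes exactly.

Step discontinuities (the noiseless device, step/two-level response
curves, the truth indicator in the agreement metrics) get a node pair
inserted just below and at the jump before trapezoidal integration, which
is why identities like "matched noiseless selection ⇒ ORR = 1" and
"Ψ ≡ c ⇒ ORR = c" hold to machine precision rather than to grid
resolution.

## Synthetic cohort presets

The generator's presets are calibration stand-ins for the shapes of real
histology TMB distributions (all values mut/Mb):

* `luad_like` — 0.7·LogNormal(median 4, σ 0.9) + 0.3·LogNormal(median 12,
  σ 0.8): long right tail, exact mixture median ≈ 5.6 (documented band
  4.8–6.4), emulating lung adenocarcinoma.
* `lusc_like` — LogNormal(median 8.5, σ 0.55): higher median, tighter
  body, emulating squamous lung tumors (smoking-enriched).
* `low_tmb_like` — LogNormal(median 1.2, σ 0.7): breast/prostate-like
  low burden.
* `uniform` — U[0, 20] for analytic tests (top-20% cutoff exactly 16).

What the generator does *not* emulate: hypermutator subpopulations
(POLE/MSI spikes), inter-assay batch effects, tumor purity gradients, and
panel content specifics. Tests passing on these cohorts demonstrate the
internal consistency and the qualitative mechanisms of the model, not
calibration to any particular real cohort.

Paired WES/panel cohorts are produced by `attach_panel_readouts` (the full
noise model) or by `thin_to_panel` (pure binomial subsampling); the
regression-variability scan accepts either route so the two can be
compared.

## Fitting

* **Noise constants.** `fit_noise_params` grid-searches (C0, λ) by
  simulating 8 readout replicates per record (common random numbers across
  grid points) and scoring the pooled sample against the observed panel
  values; the default objective is the two-sample energy distance, which
  identifies C0 markedly better than matched-quantile RMSE (also
  available). λ is recovered exactly on synthetic data at n = 2000; C0 to
  within one grid step (exactly at n ≈ 5000) — its effect on σ is second
  order whenever K·t is large.
* **Response curve.** `fit_gamma_response` minimizes the ordinary
  least-squares error between binary responses and P(n, r·T) over a small
  integer shape grid ({1, 2, 3} by default, reading the shape as the number
  of neoepitopes needed for activation), with bounded scalar minimization
  of the rate (tolerance 1e-8). OLS on binary outcomes is used
  deliberately — it is the fitting strategy the model calculus is built
  around — rather than logistic likelihood.
* **Rate calibration.** `calibrate_gamma_rate` inverts
  P(n, r·τ) = target in closed form via `gammaincinv` at the histology's
  top-fraction cutoff (e.g. 50% response at the top-20% threshold);
  round-trip verified to 1e-6.

## Threshold solvers and the harmonization trade-off

`threshold_for_fraction` (Z monotone nonincreasing in τ) and
`threshold_for_orr` (ORR nondecreasing in τ for nondecreasing Ψ) use
predicate bisection to the *leftmost* satisfying threshold — plateaus, such
as a perfect step response on a noiseless device, resolve to their left
edge — with a 1e-3 round-trip tolerance in probability space and solver
errors that report the attainable range. `harmonization_tradeoff` computes
both threshold pairs for two assays and cross-evaluates them; the headline
flag `harmonizable_in_both` is true only when matching the treated
fraction also matches the ORR within tolerance, which holds for identical
devices and fails generically once the noise differs (on the default
configuration — noiseless exome vs a 1 Mbp panel, gamma shape-1 response
calibrated to 50% at the top 20% — the fraction-matched ORR gap is ≈ 2
points and the ORR-matched treated-fraction gap ≈ 4 points).

The Cramér two-sample test uses the Baringhaus–Franz energy form
nm/(n+m)·(mean|a−b| − mean|a−a′|/2 − mean|b−b′|/2) with permutation
p-values (1 + exceedances)/(n_perm + 1); the statistic is cross-checked in
the suite against an independent energy-distance computation.

## Classification metrics

Truth is the noiseless exome call at the clinical threshold; the test call
is a simulated panel readout at (possibly) a different threshold, so
harmonized cutoffs can be scored against the original intent. The default
estimator is Monte-Carlo over T ~ Π; `method="quadrature"` computes the
expected confusion table exactly as Π·Θ integrals over the two truth
strata (possible because truth is deterministic given T) and is what the
deterministic directional assertions use. Metrics with an empty
denominator stratum are reported as NaN, never coerced.

## Numerical choices at a glance

* Quadrature: trapezoid on the density grid, breakpoint node insertion at
  integrand jumps; ratio identities exact by construction.
* Poisson convolution truncated at cumulative mass 1 − 1e-12.
* Bisection: 200 iterations / 1e-12 relative bracket floor; probability
  tolerance 1e-3 (solvers), 1e-6 (rate calibration).
* Degenerate inputs: zero-variance regressors, all-identical responses,
  empty selections, and sub-minimum sample sizes raise typed errors
  (`DegenerateDataError`, `ZeroSelectionError`, `InsufficientDataError`)
  rather than returning sentinel values; grid evaluation records per-cell
  errors in an `error` column instead of aborting.

## Problem sizes used in the shipped checks

Cohorts of 2000–5000 synthetic samples for density fits and parameter
recovery; 98 paired samples for the NSCLC-like regression concordance
check (R² ≈ 0.84–0.90 across noise seeds, model re-simulation within
0.03); 23 histologies × 300 samples × 150 bootstrap replicates for the
slope-variability comparison (model-vs-thinning profile correlation
≈ 0.88); 10^5–10^6 draws where Monte-Carlo estimates are compared with
analytic values. These sizes were chosen so the full suite completes in
well under a minute on one core while keeping Monte-Carlo error far inside
every asserted tolerance.

## Known limitations

* The OPA "plateau" near 1 Mbp is threshold- and histology-dependent: it
  holds at per-histology top-20% cutoffs on heavy-tailed distributions,
  but at fixed 6–10 mut/Mb cutoffs (and for low-TMB histologies at their
  own top-20% cutoff) agreement keeps improving measurably beyond 2 Mbp —
  one more reason low-TMB indications favor large panels.
* C0 is weakly identified from marginal readout distributions; fits should
  be read with a one-grid-step uncertainty.
* The treated-fraction inflation of small panels depends on where the
  threshold sits in the density (≈ 12% relative for the LUAD-like preset
  at 10 mut/Mb, ≈ 6% at 6 mut/Mb).
* Exact ORR decimals inherit the unspecifiable parts of any KDE choice
  (kernel, bandwidth, boundary rule); directional conclusions are robust
  to these, point values carry that uncertainty.
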