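# Methods

## The problem and the model

Soluble markers in pleural effusions separate malignant mesothelioma
from metastatic carcinoma and benign disease well enough that the
strongest marker, hyaluronan, induces quasi-complete separation in a
joint logistic regression: the maximum-likelihood slope diverges and no
second marker can enter the model. The two-step construction removes
the separating region *before* regressing:

1. **Gates.** For hyaluronan (HA) and N-ERC/mesothelin, a cut-off equal
   to the largest training non-mesothelioma value is applied with the
   rule *value > cut-off → positive*. Each gate has training
   specificity exactly 1 by construction; values exactly at the cut-off
   go on to step 2 (strict inequality keeps the training-negative
   maximum below the gate).
2. **Sub-gate logistic regression.** On samples at or below both gates,
   mesothelioma status is regressed on (log10 HA, log10 N-ERC) by
   maximum likelihood (Newton/IRLS via statsmodels; covariance = inverse
   observed information). The predicted risk is
   `expit(b0 + b_ha·log10 HA + b_nerc·log10 NERC)`; a sub-gate sample is
   positive when risk exceeds the operating threshold.

The reference coefficient set shipped as `reference_model()` is gates
120 µg UA/mL and 1050 ng/mL, b0 = −12.42, b_ha = 4.71, b_nerc = 2.71,
threshold 0.9. The printed form of this risk equation in the source
literature is internally inconsistent (it renders unambiguously benign
profiles near-certain positives under a literal reading); the standard
logistic risk above is the unique sign convention under which those
cut-offs and threshold behave sensibly, and is what this package
implements throughout.

Conventions adopted where the original description is silent:

* gate-route predictions report risk 1.0 with a `route` flag
  (`gate_ha` / `gate_nerc` / `logistic`), the HA gate being checked
  first — the label order is documentation, the outcome is
  order-independent;
* assay zeros (below detection limit) become 0.1 before log10, so
  `log_transform(0) == -1`; the images of 0 and 0.1 deliberately
  collide;
* marker units are carried as metadata and never converted; each gate
  is quoted in its marker's own assay units;
* the operating threshold is a parameter (0.9 default, 0.81 the
  external-validation point), never hard-coded;
* validation applies the frozen generation-fit model; the CLI separates
  `fit-two-step` from `predict` so no silent refit can occur.

## Statistical toolkit

**Univariate table.** Per marker: logistic slope on log10 concentration;
interquartile odds ratio `exp(beta·(Q3−Q1))` with Wald CI scaled by the
same IQR (quartiles by linear interpolation over the whole modelling
cohort); one-tailed Wald p (direction OR > 1); optimal cut-point
maximising `min(sensitivity, specificity)` over all candidate thresholds
(midpoints of consecutive distinct values plus ±∞), ties broken by
higher Youden index then lower threshold; positive likelihood ratio
`se/(1−sp)` with the standard log-method CI, flagged infinite at
specificity 1. No multiple-testing correction is applied; the marker
count is reported instead.

**Marker selection.** Forward stepwise AIC from the intercept-only
model inside outcome-stratified bootstrap resamples (both classes
guaranteed in every resample; one seed drives everything). Candidate
fits are evaluated at their achieved likelihood even when a resample
separates: a damped IRLS with a capped linear predictor (|η| ≤ 35)
converges monotonically to the boundary value, where the deviance is
≈ 0 and AIC = 2k, so nothing further can enter — the behaviour of
glm-based stepwise selection, and the reason a strongly separating
marker is selected rather than discarded. Rejecting separated fits
here would paradoxically punish the strongest markers. Plain AIC is
used (not AICc); forward steps only, no backward drops.

A structural note for interpreting selection frequencies: for a marker
with no conditional signal, entry requires a chi-square(1) likelihood
gain above 2, and averaging that event over both cohort and resample
randomness yields a noise baseline of roughly 0.2–0.35 — bootstrap
stepwise AIC never drives genuinely uninformative markers to 0%.
Frequencies should therefore be read as a ranking (signal markers near
1, noise markers near the baseline), not as exact inclusion
probabilities.

**Separation detection elsewhere.** Outside selection, `fit_logistic`
raises a `SeparationError` on perfect prediction, or when a fitted
|slope| exceeds 50 per log10 unit *and* the optimizer failed to
converge (diverging estimates). A converged, finite MLE with a steep
slope — e.g. a sub-gate subset containing a single event — is
legitimate and accepted.

**Evaluation.** Empirical ROC with trapezoidal AUC (equal to the
tie-corrected Mann–Whitney statistic); sensitivity at a target
specificity by exhaustive threshold enumeration; categorical NRI on the
two models' binary calls (up = negative→positive), continuous NRI on
any risk movement; IDI defined exactly as the difference of
discrimination slopes (mean risk in events minus mean risk in
non-events); all CIs by outcome-stratified bootstrap percentile (2000
resamples by default, seeded). Calibration: risk-decile bins,
Spiegelhalter's z `Σ(y−p)(1−2p)/√Σ(1−2p)²p(1−p)` with two-sided normal
p, Brier score on the unclipped risks, Nagelkerke R² from Bernoulli
likelihoods against the prevalence-only null. Gate-route risks of
exactly 1 are clipped inward by 1e-9 only inside the likelihood-based
calibration statistics (the clip count is reported), never in
classification.

## Synthetic study conditions

The generator draws each diagnostic group from a multivariate normal on
the log10 scale and exponentiates (multivariate lognormal), then
censors below per-marker detection limits to 0 — the same zero
mechanism the ELISAs produce. Group sizes follow the two source
referral-centre datasets: 46/49/95 (mesothelioma / other cancer /
benign) for model generation, 48/166/161 for validation. One seed
drives the whole cohort; the stream splits deterministically per group.

The default locations and spreads are synthetic stand-ins calibrated
once, by Monte-Carlo, to the operating characteristics the source data
showed rather than to any tabulated concentrations:

* mesothelioma crosses the 120 µg UA/mL HA gate in ≈ 51% of cases and
  the 1050 ng/mL N-ERC gate in ≈ 43%; non-mesothelioma crosses either
  gate with probability ~1e-4–6e-4;
* HA and N-ERC share a log-scale R² of ≈ 0.35 within each group;
* C-ERC/mesothelin is generated as a fixed linear function of log
  N-ERC plus noise, shared across groups — marginally informative (the
  two fragments derive from one precursor) but conditionally null given
  N-ERC, so it can never improve a model that already contains N-ERC;
* osteopontin, syndecan-1, syndecan-2 and thioredoxin carry no group
  signal; syndecan-2's detection limit sits near its median, giving the
  large below-detection fraction typical of that assay;
* resulting whole-cohort behaviour: AUC ≈ 0.99, two-step sensitivity at
  training specificity 1 ≈ 0.75–0.87 versus ≈ 0.45–0.6 for either gate
  alone.

What the generator does **not** emulate: measurement error and assay
drift, missing markers from insufficient material (supported by the
data model, not simulated by default), secular case-mix differences
between centres, and any mesothelioma subtype structure (a single
lognormal component per group, so the low-marker sarcomatoid-like tail
is thinner than in real cohorts). Passing tests on synthetic cohorts
demonstrate the statistical machinery and the structural claims (gate
specificity, superiority of the combination, calibration of the
diagnostics), not clinical performance on real effusions.

## Numerical choices and problem sizes

Logistic fits: Newton iterations, tolerance 1e-10, 100 iterations.
Selection IRLS: |η| capped at 35, step-halving on likelihood decrease,
tiny (1e-12) ridge in the weighted normal equations only. Quartiles and
percentile CIs: linear interpolation. ROC points from distinct observed
thresholds. Degenerate inputs (constant predictors, zero IQR, one-class
samples, all-0.5 forecasts) raise typed errors rather than returning
NaNs.

Test-suite problem sizes: parameter recovery uses 100 replicates of
n = 2000 sub-gate simulations; the calibration null uses 500 cohorts of
n = 300; selection behaviour uses study-sized cohorts (n = 190) with
200 bootstrap resamples; oracle equivalence uses 200 random instances
of n ≤ 50. The acceptance script runs study-sized cohorts end to end
plus one large (n = 20000 per group) draw to measure the generator's
HA–N-ERC coupling.
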