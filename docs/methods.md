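# Methods

## The experiment

`bootce` studies how the evidential value of a two-arm randomised trial
degrades — or does not — as its sample size shrinks, under two different
inferential standards applied to the *same* resampled data:

1. **Hypothesis testing.** A Welch two-sample t-test of the 6-month LDL
   cholesterol difference at two-sided α = 0.05.
2. **Decision making.** A cost-effectiveness analysis: the subsample's
   effect estimates on LDL, systolic blood pressure and smoking are mapped
   to a relative risk of acute cardiovascular events, extrapolated by a
   Markov cohort model, and classified on the cost-effectiveness plane.

One fixed 710-patient dataset is generated, then bootstrapped (with
replacement, unstratified by arm) at sizes 100, 200, …, 700 with 500
replicates per size. Per-size summaries report the proportion of replicates
significant and the proportion in which the programme would be adopted.

## Synthetic trial generator

No patient-level data from the motivating trial are available, so the
generator emulates it. Per-arm normal draws for LDL, SBP and BMI and
Bernoulli draws for smoking are calibrated so the *configured* between-arm
effects equal the published 6-month results: ΔLDL = −5 mg/dL,
ΔSBP = −8 mmHg, ΔBMI = −1.3 kg/m², smoking prevalence ratio 0.61.

Two anchors are derived rather than printed:

* **LDL SD = 30.5 mg/dL** inverts the published 95% CI half-width of the LDL
  difference: 4.5 = 1.96 · σ · √(2/355) ⇒ σ ≈ 30.5.
* **Design SD = 18.4 mg/dL** (inference module) inverts the sample-size
  formula against the published design: d = 4.5 mg/dL, α = 0.05, power 0.90,
  704 participants ⇒ σ ≈ 18.4. The planning SD and the realised SD are kept
  deliberately distinct so that both published anchors (the 704-participant
  design and the CI width) hold simultaneously.

**Moment matching.** After generation, each arm's LDL values are affinely
rescaled so the realised arm means and SDs equal the configured targets
exactly. The grid experiment resamples a single fixed dataset, and without
this step the headline LDL difference would be hostage to one random draw.
SBP, BMI and smoking are left stochastic, so their realised full-sample
effects vary around the configured values from seed to seed.

**Placeholders.** The control-arm baselines are not published and are set to
plausible values for a secondary-prevention coronary population: LDL
100 mg/dL, SBP 135 mmHg (SD 15 mmHg, a typical 6-month SD in treated CHD
cohorts), BMI 29 kg/m² (SD 5), control smoking prevalence 0.43 (the
published prevalence ratio then implies ≈ 0.26 in the intervention arm).
Odd totals give the control arm the extra patient.

**Null construction.** `make_null_trial` permutes the arm labels across
patients and resamples the records with replacement to the original size, so
the arm label carries no information about any outcome. Economic analyses of
null data set `EconParams.null_effect = True`, which forces the combined
relative risk to exactly 1: the cohort pays the programme cost and receives
nothing.

## Inference

The Welch (unequal-variance) t-test is used rather than the pooled-variance
test; at these sample sizes the difference is negligible, and Welch is the
robust default. Replicates in which the unstratified bootstrap leaves an arm
with fewer than two patients are flagged degenerate and their p-value
recorded as missing — replicate counts stay exact at 500 rather than
redrawing. The smoking endpoint uses a prevalence ratio with a log-scale
Wald interval. Power and required sample size use the standard
normal-approximation formulae; per-arm sizes are rounded up.

## Economic model

The published companion economic evaluation is proprietary in its details;
this package adopts the simplest structure honouring its described
ingredients. All constants are configuration-driven.

**Risk mapping.** The combined relative risk of acute events is log-linear
in the continuous risk-factor changes, with a prevalence-proportional
smoking multiplier:

RR = exp(β_ldl · ΔLDL + β_sbp · ΔSBP) · RR_quit^(−Δprev / prev₀)

Defaults: β_ldl = 0.0064 per mg/dL (≈ 22% fewer major vascular events per
1 mmol/L lower LDL), β_sbp = 0.022 per mmHg (≈ 20% per 10 mmHg),
RR_quit = 0.64 (the canonical post-event smoking-cessation figure),
prev₀ = 0.43. The exponent −Δprev/prev₀ is the fraction of baseline smokers
the intervention removed, so full cessation applies the full quit RR and a
prevalence *reduction* reduces risk. The baseline prevalence is a model
constant, like the β coefficients — external epidemiological inputs, not
per-resample estimates. BMI is measured in the trial but excluded from the
pathway, which uses only LDL, SBP and smoking. The `null_effect` switch
short-circuits the mapping to RR = 1 exactly.

**Markov cohort model.** Three states — event-free, post-event, dead —
on annual cycles. Event-free patients suffer an acute event with probability
(baseline rate × RR), fatal with the case-fatality probability, and die of
other causes at the background rate; post-event patients face the same
background mortality. Utilities (0.85 event-free, 0.70 post-event) and the
post-event care cost accrue on start-of-cycle occupancy with **no half-cycle
correction** (a simplicity choice; the comparison between arms is
insensitive to it); each event costs $15,000; discounting is 5%/year over a
15-year horizon. Defaults for the event rate (0.04/yr), case fatality
(0.15) and background mortality (0.02/yr) are placeholders in the range of
secondary-prevention cohorts. A relative risk that would push the annual
event probability above 1 is an error, not a clamp.

**Cohort outcomes.** ΔCost = N·(per-patient cost difference) + N·$30 and
ΔQALY = N·(per-patient QALY difference) for the N = 50,000 cohort. The $30
programme cost per patient is derived from the published cohort figure of
about $1.5 M for 50,000 patients.

Because the true magnitudes of the companion model are unknown, the QALY and
cost *scales* here are not comparable to the published figures; only the
structure of the conclusion (all-dominant adoption in the calibrated
scenario, certain rejection in the null scenario, and the $1.5 M programme
cost) is. The placeholder constants were chosen once, from the
secondary-prevention literature, under the calibration requirement that the
package reproduce that qualitative behaviour.

## Resampling engine

Each (size, replicate) cell owns an independent RNG substream keyed on
(seed, size, replicate) via numpy's `SeedSequence`, so results are exactly
reproducible and invariant to execution order. The bootstrap is unstratified
— patients, not arms, were resampled — so small subsamples can have
unbalanced or even degenerate arms; such replicates are flagged, never
redrawn. Per-replicate effects fed to the economic model are the resample's
own estimates, with no shrinkage.

## Decision rules

Exact zeros on the CE plane preserve the status quo: adopt only on a strict
improvement in at least one dimension with no worsening in the other
(ΔQALY = 0 with ΔCost < 0 adopts; ΔCost = 0 with ΔQALY > 0 adopts; both
zero rejects). Points on the ICER boundary adopt (weak preference). The
willingness-to-pay threshold λ is disabled by default — in both study
scenarios essentially all mass is in the dominant/dominated quadrants where
it never binds; `classify` raises an explicit error for a mixed-quadrant
point without λ, while the per-size rollup counts such points as
not-cost-effective (a decision maker without a stated λ keeps the status
quo). Quantiles everywhere, including the Tukey boxplot statistics
(whiskers at 1.5 IQR, outliers beyond), use linear interpolation (type 7).

## What passing tests do and do not show

The generator reproduces the published *summary* statistics and CI widths,
not the real trial's covariance structure, baseline measurements or missing
data. Results therefore demonstrate the methodological contrast — that
decision-analytic inference stabilises at far smaller samples than
significance testing, and that a null effect is recognised at any size —
under study conditions faithful to the published effects, not a reanalysis
of the original patient data. Problem sizes in the test suite match the
study (710 patients, 7 × 500 grid, 50,000-patient cohort); heavier
Monte-Carlo checks (null p-value uniformity, inclusion-count calibration)
use 500–2,000 replicates, enough to bind at the stated 3-SE tolerances.

## Known limitations

* One event type: MI and stroke are not distinguished by cost or utility.
* No second-order (parameter) uncertainty: variation across replicates is
  bootstrap-induced only.
* No cost-effectiveness acceptability curves or value-of-information
  analysis; the grid experiment answers a simpler, starker question.
* The normal-approximation power formula ignores the t-distribution
  correction; at n ≥ 100 per arm the error is negligible.
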