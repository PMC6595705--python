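# Methods

This note documents the models, defaults and design choices behind
`gepreport`, and what the synthetic-data experiments do and do not show.

## Synthetic cohort generator

The generator (`gepreport.simulate`) draws, per patient: identity labels
(sex, heavy-chain isotype IgA/IgG/IgD/none, light-chain type κ/λ), binary
cytogenetic and expression risk factors, a continuous proliferation axis,
ISS-consistent clinical chemistry, and right-censored survival times for two
endpoints (PFS, OS). Expression is a features × samples matrix of log2
intensities: every feature has a baseline drawn from N(7, 1), group-specific
features are shifted by a configured log2 effect in the corresponding group,
and i.i.d. Gaussian noise (SD 0.6 by default) is added everywhere.

Key structural choices:

* **Identity markers.** 4 Y-linked and 2 X-linked surrogates for sex, two
  marker genes per immunoglobulin class. Male samples lose their Y-marker
  signal with probability 0.05 by default, emulating the frequent somatic
  loss of the Y chromosome in myeloma cells — the biological reason sex
  prediction from tumour expression has a male-specific error while
  "female" is predicted without error.
* **Translocation spike genes.** t(4;14)-positive samples carry three
  up-shifted spike features; the expression-based t(4;14) predictor is
  trained on exactly these.
* **Bimodal targets.** A target gene is background in "absent" samples and
  background + 3 log2 units in "expressed" samples; the expressed fraction
  is the configured prevalence (defaults 43.2% *AURKA*, 33.1% *IGF1R*, 11%
  *FGFR3*).
* **Risk signatures.** Binary latent high-risk states (24.8% GEP70-like,
  23.2% IFM15-like) shift dedicated up- (and for GEP70, down-) gene sets; a
  latent standard-normal proliferation score loads on ten proliferation
  genes, with GPI strata defined as fixed quantile bands of the latent law
  (7.9% high / 41.9% medium / 50.2% low). Risk factors are drawn
  independently of each other.
* **Clinical covariates.** ISS stage is drawn first (default frequencies
  0.36/0.30/0.34) and β2-microglobulin/albumin are then drawn uniformly
  from ranges consistent with that stage; LDH exceeds its upper limit of
  normal (250 U/L) with probability 0.15. The source material gives no
  distributional detail for these covariates, so the marginals are chosen
  for plausibility, not fidelity.
* **Survival.** Weibull baseline hazards (PFS: shape 1.2, scale 55 months;
  OS: shape 1.1, scale 140 months) with log-linear covariate effects
  (log-HRs 0.25–0.7 per risk factor). The linear predictor is centred at
  its configured expectation, so the scale parameter describes a
  cohort-average patient. Censoring is independent and exponential; the
  exponential rate is solved by bisection so the expected censored fraction
  equals the configured rate (25% PFS, 45% OS), which keeps the IPCW
  assumptions used downstream exactly satisfied.

What the generator does **not** emulate: correlation between risk factors
(in real cohorts proliferation, high-risk signatures and adverse
cytogenetics co-occur), probe-level array artifacts, batch effects,
non-proportional hazards, or informative censoring. Tests passing on these
cohorts therefore validate the statistical machinery and its contracts, not
clinical performance on real data.

## Quality control

The seven per-sample metrics (median intensity, dynamic range p99−p1,
fraction of features above a 4.0 log2 background, Spearman correlation to
the cohort median profile, identity-marker intensity, signature-feature
coverage, missing-value fraction) are this package's own surrogate panel:
the upstream framework's quality parameters are array-specific and not
enumerable from the source material, so the panel preserves the contract —
seven metrics, each with a nested minor band and major band, exclusion iff
any major failure — with configurable thresholds. Defaults are set so a
clean default-parameter synthetic cohort passes everything. An incomputable
metric (e.g. correlation with a single sample) degrades to a minor warning
rather than an error.

## Nearest-shrunken-centroid classification

Identity control and the t(4;14) call use the standard shrunken-centroid
model: per-feature class deviations `d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0))`
with `m_k = sqrt(1/n_k − 1/n)` (the variance factor of the class-mean minus
overall-mean contrast), soft-thresholded at Δ; classification minimises the
standardised distance to the shrunken centroid minus `2 log π_k`, with
posteriors from softmax(−δ/2). `s0` is the median pooled SD (the usual
stabiliser). When Δ is not supplied it is selected by stratified
cross-validation over a grid of observed deviation magnitudes with ties
broken toward the larger Δ (sparser model). A Δ so large that no feature
survives is valid and yields a priors-only classifier. Interchange
flagging — a sample mismatching recorded labels on ≥ 2 of 3 axes — is this
package's operational rule; the threshold is configurable.

## Signature scores, strata and presence calls

Scores are `mean(up-genes)` or `mean(up) − mean(down)` on log2 data.
Thresholds may be fixed values or training-cohort quantiles; quantile cuts
are computed once on the named training cohort and frozen into the results
(prospective-use contract: new samples are scored against stored cuts). The
shipped GEP70-like (upper-quartile cut), IFM15-like (76.8% cut) and GPI
(49.8%/92.1% cuts) definitions are placeholder gene lists keyed to the
synthetic feature panel — the published signatures' gene lists and
coefficients live in their original reports and are deliberately not
reproduced; the scoring machinery, not the gene lists, is the contract.

Presence/absence calls default to a cohort-level two-component Gaussian
mixture with the higher-mean component read as "expressed" (posterior
> 0.5). Degenerate fits — Ashman's D = √2·|μ₁−μ₀|/√(σ₀²+σ₁²) below 2.5 (a
unimodal Gaussian split in half scores ≈ 2.2) or a component weight below
2% — fall back to a fixed threshold with a warning. A fixed-threshold
method is available explicitly.

## Staging and metascore

ISS and revised ISS follow their standard rules (stated in the module
docstring). Unknown cytogenetics are resolved both ways; when the two
resolutions disagree the rISS stage is reported unknown with an
explanation, otherwise the unambiguous stage is used.

The metascore is an additive point system over ISS stage, del17p13,
t(4;14), GEP70/IFM15 strata, GPI stratum and the two target calls. The
original clinical weighting is defined externally and not printed in the
source material, so the shipped `MetascoreConfig` (version `hm-like-1.0`)
is this package's own calibration: ISS I/II/III → 0/1/2 points, each
adverse cytogenetic or high-risk signature stratum → +1, each expressed
target (*AURKA*, *IGF1R*) → +0.5, cut points low ≤ 0.5 and high ≥ 4.0.
The half-point target weights are necessary as well as interpretable
(the targets are the weakest prognostic factors in the set): with
all-integer weights the exact distribution of the total jumps from 5.6% to
24.5% cumulative probability around any candidate low cut, so no integer
weighting can reproduce a ~12.7% low-risk fraction. With the defaults, the
exact low/medium/high split under the generator's factor prevalences is
12.6/77.4/10.0%, computed by convolution of the independent factor
distributions before any sampling. Missing factors contribute 0 points and
are listed in the result; a strict mode raises instead (complete-case
analysis).

## Survival statistics

Kaplan–Meier estimates, the G-rho weighted log-rank family (w(t) = Ŝ(t⁻)^ρ,
ρ = 0 default) and Cox fits (Efron tie handling, Wald intervals) are
delegated to lifelines; Greenwood variances are accumulated from the event
table. The IPCW Brier score is implemented in-package with the censoring
distribution estimated by reversed-role Kaplan–Meier (at tied times events
precede censorings) and left limits Ĝ(T⁻) by predecessor-time lookup; grid
points where Ĝ reaches zero are truncated with a warning. The IBS is the
trapezoid time-average of BS(t) over the grid span.

Model comparison uses subsampling cross-validation: each replicate draws a
fixed-size training set without replacement (defaults mirror the design of
the trial analysis: 301 training subjects, 150 replicates, 73-month
horizon), refits every model (Cox on the model's stratum indicators;
covariate-free Kaplan–Meier as Reference), and evaluates the Brier curve on
the left-out complement; replicates where any model fails to fit are
dropped for all models to keep the design paired. Per-replicate integrated
errors are compared by a paired Wilcoxon signed-rank test (exact for ≤ 25
replicates), a documented surrogate for the cross-validated comparison test
the trial analysis cites — output metadata labels it as such. The test
suite and acceptance script run 30–150 replicates depending on the check;
the evaluation CLI default is 30.

## Numerical and degenerate-input choices

* Percentages are rounded half-up to one decimal everywhere they are
  reported (matching clinical-report style); `round()`'s banker's rounding
  is deliberately avoided.
* Cox convergence follows lifelines' criteria; constant covariates and
  separations are surfaced as `CoxFitError` before/at fit time.
* A cohort with no events yields S(t) ≡ 1 and "median not reached";
  all-censored-at-zero inputs are flagged as degenerate, not an error.
* Cohort CSV/TSV round trips use `float_precision="round_trip"` so stored
  values reproduce to the last ulp.
* All pipeline randomness derives from one seed via
  `numpy.random.SeedSequence(seed).spawn`; sub-seeds stay below 2³¹.

## Known limitations

Placeholder gene lists (see above); independence of generated risk factors;
uncorrelated noise; the metascore weighting is a calibration, not the
externally validated clinical weight table; the paired signed-rank
comparison is a surrogate for the cited cross-validated test; no competing
risks, time-dependent covariates or restricted-mean summaries.
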