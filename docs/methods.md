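# Methods

## Problem and model

Bulk tumor expression cohorts mix samples in which the p53 transcriptional
program is intact with samples in which it is impaired — by TP53 mutation or
by lesions downstream of p53. When a gene pair's correlation depends on that
program (ZNF224 and p21/CDKN1A being the motivating case), the impaired
subset dilutes the correlation measured on the whole cohort. `p53eff`
(1) scores each tumor sample's p53 effectiveness against a nontumor
calibration, (2) removes low-scoring samples, and (3) quantifies how much
robust pair correlations recover.

The calibration model is deliberately minimal. In log2 expression space each
panel target g is assumed linear in the regulator across nontumor samples:

    target_g = a_g + b_g * p53 + eps_g,   eps_g ~ N(0, sigma_g^2)

fit by ordinary least squares (a quadratic form, `form="quadratic"`, is
available behind the same interface; a straight line in log-log space is the
minimal relationship consistent with per-sample profiles being summarized by
a line). For a scored sample with regulator level p, each target's expected
value is a_g + b_g * p, and the sample's responsiveness is the OLS slope of
its measured values against those expected values across the panel. A free
intercept is included by default so a per-sample global offset (array
scaling, contamination) does not masquerade as attenuation; a
`through_origin` option removes it. Slopes in [0.9, 1.1] (inclusive) are
`normal_like`, below 0.9 `impaired`, above 1.1 `above_range`. Only
`impaired` samples are removed by filtering: `above_range` samples show
over-response, not loss of the program.

Assumptions worth keeping in mind: nontumor samples of the same series are
an adequate proxy for "functional p53"; the targets' responses are
approximately linear over the observed regulator range; and impairment acts
multiplicatively on the whole expected profile rather than on a
gene-specific subset. Violations bias the slope toward 1 (partial-panel
impairment) or add variance (nonlinearity).

## Robust correlation

bicor median-centers each vector and applies Tukey biweights with the
conventional tuning constant 9 on the unscaled MAD (median of absolute
deviations, no 1.4826 consistency factor). With fewer than half the points
displaced, a gross outlier gets weight zero and cannot dominate the
estimate. When MAD = 0 (more than half the values tied) the robust scale is
undefined; that vector falls back to uniform weights around its mean
(Pearson-style centering) and results carry a `fallback` flag. Correlations
are not capped by a maximum-outlier-proportion parameter.

Significance uses the standard correlation t-transform,
t = r sqrt(n-2)/sqrt(1-r^2) with n-2 df, two-sided; |r| = 1 returns the
smallest positive double instead of dividing by zero. The transform is exact
for Pearson under Gaussian nulls and an approximation for bicor; its
empirical type-I error at alpha = 0.05, n = 50 measures ~0.04-0.05 (the
acceptance script recomputes this). On clean Gaussian data bicor and Pearson
track each other with mean absolute difference well under 0.02 at n = 500;
individual draws can differ by up to ~0.04 from estimator sampling
variability alone, which the property test's bounds reflect.

A second, deliberately naive implementation (`p53eff.reference`) transcribes
the weight formula term by term in pure Python and serves as the in-repo
oracle: the optimized path must agree with it to 1e-12.

## Synthetic cohorts

The generator produces the structure the inference assumes, so every stage
is testable without downloads. Defaults define the study conditions: 40
nontumor + 100 tumor samples; 59 targets; regulator ~ N(8, 1) log2 units
(typical RMA intensity scale); per-target intercepts a_g ~ U(1, 4) and
slopes b_g ~ U(0.4, 1.2); residual noise sd 0.3 log2 units (mid-range for
well-expressed microarray genes); impaired fraction 0.2 with attenuation
lambda ~ U(0.3, 0.7). Impaired samples are assigned by exact count —
round(fraction * n_tumor) taken from one seeded shuffle — so tests can
assert counts exactly. Nontumor samples are always functional.

Impairment scales the whole modeled target profile:

    target_g = lambda_s * (a_g + b_g * reg_s) + eps

so in the noise-free limit a sample's measured values are exactly
lambda * expected and the recovered OLS slope equals the generating lambda.
(Attenuating only the coupling term b_g * reg would leave the dispersed
intercepts unattenuated and make the measured-vs-expected slope a biased,
sample-composition-dependent function of lambda; the full-profile form is
also what per-sample low-slope lines in observed-vs-expected space depict.)
Two anchor genes emulate the ZNF224/p21 pair: anchor1 = c0 + c1*reg + eps
with (c0, c1) = (2.0, 0.8), and anchor2 = d0 + lambda_s*(d1*reg +
d2*anchor1) + eps with (d0, d1, d2) = (1.0, 0.4, 0.5) — the anchor2
couplings, but not its baseline, are attenuated in impaired samples, which
is what makes filtering restore the anchor correlation.

What the generator does **not** emulate: probe-level effects and saturation,
batch effects, heteroscedastic per-gene noise (available via
`per_gene_noise_sd` but off by default), correlated residuals among targets,
and partial impairment of gene subsets. Passing tests therefore demonstrate
the statistical machinery is correct under the assumed model, not that real
cohorts satisfy the model.

## Numerical and design choices

- OLS is computed in closed form (centered cross-products); the quadratic
  form uses `numpy.polyfit`. Residual sd uses dof = n - number of
  parameters; r^2 is clipped to [0, 1] and defined as 0 for a constant
  response.
- Class boundaries 0.9 and 1.1 are inclusive into `normal_like`.
- All panel genes with a fitted model and a finite measured value enter a
  sample's slope fit; an optional `min_r_squared` calibration filter exists
  but is off by default. A sample with fewer than 3 usable genes, or a
  degenerate (constant) expected vector, is an error naming the sample.
- Probe collapsing keeps the probe with the highest mean expression across
  all samples; ties keep the earlier probe in file order. Missing cells are
  imputed by the gene's within-group median when under 20% missing for that
  gene, otherwise the gene is dropped with a warning — median imputation is
  neutral for the downstream median-based correlation.
- Inputs are assumed log2; `log2_transform` applies log2(x+1) for
  linear-scale tables. Normalization itself (RMA etc.) is out of scope.
- Correlations default to tumor samples only (`tumor_only`), configurable,
  since series mix nontumor samples whose inclusion would inflate
  correlations through group differences.
- Pipeline outputs are flat TSVs with a one-line `# scale=log2
  config_hash=...` header and a JSON manifest of config echo plus content
  hashes; the hash covers analysis-relevant settings only, so identical
  analyses are byte-identical wherever they are written.
- Problem sizes in the test suite and acceptance script (50-seed detection
  study, 20-seed restoration study, 1000 oracle pairs, 2000 null pairs at
  n = 50) were chosen as the smallest sizes at which the binomial/sampling
  noise of each summary is comfortably below the decision margins.

## Known limitations

- The slope is a cohort-calibrated, relative measure: it depends on the
  nontumor samples of the same series and is not comparable across series
  with different platforms or panels.
- The default 59-gene panel is a curated list of canonical p53 targets and
  is meant to be replaced by a study-specific list; results on public
  accessions depend on the exact panel and on probe-collapsing choices.
- The t-based p-value for bicor is asymptotic; at very small n it is
  approximate.
- No multiple-testing correction is applied to anchor-vs-panel tables; with
  a dozen partners the raw two-sided p-values are what is reported.
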