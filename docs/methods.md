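# Methods

This note documents the statistical model behind `nanorisk`, the
defaults it ships, the choices made where the design was genuinely
open, and what the synthetic-data validation does and does not show.

## Distributional carrier

Every propagated quantity — animal benchmark concentration, the three
uncertainty factors, workplace exposure, and the risk characterization
ratio (RCR) — is a lognormal distribution parameterized by geometric
mean (GM) and geometric standard deviation (GSD ≥ 1; GSD = 1 is a point
mass). Internally the package works with μ = ln GM and σ = ln GSD; all
I/O uses (GM, GSD), the reporting convention of occupational hygiene.
Lognormals are closed under products and quotients (GMs multiply,
log-variances add), which gives every Monte Carlo stage an exact
analytic counterpart used as a cross-check.

Exposure summaries arrive as arithmetic mean m and SD s, so the
lognormal is moment-matched: σ² = ln(1 + (s/m)²), GM = m/√(1 + (s/m)²).
Method of moments is the only option here — the underlying measurement
series are not published — and it reproduces the input arithmetic
moments exactly.

## Monte Carlo sampling

Default 10,000 iterations of Latin hypercube sampling (LHS): the unit
interval is split into n equal-probability strata, one uniform draw is
taken inside each, and the strata are randomly permuted before the
inverse CDF is applied. Uniform within-stratum jitter (rather than
stratum midpoints) is used deliberately: midpoint LHS truncates the
extreme tails and would bias exceedance probabilities. With LHS the
sample geometric mean is nearly exact at n = 10⁴ (≲0.5% error), while
tail frequencies retain binomial-scale noise.

All randomness derives from one root seed. Stage- and cell-specific
streams use child seeds computed as CRC32(label) mixed with the root
(always < 2³¹), so each stage is individually reproducible and
numerator/denominator streams of a ratio are independent by
construction. A Kolmogorov–Smirnov statistic of the log draws against a
fitted normal is reported as a shape diagnostic only (Lilliefors-style,
approximate); it never gates the pipeline.

## Benchmark-dose engine

Continuous dose–response data enter as per-group summaries (dose, n,
mean, SD). The likelihood is normal with a constant variance across
groups, written on sufficient statistics:

    ll = Σᵢ [ −nᵢ/2 · ln(2πσ²) − ((nᵢ−1)sᵢ² + nᵢ(mᵢ−μᵢ)²) / (2σ²) ]

so raw animal-level responses are never required. Maximizing over the
mean parameters reduces to weighted least squares on the group means;
σ² is profiled analytically. AIC uses k = (mean parameters) + 1.

Five mean families are supported: linear γ+βd; quadratic polynomial
γ+β₁d+β₂d²; power γ+βd^δ (δ ≥ 1); Hill γ+v·d^η/(k^η+d^η) (η ≥ 1); and
exponential a·exp(±(bd)^c) (c ≥ 1, sign from the adverse direction).
Polynomial coefficients are sign-restricted to the adverse direction so
the fitted curve is monotone — the standard restricted-polynomial
practice; an unrestricted quadratic lets a weakly identified linear
term inflate low-dose curve variance and destabilize the benchmark
estimate. Shape exponents are capped at 18. Nonlinear families use
deterministic multi-start optimization (five data-driven starts,
Nelder–Mead with an inner linear solve for the coefficients that enter
linearly); convergence flags are honest and a non-converged fit is
never treated as reliable.

Lack of fit is a likelihood-ratio test against the saturated
(free group means) model, df = #groups − #mean-parameters, χ²
reference; with no residual df the p-value is undefined and the fit is
unreliable.

**Benchmark response and BMC.** The benchmark response is a change in
the mean equal to one control-group SD. Under the constant-variance
model the natural estimate of that SD is the pooled MLE σ̂, so the
default anchor is the modeled SD (an explicit anchor can be passed
instead). The BMC solves |m(BMC) − m(0)| = σ̂ on the fitted curve, by
bracketing scan plus Brent root-finding on [0, 10×top dose]; a curve
that never reaches the benchmark response yields no BMC and the fit is
flagged.

**Profile-likelihood bounds.** The one-sided 95% BMCL (BMCU) is the
smallest (largest) BMC among parameter vectors whose log-likelihood is
within χ²₁(0.90)/2 ≈ 1.353 of the maximum. With the modeled anchor the
variance parameter is tied to the constraint σ = |m(b) − m(0)| during
profiling, so anchor uncertainty — a dominant error source at typical
group sizes — propagates into the bound; with an explicit anchor the
scale coefficient is eliminated through the constraint and σ is
profiled analytically. The profile is walked outward from the MLE on a
log grid (200 points per 3 decades) with warm starts and the crossing
refined by bisection to ~10⁻⁶ relative; an uncrossed profile returns
the widest searched bound with a warning flag.

**Reliability and averaging.** A fit is reliable when it converged,
its lack-of-fit p ≥ 0.10 (boundary inclusive), its BMCL is finite and
positive, and BMC/BMCL ≤ 20 (guards degenerate profiles); thresholds
are config-exposed since "reliable" is a matter of practice. Surviving
fits are averaged with Akaike weights exp(−ΔAIC/2) (equal weights
available — the weighting scheme behind published averaged values is
often unstated); each pooled quantity is summarized on the log scale,
μ = Σwᵢ ln xᵢ, σ = √(Σwᵢ(ln xᵢ−μ)²), giving lognormal BMC_a, BMCL_a,
BMCU_a.

## Extrapolation to a human guidance value

BMC_h = 1000 · BMCL_a / (EF_inter · EF_intra · UF), with BMCL_a in
mg/m³ and BMC_h in µg/m³; the unit conversion lives here and is applied
exactly once. The four inputs are sampled independently and combined
elementwise; the returned distribution is the log-moment fit to the
draws, with the closed-form product carried alongside. Factors must
have GM ≥ 1 (they never amplify the guidance value).

The `paper_calibration` preset encodes the published summary values of
the reference assessment: BMCL_a = (9.4, 1.006) mg/m³ mapping to
BMC_h = (10.0, 1.5) µg/m³ pins the combined factor at GM 940 with
log-SD √(ln²1.5 − ln²1.006). The per-factor breakdown behind those
summaries is not public, so the combined factor is split evenly on the
log scale (each GM = 940^⅓ ≈ 9.80, each σ = combined/√3). This
preserves the extrapolation structure and the published endpoints
without inventing per-factor science; any per-factor set can be
supplied in the config instead.

## Exposure and background

The packaged reference table covers 15 (technique, event) cells; the
MT3/WE3 cell was never measured and propagates as a structured
not-available record through every report. The risk-assessment default
uses exposure *without* background subtraction — a precautionary
choice, since ambient particles counted as nanomaterial can only
overstate risk. Subtraction of the non-working-hours mean is opt-in,
happens on arithmetic means before the lognormal fit, is floored at
zero (with a warning), and is flagged in validation findings.

Two rows of the published summary tables are treated as errata and
excluded from anchors: the MT2 working-hours GM/GSD row (it duplicates
the background row, while the corresponding RCR row is consistent with
the measurement table the pipeline uses) and the MT3/WE1 RCR GM (0.56
printed where ≈0.056 is consistent with its own printed probability).
Published 5th/95th-percentile columns are internally inconsistent with
the printed GM/GSD and are not used as anchors either.

## Risk characterization

RCR draws are exposure draws over BMC_h draws. By default each cell
resamples BMC_h with its own child stream (independent numerator and
denominator, matching the ratio-of-distributions definition); a shared
BMC_h stream across cells is available, and the analytic quotient is
invariant to that choice. P(RCR ≥ 1) is the fraction of draws at or
above 1 — the boundary is inclusive — and "significant at 95%" means
P(RCR ≥ 1) ≥ 0.95, the only reading consistent with the reference
table's verdict column. Reported tables round GM/GSD to 2 significant
figures and probabilities to one decimal; full precision is retained
internally.

## Sensitivity analysis

Nominal range, one-at-a-time: each of the five chain inputs (BMCL_a,
three factors, exposure) is moved between its 5th and 95th percentile
with the others held at their medians; the deterministic chain is
re-evaluated and the absolute RCR swing recorded; contributions are
swings normalized to 100%. Medians (not means) are the hold points and
the swing is measured on the median response — stable under the heavy
right tails lognormal inputs can have. The percentile range and the
per-work-event evaluation are config-exposed choices; published percent
contributions depend on unpublished per-factor distributions, so only
structural facts are asserted (contributions sum to 100%, symmetric
inputs share equally, the three factors jointly dominate with > 75%,
the animal BMCL contributes least).

## Synthetic validation

The generators simulate what the pipeline actually consumes: per-group
summary statistics from normal responses around a known curve, and
campaign mean/SD cells from lognormal truth. Engine validation uses a
fixed per-family truth battery (`RECOVERY_TRUTHS`): 6 dose groups at 0,
0.1, 0.25, 0.5, 1, 2 mg/m³, 10 animals per group, within-group SD ≈10%
of the response range, and coefficients placed so the benchmark region
is interior to the design — the way a dose-ranging study is planned.
Under those conditions the median relative BMC error over 200
replicates is ≤10% for every family and the one-sided BMCL covers the
true BMC in ≥90% of replicates at nominal 95%.

What this does not show: performance on designs whose benchmark region
falls below the lowest dose (a steep Hill truth with its BMC at the
bottom dose shows ~12% median error — an identifiability limit of the
design, not of the estimator), heteroscedastic responses, or
non-lognormal exposure. Real campaigns also carry instrument and
sampling biases the lognormal summary cannot express.

## Numerical choices and degenerate inputs

- σ² is floored at 10⁻³⁰⁰ so noiseless fixtures cannot produce −∞
  log-likelihoods; "tiny but nonzero" SDs are the supported way to
  express near-noiseless data.
- Point masses (GSD = 1) flow through sampling, quotients and
  exceedance probabilities exactly (indicator semantics).
- LHS CDF values are clipped to [10⁻¹², 1−10⁻¹²] before the normal
  quantile.
- A single reliable model pools to GSD 1 with a warning; an empty
  reliable set is a hard error.
- Optimizer ties are broken by lowest AIC, then model-name order.

## Known limitations

- Constant-variance likelihood only; modeled (dose-dependent) variance
  is out of scope in this version.
- Quantal/dichotomous endpoints, covariate adjustment, and
  fiber-count (number-concentration) metrics are not supported — for
  the reference nanotube data no usable number-concentration
  dose–response model exists.
- Independence is assumed between all sampled inputs; correlated
  sampling is not implemented.
- The exposure family is lognormal only (no Weibull/gamma).
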