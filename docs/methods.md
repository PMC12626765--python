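# Methods

## Model and assumptions

`mrmediate` performs two-sample Mendelian randomization: per-variant
associations with the exposure and with the outcome come from separate
GWAS, summarised as (β, SE, EAF, N) per variant. Causal interpretation
rests on the usual instrumental-variable assumptions — relevance
(instruments associate with the exposure; enforced by the p-value and F
filters), independence from confounders, and exclusion restriction
(variant affects the outcome only through the exposure; probed, not
guaranteed, by the sensitivity battery).

The estimators operate on harmonized instrument tables:

* **IVW (primary).** Weighted regression of outcome effects on exposure
  effects through the origin, weights 1/σᵧ². The multiplicative
  random-effects flavour multiplies the fixed-effect SE by
  max(1, √(Q_resid/(J−1))); the floor means the SE is never deflated below
  the fixed-effect one. Inference is normal.
* **MR-Egger.** The same regression with a free intercept estimating
  average directional pleiotropy. Because the intercept depends on the
  chosen effect-allele orientation, instruments are re-oriented so every
  exposure effect is non-negative before fitting. Inference uses t with
  J−2 degrees of freedom — small instrument counts are the norm and normal
  quantiles would be anti-conservative for the intercept test.
* **Weighted median.** Interpolated weighted median of the Wald ratios
  with weights βₓ²/σᵧ²; consistent when over half the weight comes from
  valid instruments. SE by parametric bootstrap: θⱼ resampled from
  N(θ̂ⱼ, seⱼ), the median recomputed per resample (seeded, bit-reproducible).
* **Simple/weighted mode.** Argmax of a normal-kernel density of the
  ratios (equal weights or βₓ²/σᵧ²), bandwidth
  h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5) with φ = 1 by default, maximised
  on a 512-point grid spanning range(θ) ± 3h; consistent when the largest
  cluster of instruments is valid. SE by the same bootstrap, bandwidth
  recomputed per resample. All identical ratios give the common ratio.
* **Cochran's Q** is computed on the Wald ratios with first-order
  variances (σᵧⱼ/βₓⱼ)²; the regression-residual form appears only inside
  the IVW dispersion scale. The two differ at second order.

First-order Wald SEs ignore exposure-side sampling error (the standard
no-measurement-error approximation); the F > 10 filter is what keeps that
approximation honest.

## Mediation

With IVW estimates of the exposure→mediator (β_EM), mediator→outcome
(β_MO) and total exposure→outcome (β_EO) legs, the indirect effect is
β_EM·β_MO with the two-term delta SE √(β_MO²se_EM² + β_EM²se_MO²)
(legs from non-overlapping samples, treated as independent), and the
proportion mediated is β_EM·β_MO/β_EO. The default proportion interval
treats β_EO as fixed and rescales the indirect-effect interval by it; this
is the convention that reproduces published intervals computed this way. A
`full_delta=True` variant additionally propagates var(β_EO) through the
ratio and is wider. Reported tables round effects to 3 decimals and quote
the proportion as the rounded indirect over the total (3 significant
figures); full precision is kept internally. SEs can be reconstructed from
printed 95% CIs as (hi − lo)/(2·1.959964).

## Pipeline defaults (and why)

| parameter | default | rationale |
|---|---|---|
| instrument p-threshold | 1e-5 | screening threshold for traits with few genome-wide hits (metabolites); use 5e-8 for large-GWAS exposures |
| reverse-arm p-threshold | 1e-5 | disease outcomes rarely have 5e-8 hits at small effective n; logged prominently per run |
| clumping | r² < 0.001 within 10 Mb | pairwise \|Δpos\| ≤ window; LD from an explicit precomputed table, variants outside its domain treated as independent with a warning |
| F filter | keep F > 10 (strict) | conventional weak-instrument cutoff; p-selection uses strict <, clumping discards at r² ≥ cutoff |
| verdict α | 0.05 two-sided | applied to Q, Egger intercept and reverse-IVW tests; configurable |
| bootstrap | n_boot = 1000, seeded | all stochastic outputs bit-reproducible under a fixed seed |
| multiple testing | none (optional BH) | the screen is deliberately raw-p; Benjamini–Hochberg available but off by default |

Harmonization policy: non-palindromic variants match directly, by allele
swap (outcome β negated, EAF complemented) or by strand complement;
palindromic (A/T, C/G) variants are resolved by comparing allele
frequencies, and are dropped when either frequency is missing or both lie
in 0.5 ± 0.08 (the community-standard ambiguity band), or all dropped under
`drop_all`. A strand flip that also requires a swap is recorded as
`kept_strand_flipped` with the sign change noted in the `sign_flipped`
column. The R² used for strength is the simplified β²/(β²+SE²N); it is
algebraically identical to the 2β²·EAF(1−EAF)-form and the equality is
property-tested.

## The synthetic-GWAS generator

`simulate_triad` emulates the statistical structure of the target data:
a very large continuous exposure GWAS (default N = 330,762), a moderate
metabolite GWAS (N = 8,299), and a heavily imbalanced binary outcome GWAS
(855 cases / 345,118 controls, entering through the effective sample size
4/(1/cases + 1/controls) ≈ 3,400 — which is what makes outcome intervals
realistically wide). Variants are independent (optional LD blocks exist for
exercising clumping), uniformly spaced on one synthetic chromosome, with
MAF ~ U(0.05, 0.5). Observed effects are true effects plus N(0, SE) with
SE = 1/√(2·N·MAF(1−MAF)); reported allele orientation/strand is randomly
scrambled so harmonization does real work. The causal chain E→M→O has
effects a, b and a direct c′; the generator's true total effect is
a·b + c′ and the true mediation proportion a·b/(a·b + c′). Contamination
channels: sign-aligned directional pleiotropy (visible to the Egger
intercept after re-orientation), outcome noise inflation with the reported
SE kept nominal (visible to Q), and reverse-causal variants that drive the
outcome with the "mediator" responding downstream. Default per-variant
effect ranges (exposure |β| 0.02–0.06 SD across 100 instruments, metabolite
|β| 0.15–0.35 SD across 15) give selection-stage z-scores in the realistic
4–25 range at the default sample sizes.

What the generator does **not** emulate: real LD structure, allele-frequency
spectra tied to LD, population stratification, sample overlap between
studies, and genotype-level effects. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated sampling model,
not robustness to those real-data complications.

## Calibration studies and their results

`mrmediate.validation` measures operating characteristics by simulation,
using compact replicate panels (160 variants: the default instrument blocks
plus a null margin) so thousands of replicates run in seconds; the measured
characteristics depend on instrument counts and strengths, not panel size.

* **Type-I error** of the primary IVW stage under the global null is
  slightly *below* the nominal 5% (empirically ≈ 3.5–4.5% over 1000
  replicates): the max(1, ·) dispersion floor only ever widens the SE.
* **Coverage** of the IVW 95% interval under a homogeneous effect is at the
  nominal level (≈ 95% over 2000 replicates), marginally above it for the
  same reason.
* **Mediation recovery**: the median estimated proportion over 500
  replicates at a = 0.2, b = 0.3, c′ = 0.3 lands within ~1 point of the
  true 16.7%; single-replicate estimates are noisy (the E→M leg has
  per-instrument z ≪ 1 at metabolite sample sizes, exactly as in real
  two-step designs).
* **Cascade operating characteristics** — a known limitation worth stating
  plainly. With 20 metabolites of which 3 are truly causal, the screen
  recovers *exactly* the causal set in only ~15–30% of replicates. This is
  inherent to the protocol, not an implementation defect: (i) each causal
  trait faces two 5%-level sensitivity exclusions (Q, Egger intercept)
  under which it is null, so three causal traits all survive with
  probability ≈ 0.95⁶ ≈ 0.74 at best; (ii) the reverse-MR arm selects
  outcome instruments at p < 1e-5, and a causal metabolite's own variants
  reach that threshold by winner's curse in many replicates, producing
  reverse-causation flags for genuinely forward-causal traits — the
  standard bidirectional-MR artifact that Steiger filtering (out of scope
  here) addresses; (iii) each of the 17 null traits survives
  IVW + direction-consistency by chance with probability ~2%, so some
  false survivor appears in ~30–40% of replicates. The
  `cascade_recovery_study` reports joint-exact, all-causal-found and
  false-survivor rates separately so users can see each mechanism.

## Degenerate inputs and numerical choices

Zero p-values on input are clamped to the smallest positive float;
duplicate variant ids are an error; indel/multi-character alleles are
dropped with logged reasons; missing EAF is retained but rejected by R²/F
and palindrome resolution. A single harmonized instrument downgrades IVW to
the Wald ratio with a logged note; fewer than three instruments disable
Egger/median/mode (and therefore direction consistency, which then fails
the cascade's consistency stage explicitly rather than silently passing).
Exact-fit regressions (residual scale 0) use the unscaled (X′WX)⁻¹
covariance. Clumping ties on p break by (chromosome, position, variant id)
so results are input-order invariant. An untestable reverse arm (no outcome
instruments at the threshold) is reported as NaN and treated as "no
evidence of reverse causation", with the choice logged.

## Limitations

No MR-PRESSO outlier removal, Steiger filtering, multivariable MR or
multiple simultaneous mediators; no genotype-level data, liftover, or
proxy-variant search; LD must be supplied as a precomputed table. The
binary-outcome scale is assumed log-odds; mediation on the odds-ratio
scale inherits the usual non-collapsibility caveats.
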