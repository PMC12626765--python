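# mrmediate

Two-sample Mendelian randomization (MR) mediation analysis over GWAS
summary statistics.

`mrmediate` is for epidemiologists and statistical geneticists asking
whether an exposure's effect on a disease travels through an intermediate
trait — e.g. whether adiposity raises small-cell lung cancer risk partly by
shifting a circulating metabolite. It implements the full two-step screen:
instrument selection with explicit R²/F strength formulas, effect-allele
harmonization across studies, five causal estimators with a sensitivity
battery, a staged exclusion cascade over many candidate mediators, and
product-of-coefficients mediation. A bundled synthetic-GWAS generator with
known causal truth makes every stage testable without any external data.

## The method

Per variant *j*, with effect β̂ₓⱼ (SE σₓⱼ) on the exposure and β̂ᵧⱼ (SE σᵧⱼ)
on the outcome after harmonization, the Wald ratio is θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ. The
primary estimator is inverse-variance weighted (IVW) regression of β̂ᵧ on
β̂ₓ through the origin with weights 1/σᵧⱼ²:

    β̂_IVW = Σ wⱼ β̂ₓⱼ β̂ᵧⱼ / Σ wⱼ β̂ₓⱼ² ,   se_fixed = (Σ wⱼ β̂ₓⱼ²)^(−1/2)

with a multiplicative random-effects SE, se_fixed · max(1, √(Q_resid/(J−1))).
MR-Egger adds a free intercept (average directional pleiotropy); the
weighted median and the simple/weighted mode estimators are robust to
invalid instruments under majority-valid and plurality-valid assumptions.
Instrument strength uses R² = β²/(β² + SE²·N) and F = R²(N−2)/(1−R²), with
F > 10 retained. The sensitivity battery reports Cochran's Q, the Egger
intercept test, five-method direction consistency, and a reverse-direction
IVW with exposure and outcome roles swapped.

Given IVW estimates of the three legs — exposure→mediator β_EM,
mediator→outcome β_MO, total exposure→outcome β_EO — mediation is
quantified by the product of coefficients:

    indirect = β_EM · β_MO ,  proportion mediated = β_EM · β_MO / β_EO

with se(indirect) = √(β_MO²·se_EM² + β_EM²·se_MO²) and the proportion
interval obtained by rescaling the indirect-effect interval by β_EO.

## Worked example

The mediation arithmetic from printed coefficients (an adiposity →
metabolite → cancer-risk pathway, with 95% CIs for each leg):

```python
from mrmediate import mediation_from_intervals

res = mediation_from_intervals(
    0.200, (0.096, 0.303),   # exposure -> mediator
    0.329, (0.005, 0.653),   # mediator -> outcome
    0.442, (0.114, 0.771),   # total exposure -> outcome
)
print(res.summary())
```

prints

```
{'beta_em': 0.2, 'beta_mo': 0.329, 'beta_eo': 0.442, 'indirect': 0.066,
 'indirect_se': 0.0373, 'proportion_pct': 14.9,
 'proportion_ci_low_pct': -1.67, 'proportion_ci_high_pct': 31.4}
```

i.e. an indirect effect of 0.066 on the log-odds scale: 14.9% (95% CI
−1.67% to 31.4%) of the exposure's total effect runs through the mediator —
an interval that includes zero, so the mediation is suggestive rather than
definitive.

A full synthetic run from the shell:

```sh
mrmediate simulate --config config.yaml --out-dir sim/
mrmediate screen   --config config.yaml --out-dir screen/
mrmediate mediate  --config config.yaml --out-dir mediation/
```

`simulate` writes canonical tab-separated summary statistics, an LD table
and a truth sidecar; `screen` runs the five-stage exclusion cascade
(IVW significance → direction consistency → pleiotropy → heterogeneity →
reverse causality) and writes audit, results, volcano and forest-table
files; `mediate` estimates the three legs and the mediation proportion.
See the `mrmediate.cli` docstring for the config schema.

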