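# latentdiff

Group comparisons on questionnaire scale scores are routinely reported as
Cohen's *d* computed from the observed sum or mean score. But the observed
score is contaminated by measurement error: under classical test theory
X = τ + ε, so σ²_X = σ²_τ + σ²_ε, and every statistic that divides by the
observed standard deviation is attenuated by the factor √reliability,

    d_observed = d_true · √rel,    bias% = 100 · (1 − √rel).

`latentdiff` is a toolkit for researchers in psychometrics, epidemiology and
the social sciences who want to quantify that distortion. It compares, for
each scale, the **observed** standardized mean difference *d_Y* (on the
reverse-keyed sum/mean score) against the **latent** standardized mean
difference *d_τ* from an invariance-constrained multigroup ordinal
confirmatory factor analysis — thresholds and loadings equal across the two
groups, the group-2 latent mean α₂ and variance ψ₂ free, group 1 fixed at
(0, 1) for identification — with

    d_τ = (α₁ − α₂) / √(((n₁−1)·1 + (n₂−1)·ψ₂) / (n₁+n₂−2)).

Estimation is the standard two-step ordinal-SEM route: item thresholds from
the univariate margins (normal quantiles of cumulative proportions),
pairwise polychoric correlations by maximum likelihood with thresholds
fixed, then (diagonally) weighted least squares on the stacked summary
statistics. Per-scale discrepancies Δd = |d_τ| − |d_Y| (with a one-tailed z
test using Var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))) are aggregated by
random-effects meta-analysis (REML or DerSimonian–Laird), giving a pooled
discrepancy, Cochran's Q, I², and the between-scale SD τ — which, being in
the same metric as Δd, answers "what fraction of scales should exceed a
given discrepancy?". McDonald's ω from the fitted model links each scale's
reliability to its discrepancy.

Because real item-bank archives are deliberately not a dependency, the
package ships a synthetic-data generator with a fully known truth: a
unidimensional congeneric factor model per scale, ordinal Likert-type items
produced by thresholding normal latent responses, a chosen true latent
group difference, group-specific latent variance, and a chosen reliability.
Every stage of the pipeline is validated against it.

## Worked example

The closed-form attenuation table (true Δμ = 1, σ²_τ = 1, so true d = 1):

```
$ latentdiff theory table1
 reliability  error_variance  observed_variance  observed_d  bias_percent
         1.0            0.00               1.00        1.00          0.00
         0.9            0.11               1.11        0.95          5.13
         0.8            0.25               1.25        0.89         10.56
         0.7            0.43               1.43        0.84         16.33
         0.6            0.67               1.67        0.77         22.54
         0.5            1.00               2.00        0.71         29.29
```

A reliability of 0.80 already biases *d* by more than 10% — the usual rule
of thumb for preferring a latent-variable comparison.

A three-scale simulated study (6 items each, 2000 respondents per group,
true latent d = 0.5, loadings 0.5 / 0.65 / 0.8):

```python
from latentdiff.pipeline import run_study

cfg = {
    "seed": 5,
    "estimation": {"estimator": "ULS"},
    "scales": [
        {"name": f"scale_{i}",
         "source": {"type": "simulate", "n_items": 6, "loading": l,
                    "group_sizes": [2000, 2000], "latent_d": 0.5}}
        for i, l in enumerate([0.5, 0.65, 0.8])
    ],
}
res = run_study(cfg)
```

after which `res.table` holds (columns abridged) and `res.meta_signed` the
pooled summary:

```
  scale  d_tau   d_Y  signed_delta_d  signed_percent_change     p  omega
scale_0  0.541 0.428           0.113                 23.234 0.007  0.665
scale_1  0.540 0.480           0.060                 11.841 0.092  0.820
scale_2  0.504 0.473           0.031                  6.437 0.244  0.918
meta (signed): pooled=0.068 [0.017, 0.120] tau=0.000
```

The latent d recovers the generating value 0.5 for every scale while the
observed d is shrunk — by more for the low-reliability scale (ω = 0.67,
−23%) than for the high-reliability one (ω = 0.92, −6%) — exactly the
√ω attenuation the theory predicts. The same pipeline runs from the shell
(`latentdiff simulate / compare / meta / run`) on item-level CSVs plus a
YAML scale definition, so real questionnaire exports can be analyzed the
same way.

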