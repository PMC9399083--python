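# ginvest — Bayesian SEM of grandparental investment

`ginvest` estimates how the survival status of grandparents shapes the
investment of the *other* grandparents in a grandchild, using a Bayesian
structural equation model with ordinal survey indicators.  It is aimed at
researchers in evolutionary demography and family sociology who work with
grandchild-reported surveys (e.g. the UK "Involved Grandparenting and Child
Well-Being" study design) where each adolescent reports, for every living
grandparent, a handful of Likert-type items about contact, care, dependability
and financial help.

## The model

For grandchild *i* and grandparent type *g* ∈ {MGM, MGF, PGM, PGF} (maternal/
paternal grandmother/grandfather), an unobserved "investment" factor η<sub>ig</sub>
is measured by four ordinal items through a probit threshold link:

```
y*_ijg = λ_jg η_ig + ε_ijg ,   ε ~ N(0, 1)
y_ijg  = c   iff   τ_{j,c-1} < y*_ijg ≤ τ_{j,c}
```

Items: Q15 (contact frequency), Q26 (looked after, reverse-coded), Q27
(dependability) on 1–4 scales; Q38 (financial assistance) on 1–3, used as the
marker with λ fixed at 1.  Thresholds τ are shared across the four grandparent
types and one loading (Q15 by default) is type-specific — partial measurement
invariance.  The structural part regresses each factor on the *other three*
alive/dead flags plus grandchild age:

```
η_ig = α_g + Σ_h β_gh · alive_ih + β_age,g · age_i + ζ_ig ,   ζ_i ~ N_4(0, Ψ)
```

with α_MGM ≡ 0 (reference) for identification and a full 4×4 latent error
covariance Ψ capturing within- and between-lineage correlation.  Responses for
deceased grandparents are missing by design and enter as MAR through the joint
latent structure.  Estimation is by Gibbs sampling with truncated-normal data
augmentation; priors are N(0, 100²) on structural coefficients, N(0, 5) on
loadings, N(0, 1) on thresholds, inverse-Wishart(I₄, 5) on Ψ.  Reporting uses
posterior medians, 95% highest-posterior-density intervals, a one-tailed
posterior p, and the Gelman–Rubin PSRF.

Two derived analyses are included: probit **marginal effects** (marker-item
category probabilities with a predictor at 0 vs 1) and a **phantom-variable
sensitivity analysis** for unmeasured within-lineage confounding (an
indicator-less latent with fixed mean 0 / variance 1 wired with equal fixed
paths γ into a spouse-survival flag and the focal factor, at 1× and 2× a
chosen confounding strength).

Because the original survey is safeguarded, the package ships a synthetic
cohort generator whose defaults emulate the published study conditions
(survival proportions 83.7/68.8/73.2/57.1 %, age 13.39 ± 1.41 on 11–16,
n = 1411, published structural medians and latent correlations); measurement
parameters are synthetic plumbing (see `docs/methods.md`).

## Worked example

```python
import ginvest as gv

truth  = gv.default_truth()                       # published-condition defaults
cohort = gv.generate_cohort(truth, 1411, seed=11)

model = gv.InvestmentModel(cohort.table)          # applies exclusion rules
res = model.fit(chains=3, iterations=20_000, burnin=10_000, thin=10, seed=11)
print(res.structural_table().head(3).round(3))
print(res.correlation_table().round(3))
```

prints (seed 11):

```
                     median  hpd_lo  hpd_hi  p_one_tailed   psrf
parameter
beta[MGM~MGF_alive]   0.210   0.086   0.334         0.001  1.011
beta[MGM~PGM_alive]   0.030  -0.091   0.149         0.316  1.021
beta[MGM~PGF_alive]   0.084  -0.038   0.204         0.091  1.002
       MGM    MGF    PGM    PGF
MGM  1.000  0.897  0.186  0.190
MGF  0.897  1.000  0.271  0.276
PGM  0.186  0.271  1.000  0.936
PGF  0.190  0.276  0.936  1.000
```

The first block is the structural-coefficient report (table 1 of the output bundle): e.g. the maternal grandmother's
investment rises by 0.210 latent-SD-scale units when the maternal grandfather
is alive (true generating value 0.157, inside the HPD).  The correlation
matrix recovers the strong within-lineage clustering (generating values 0.881
and 0.958).  `res.marginal_effects()` converts coefficients into marker-item
category probabilities, and `res.sensitivity()` produces the side-by-side
confounding scan (table 3 of the output bundle).

A CLI wraps the same workflows:

```bash
ginvest simulate --n 1411 --seed 1 --out sim/
ginvest fit sim/cohort.csv --chains 3 --out fit/
ginvest sensitivity sim/cohort.csv --quick --out sens/
ginvest recover --quick --seed 1 --out rec/
```

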