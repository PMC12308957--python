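# dynacor

Dynamic gene co-expression along pseudotime, modelled by a zero-inflated
Gamma copula distributional regression.

## The problem

Single-cell RNA-seq studies routinely order cells along a developmental
trajectory ("pseudotime") and ask how expression changes along it — usually
one gene at a time. But genes act together, and the *co-expression* of a
gene pair can strengthen, weaken, or reverse along the trajectory even when
neither gene's mean changes. Normalized single-cell expression is
continuous, over-dispersed, and full of exact zeros whose frequency itself
drifts along pseudotime, so a useful model of dynamic co-expression must
handle all of these at once — and, for case/control designs (e.g. wild-type
versus mutant embryos), it must compare groups inside one model rather than
fitting each group separately.

`dynacor` is for analysts who have (a) a cells × genes matrix of normalized
non-negative expression, (b) a pseudotime and a group label per cell, and
(c) gene pairs to screen for group-differential co-expression dynamics.

## The model

For cell *i* with expression pair (y₁, y₂), a two-part model separates
structural zeros from positive expression. Bernoulli "off" masks
D_ij ~ Bern(p_ij) generate exact zeros; positive values follow Gamma
marginals in the mean / coefficient-of-variation parametrization
(E W = μ, Var W = σ²μ²), joined by a Gaussian copula with correlation ρᵢ:

    f(w₁, w₂) = c( F_GA(w₁; μ₁, σ₁), F_GA(w₂; μ₂, σ₂); ρ ) · f_GA(w₁) · f_GA(w₂)

Every distributional parameter θ ∈ {μ₁, σ₁, μ₂, σ₂, ρ, p₁, p₂} gets its own
additive predictor with a link keeping it in its domain
(log for μ and σ, tanh⁻¹ for ρ, logit for p):

    g(θᵢ) = β₁ + β₂·1(gᵢ = 2) + s₁(zᵢ)·1(gᵢ = 1) + s₂(zᵢ)·1(gᵢ = 2)

i.e. a group fixed effect plus a separate thin plate regression spline per
group — the formula `gene_j ~ group + s(z, by=group)`. The copula-side
coefficients maximize the penalized log-likelihood ℓ_p = Σℓᵢ − ½δᵀSδ by a
trust-region Newton method, alternating with smoothing-parameter selection
that minimizes a prediction-error criterion of the working linear model.
Zero-inflation curves are fitted separately as penalized logistic additive
models on the zero indicators — the zero rate is exactly the marginal zero
probability, so it decouples from the copula fit.

Inference: a Wald-type test of ρ(z) ≡ 0, likelihood-ratio tests of
"both groups share one curve" for ρ(z) and for each gene's zero-inflation
curve, Benjamini–Hochberg adjustment across screened pairs, and the curve
separation metrics Δ|ρ̂| (mean absolute difference on a shared grid),
|Δρ̂|max, and AUD (area under the absolute difference curve).

## Worked example

Two groups of cells whose correlation trajectories genuinely differ
(built-in study scenario III: the wild-type correlation climbs from
negative to near 1, the mutant stays weak):

```python
import numpy as np
from dynacor import (scenario_III, fit_pair, predict_curves,
                     test_group_difference_rho, delta_rho_bar,
                     max_abs_diff, aud)
from dynacor.inference import shared_grid

sim = scenario_III(n=2000, seed=42)
fit = fit_pair(sim.y1, sim.y2, sim.z, sim.group)
grid = shared_grid(sim.z, sim.group, n_time=100)
wt  = predict_curves(fit, grid, group=1, parameters=["rho"])["rho"]["value"]
mut = predict_curves(fit, grid, group=2, parameters=["rho"])["rho"]["value"]
test = test_group_difference_rho(sim.y1, sim.y2, sim.z, sim.group,
                                 full_fit=fit)
```

This prints (seed 42):

```
converged: True   cells: 2000 (wild-type 1100, mutant 900)
rho(z) wild-type: -0.36 -> +0.96;  mutant: +0.23 -> +0.07
curve-difference test: LR = 229.0, df = 0.7, p = 3.7e-52
delta|rho| = 0.514   max|diff| = 0.887   AUD = 13.84
```

The fitted wild-type correlation rises from −0.36 to +0.96 across
pseudotime while the mutant curve stays near zero — the generating truth —
and the curve-identity null is overwhelmingly rejected. Δ|ρ̂| = 0.51 says
the two curves differ by 0.51 correlation units on average;
AUD = span × Δ|ρ̂| integrates that difference over the pseudotime window.

The same machinery is scriptable from the shell:

```bash
dynacor simulate --scenario III --n 2000 --seed 42 --out pair.csv
dynacor fit --data pair.csv --out curves.tsv
dynacor screen --expr expr.csv --meta meta.csv --genes genes.txt --out results.tsv
dynacor power --c-grid 0,0.5,1,2 --replicates 60 --seed 1
```

`screen` fits every unordered gene pair, tests the group difference,
computes the curve metrics, and writes a BH-adjusted TSV sorted by adjusted
p-value.

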