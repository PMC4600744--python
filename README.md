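# neutralnull

Tools for asking a central question of community ecology with microbial
data: how much of community assembly is deterministic (niche-based
environmental filtering) and how much is stochastic (dispersal limitation
and drift)? The package implements the full analysis chain used in
large-scale soil-survey studies of bacteria and fungi: community-fingerprint
(T-RFLP) table processing, pairwise turnover and distance decay, maximum-
likelihood fitting of Hubbell's neutral model via the Etienne sampling
formula, null-model effect sizes against ensembles of neutral simulations,
variogram-based spatial dependence, and a synthetic-data generator with
controlled ground truth so every stage is testable offline.

## The model at the core

A local community of `J` individuals assembles from a neutral metacommunity
with biodiversity number `θ`; its isolation is measured by the immigration
parameter `I = m(J−1)/(1−m)`. The likelihood of an abundance configuration
`D = (n₁…n_S)` is the Etienne sampling formula

    P(D | θ, I, J) = J!/(∏ᵢ nᵢ ∏ⱼ Φⱼ!) · θ^S/(I)_J · Σ_A K(D,A) I^A/(θ)_A

with `K(D, A)` built from unsigned Stirling numbers of the first kind and
computed here entirely in log space (no overflow for any `J`). Deviations
from neutrality are quantified as effect sizes: the observed median (and
IQR/IDR) of pairwise Sørensen similarities minus the mean of the same
statistic over simulated neutral ensembles, with percentile confidence
intervals. Negative median effect = divergence (niche structuring in a
heterogeneous environment); positive = convergence. Turnover in space is
the slope `z` of `log₁₀(χ_d) = b + z·log₁₀(d)`, habitat similarity is
`E_d = 1 − Euc_d/Euc_max`, and spatial dependence of community/habitat
principal components is classified from the variogram nugget/sill ratio
(<25% strong, 25–75% moderate, >75% weak).

See `docs/methods.md` for estimation strategies, numerical choices and
limitations.

## Worked example

Simulate a landscape where 80% of recruitment is niche-driven by a spatially
autocorrelated habitat gradient, then test it against the neutral null:

```python
import neutralnull as nn

cfg = nn.ScenarioConfig(n_sites=20, n_layers=1, J=500,
                        niche_strength=0.8, niche_width=0.1,
                        n_habitat_vars=10, I=18.60, seed=1)
sites = nn.make_sites(cfg)
habitat = nn.make_habitat(sites, cfg)
cm = nn.make_communities(sites, habitat, cfg)

fit = nn.fit_neutral(nn.configurations_from_matrix(cm))
print(f"theta = {fit.theta_hat:.1f}, I median = {fit.I_median:.1f}")

median = nn.null_effect_sizes(cm, fit, n_sim=300, seed=501)[0]
print(f"median effect = {median.point:+.3f} "
      f"[{median.ci_low:+.3f}, {median.ci_high:+.3f}], "
      f"significant = {median.significant}")
```

Output:

```
theta = 24.7, I median = 186.1
median effect = -0.189 [-0.233, -0.148], significant = True
```

The fitted neutral model predicts far more similar communities than
observed: the median effect size is strongly negative with a confidence
interval well away from zero — the planted niche structuring is detected as
significant divergence. Rerunning with `niche_strength=0` gives
`median effect = -0.007 [-0.049, +0.035], significant = False`: pure
neutral assembly is not flagged.

A thin CLI wraps the same library calls, e.g.

```sh
neutralnull synth scenario --preset mixed --n-sites 36 --out-dir demo/
neutralnull turnover distance-decay --community demo/community_true.tsv \
    --sites demo/sites.csv --layer 1 --raw-pairs --out fit.json
neutralnull nullmodel run --community demo/community_true.tsv \
    --sites demo/sites.csv --group-by layer --n-sim 1000 --seed 42 \
    --out effects.tsv
```

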