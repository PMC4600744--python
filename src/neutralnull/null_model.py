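"""Null-model effect sizes against ensembles of neutral simulations.

The observed distribution of pairwise Sørensen similarities within a
group of communities is summarized by its median (central tendency) and
its interquartile / interdecile ranges (dispersion of the middle 50% and
80%).  The same summaries are computed for each of ``n_sim`` independent
neutral simulations run at the fitted (theta, I); an effect size is the
observed summary minus the mean simulated summary, with a percentile
confidence interval built from the 2.5th and 97.5th percentiles of the
simulated summaries.

Sign convention (following the direction "observed similarities reduced
relative to neutral predictions" = divergence): a negative median effect
size means the observed communities are more dissimilar than the neutral
expectation (divergence, as under environmental filtering in a
heterogeneous landscape); positive means convergence.  For IQR/IDR,
positive = overdispersion, negative = underdispersion.  Note that
published figure captions sometimes phrase the mapping the other way
round; this package documents and uses the convention above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CommunityMatrix, SiteTable
from .neutral_model import NeutralFit, configurations_from_matrix, fit_neutral, simulate_neutral
from .turnover import SimilarityMatrix, sorensen_similarity

STATISTICS = ("median", "iqr", "idr")


@dataclass
class SimilaritySummary:
    """Median / IQR / IDR of a pairwise-similarity distribution.

    Quantiles use linear interpolation (the numpy default); IQR and IDR
    values depend on this rule, so it is fixed here.
    """

    median: float
    iqr: float
    idr: float
    n_pairs: int

    def __getitem__(self, stat: str) -> float:
        return getattr(self, stat)


def similarity_summary(sim: SimilarityMatrix) -> SimilaritySummary:
    """Summaries over the strict lower triangle of a similarity matrix."""
    if len(sim.sample_ids) < 2:
        raise ValueError("need at least two samples")
    v = sim.lower_triangle()
    v = v[np.isfinite(v)]
    q10, q25, med, q75, q90 = np.quantile(v, [0.10, 0.25, 0.50, 0.75, 0.90])
    return SimilaritySummary(float(med), float(q75 - q25), float(q90 - q10),
                             n_pairs=int(v.size))


@dataclass
class EffectSize:
    statistic: str
    observed: float
    point: float      # observed - mean(simulated)
    ci_low: float     # observed - P97.5(simulated)
    ci_high: float    # observed - P2.5(simulated)
    significant: bool
    n_sim: int

    def __post_init__(self):
        if not (self.ci_low <= self.point + 1e-12 and
                self.point <= self.ci_high + 1e-12):
            raise ValueError("effect-size CI ordering violated")


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def null_effect_sizes(observed: CommunityMatrix, fit: NeutralFit,
                      n_sim: int = 1000, seed: int = 0,
                      J: int | None = None, mode: str = "binary",
                      per_sample_I: bool = False) -> list:
    """Effect sizes of the observed similarity distribution vs neutrality.

    Each simulation regenerates ``observed.n_samples`` communities of
    equal size ``J`` (default: median of the observed sample totals) from
    a shared metacommunity at the fitted theta and median I, then the
    median/IQR/IDR of its pairwise Sørensen similarities are recorded.
    ``per_sample_I`` instead simulates community j at its own fitted I_j.
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives unstable percentile CIs")
    if not fit.converged:
        warnings.warn("neutral fit did not converge; effect sizes may be unreliable")
    n_comm = observed.n_samples
    if J is None:
        J = int(round(np.median(observed.abundance.sum(axis=1))))
    obs = similarity_summary(sorensen_similarity(observed, mode=mode))

    sims = np.empty((n_sim, len(STATISTICS)))
    seeds = _child_seeds(seed, n_sim)
    I_sim = np.asarray(fit.I_hat, dtype=float) if per_sample_I else fit.I_median
    for s in range(n_sim):
        cm = simulate_neutral(n_comm, J, fit.theta_hat, I_sim, seed=seeds[s])
        summ = similarity_summary(sorensen_similarity(cm, mode=mode))
        sims[s] = [summ[stat] for stat in STATISTICS]

    out = []
    for k, stat in enumerate(STATISTICS):
        col = sims[:, k]
        lo, hi = np.percentile(col, [2.5, 97.5])
        point = obs[stat] - float(col.mean())
        ci_low = obs[stat] - float(hi)
        ci_high = obs[stat] - float(lo)
        out.append(EffectSize(stat, obs[stat], point, ci_low, ci_high,
                              significant=not (ci_low <= 0.0 <= ci_high),
                              n_sim=n_sim))
    return out


@dataclass(frozen=True)
class GroupKey:
    layer: int | None = None
    land_use: str | None = None
    taxon_group: str | None = None


def grouped_null_analysis(cm: CommunityMatrix, sites: SiteTable,
                          grouping=("layer",), n_sim: int = 1000,
                          seed: int = 0, min_group_size: int = 5,
                          strategy: str = "richness_match", J: int | None = None,
                          taxon_group: str | None = None) -> pd.DataFrame:
    """Fit the neutral model and compute effect sizes within sample groups.

    ``grouping`` selects site-table columns (``layer`` and/or
    ``land_use``).  Groups smaller than ``min_group_size`` are skipped
    with a warning.  Returns a long-format table with one row per group
    and statistic, mirroring the usual per-layer / per-land-use effect
    size panels, plus the fitted theta and I summaries per group.
    """
    grouping = list(grouping)
    bad = [g for g in grouping if g not in ("layer", "land_use")]
    if bad:
        raise ValueError(f"unsupported grouping columns: {bad}")
    meta = sites.frame.set_index("sample_id").loc[cm.sample_ids]
    groups = meta.groupby(grouping, sort=True).groups
    if not groups:
        raise ValueError("no groups formed")
    seeds = _child_seeds(seed, len(groups))
    rows = []
    for gseed, (key, idx) in zip(seeds, groups.items()):
        key_t = key if isinstance(key, tuple) else (key,)
        label = dict(zip(grouping, key_t))
        sample_ids = list(idx)
        if len(sample_ids) < min_group_size:
            warnings.warn(f"group {label} has {len(sample_ids)} samples; skipped")
            continue
        sub = cm.subset(sample_ids)
        fit = fit_neutral(configurations_from_matrix(sub), strategy=strategy)
        effects = null_effect_sizes(sub, fit, n_sim=n_sim, seed=gseed, J=J)
        for e in effects:
            rows.append({
                **({"taxon_group": taxon_group} if taxon_group else {}),
                **label,
                "n_samples": len(sample_ids),
                "theta": fit.theta_hat,
                "I_median": fit.I_median,
                "I_IQR": fit.I_iqr,
                "statistic": e.statistic,
                "observed": e.observed,
                "point": e.point,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "significant": e.significant,
            })
    if not rows:
        raise ValueError("all groups below the minimum size")
    return pd.DataFrame(rows)
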