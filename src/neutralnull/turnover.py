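"""Pairwise similarity, distance decay, neighbourhoods and Mantel tests.

Community similarity is the Sørensen index: ``2a / (2a + b + c)`` on
presence/absence (equivalently 1 - Bray-Curtis on binary data), with an
abundance variant 1 - Bray-Curtis.  Habitat similarity is
``E_d = 1 - Euc_d / Euc_max``: Euclidean distance between standardized
edaphic profiles, rescaled so the most dissimilar pair in the data set
scores exactly 0.  Turnover is the slope z of the distance-decay
relationship ``log10(chi_d) = b + z log10(d)``, fitted either to
distance-binned means weighted by pair counts (default) or to raw pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, t as t_dist

from .data_io import CommunityMatrix, HabitatMatrix, SiteTable, ValidationError


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1] with unit diagonal."""

    sample_ids: list
    values: np.ndarray
    kind: str = "community_sorensen"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite]):
            raise ValidationError("similarity matrix not symmetric")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValidationError("similarities must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.sample_ids), k=-1)
        return self.values[i, j]

    def subset(self, sample_ids) -> "SimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SimilarityMatrix(list(sample_ids),
                                self.values[np.ix_(idx, idx)], kind=self.kind)


def sorensen_similarity(cm: CommunityMatrix, mode: str = "binary") -> SimilarityMatrix:
    """Pairwise Sørensen similarity between samples.

    ``binary``: 2a/(2a+b+c) on presence/absence; ``abundance``:
    1 - Bray-Curtis on the abundances.
    """
    if cm.n_samples < 2:
        raise ValueError("need at least two samples")
    zero = np.flatnonzero(cm.abundance.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(f"all-zero sample: {cm.sample_ids[zero[0]]!r}")
    if mode == "binary":
        data = cm.presence()
    elif mode == "abundance":
        data = cm.abundance
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sim = 1.0 - squareform(pdist(data, metric="braycurtis"))
    return SimilarityMatrix(list(cm.sample_ids), sim, kind="community_sorensen")


def habitat_similarity(hm: HabitatMatrix, standardize: bool = True) -> SimilarityMatrix:
    """Habitat similarity E_d = 1 - Euc_d / Euc_max.

    Distances are Euclidean on standardized variables, pairwise-complete
    over missing values: each pair uses its shared complete variables,
    rescaled by sqrt(p / p_shared) to stay comparable across pairs.  Pairs
    sharing no complete variable get a missing similarity (flagged with a
    warning).  By construction the maximal-distance pair scores exactly 0.
    """
    if not hm.standardized and standardize:
        from .data_io import standardize_habitat
        hm = standardize_habitat(hm)
        warnings.warn("habitat matrix standardized internally")
    X = hm.values
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    diff = X[:, None, :] - X[None, :, :]          # (n, n, p), nan where missing
    shared = np.isfinite(diff).sum(axis=2)
    with np.errstate(invalid="ignore"):
        msq = np.nanmean(np.square(diff), axis=2)  # mean squared difference
    dist = np.sqrt(p * msq)
    if np.any(shared[np.tril_indices(n, -1)] == 0):
        warnings.warn("pairs with no shared complete habitat variables; "
                      "similarity left missing")
    dmax = np.nanmax(dist)
    if dmax == 0:
        sim = np.ones_like(dist)
    else:
        sim = 1.0 - dist / dmax
    return SimilarityMatrix(list(hm.sample_ids), sim, kind="habitat_euclidean")


def geographic_distance(sites: SiteTable, sample_ids=None,
                        method: str = "planar") -> np.ndarray:
    """Pairwise inter-sample distance matrix in metres.

    ``planar`` (default) assumes projected x/y coordinates in metres;
    ``haversine`` treats x as longitude and y as latitude in degrees, for
    callers who have not projected.
    """
    coords = sites.coords(sample_ids)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate")
    if method == "planar":
        return squareform(pdist(coords, metric="euclidean"))
    if method == "haversine":
        lon, lat = np.radians(coords[:, 0]), np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (np.sin(dlat / 2) ** 2
             + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
        return 2 * 6_371_000.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DecayConfig:
    """How to fit the distance-decay regression.

    ``binned=True`` regresses log10(mean similarity per distance bin) on
    log10(bin midpoint), weighted by pair counts; ``binned=False`` is an
    unweighted regression on raw pairs.  ``transform`` chooses log10-log10
    (power law, default) or linear-log (similarity vs log10 distance).
    """

    binned: bool = True
    n_bins: int = 20
    transform: str = "loglog"  # or "linear_log"
    weighted: bool = True
    min_points: int = 3


@dataclass
class DistanceDecayFit:
    z: float
    b: float
    r_squared: float
    n_pairs: int
    weighting: str
    distance_transform: str
    n_points: int = 0


def _pair_arrays(sim: SimilarityMatrix, dist: np.ndarray):
    n = len(sim.sample_ids)
    if dist.shape != (n, n):
        raise ValueError("similarity and distance matrices not aligned")
    i, j = np.tril_indices(n, k=-1)
    return sim.values[i, j], dist[i, j]


def fit_distance_decay(sim: SimilarityMatrix, dist: np.ndarray,
                       config: DecayConfig | None = None) -> DistanceDecayFit:
    """Fit the turnover slope z of similarity against geographic distance.

    Pairs at zero distance (same site) and pairs with missing or zero
    similarity are excluded from the log fit.
    """
    config = config or DecayConfig()
    s, d = _pair_arrays(sim, dist)
    ok = np.isfinite(s) & (d > 0)
    if config.transform == "loglog":
        ok &= s > 0
    s, d = s[ok], d[ok]
    n_pairs = int(s.size)
    if n_pairs < config.min_points:
        raise ValueError(f"only {n_pairs} usable pairs")

    if config.binned:
        edges = np.logspace(np.log10(d.min()), np.log10(d.max()),
                            config.n_bins + 1)
        edges[-1] *= 1 + 1e-12
        which = np.digitize(d, edges) - 1
        xs, ys, ws = [], [], []
        for b in range(config.n_bins):
            m = which == b
            if not m.any():
                continue
            mean_s = s[m].mean()
            if config.transform == "loglog" and mean_s <= 0:
                warnings.warn(f"dropping bin {b}: zero mean similarity")
                continue
            xs.append(np.sqrt(edges[b] * edges[b + 1]))  # geometric midpoint
            ys.append(mean_s)
            ws.append(m.sum())
        x = np.log10(np.asarray(xs))
        y = np.asarray(ys)
        w = np.asarray(ws, dtype=float)
        if x.size < config.min_points:
            raise ValueError(f"only {x.size} usable distance bins")
        weighting = "pair_count" if config.weighted else "none"
        if not config.weighted:
            w = np.ones_like(w)
    else:
        x = np.log10(d)
        y = s
        w = np.ones_like(x)
        weighting = "none"

    if config.transform == "loglog":
        y = np.log10(y)
    elif config.transform != "linear_log":
        raise ValueError(f"unknown transform {config.transform!r}")

    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    return DistanceDecayFit(
        z=float(fit.params[1]), b=float(fit.params[0]),
        r_squared=float(fit.rsquared), n_pairs=n_pairs,
        weighting=weighting, distance_transform=config.transform,
        n_points=int(x.size),
    )


@dataclass
class NeighborhoodSummary:
    focal_site_id: str
    mean_chi: float
    mean_E: float
    z_community: float
    z_habitat: float
    n_neighbors: int
    flagged: bool = False


def neighborhood_analysis(sim_comm: SimilarityMatrix, sim_hab: SimilarityMatrix,
                          dist: np.ndarray, radius: float = 140_000.0,
                          min_neighbors: int = 5,
                          config: DecayConfig | None = None) -> list:
    """Local turnover summaries within a fixed radius of each focal sample.

    For every focal sample, all samples within ``radius`` metres form the
    neighbourhood; the mean community and habitat similarities over all
    pairs in the neighbourhood and both distance-decay slopes are
    reported.  Records with fewer than ``min_neighbors`` neighbours (or
    failed local fits) are flagged so downstream regressions can exclude
    them.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if sim_comm.sample_ids != sim_hab.sample_ids:
        raise ValueError("similarity matrices not aligned")
    config = config or DecayConfig(binned=False)
    ids = sim_comm.sample_ids
    n = len(ids)
    out = []
    for f in range(n):
        member = np.flatnonzero(dist[f] <= radius)
        n_neighbors = int(member.size - 1)
        flagged = n_neighbors < min_neighbors
        sub = np.ix_(member, member)
        li, lj = np.tril_indices(member.size, k=-1)
        chi = sim_comm.values[sub][li, lj]
        E = sim_hab.values[sub][li, lj]
        z_c = z_h = np.nan
        if not flagged:
            sub_ids = [ids[k] for k in member]
            d_sub = dist[sub]
            try:
                z_c = fit_distance_decay(sim_comm.subset(sub_ids), d_sub, config).z
                z_h = fit_distance_decay(sim_hab.subset(sub_ids), d_sub, config).z
            except ValueError:
                flagged = True
        out.append(NeighborhoodSummary(
            focal_site_id=ids[f],
            mean_chi=float(np.nanmean(chi)) if chi.size else np.nan,
            mean_E=float(np.nanmean(E)) if E.size else np.nan,
            z_community=z_c, z_habitat=z_h,
            n_neighbors=n_neighbors, flagged=flagged,
        ))
    return out


@dataclass
class TypeIIFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    method: str


def typeII_regression(x, y, method: str = "OLS") -> TypeIIFit:
    """Model-II regression: OLS, major axis (MA) or standardized major
    axis (SMA).

    The p-value is the two-tailed test of the Pearson correlation, as in
    standard model-II regression software; R^2 is the squared correlation
    for every method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    r, p = pearsonr(x, y)
    if method == "OLS":
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    elif method == "SMA":
        sy, sx = np.std(y, ddof=1), np.std(x, ddof=1)
        slope = np.sign(r if r != 0 else 1.0) * sy / sx
    elif method == "MA":
        cov = np.cov(x, y, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]  # principal axis
        slope = v[1] / v[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = float(np.mean(y) - slope * np.mean(x))
    return TypeIIFit(float(slope), intercept, float(r ** 2), float(p), method)


def mantel_test(simA: SimilarityMatrix, simB: SimilarityMatrix,
                n_perm: int = 9999, seed: int | None = None) -> tuple:
    """Mantel association between two similarity matrices.

    Pearson correlation of the strict lower triangles; the two-sided
    permutation p-value shuffles the sample labels of the second matrix.
    """
    if simA.sample_ids != simB.sample_ids:
        raise ValueError("matrices must share the same sample set and order")
    a = simA.lower_triangle()
    B = simB.values
    n = len(simA.sample_ids)
    i, j = np.tril_indices(n, k=-1)
    b = B[i, j]
    r_obs = pearsonr(a, b)[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][i, j]
        if abs(pearsonr(a, bp)[0]) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(r_obs), float(p)
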