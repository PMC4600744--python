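"""Spatial dependence of community and habitat structure.

Principal-component scores of a samples x variables matrix are treated as
regionalized variables; their empirical semivariograms (Matheron
estimator) are fitted with spherical or exponential models by weighted
least squares (Cressie weights), and spatial dependence is classified
from the nugget/sill ratio: <25% strong, 25-75% moderate, >75% weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA


def pc_scores(matrix, n_components: int = 5, scale: bool = False):
    """First ``n_components`` principal-component score vectors.

    Columns are centred (and optionally scaled to unit variance, the usual
    choice for habitat variables on heterogeneous units).  Sign convention:
    each component's largest-magnitude loading is positive, so scores are
    reproducible across runs.  Returns (scores, explained_variance_ratio);
    if the matrix rank is below ``n_components`` the available components
    are returned with a warning.
    """
    X = np.asarray(getattr(matrix, "values", getattr(matrix, "abundance", matrix)),
                   dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"matrix rank {rank} < {n_components}; returning {k} components")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for c in range(k):
        j = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, j] < 0:
            scores[:, c] *= -1
    return scores, pca.explained_variance_ratio_


@dataclass
class EmpiricalVariogram:
    lag_midpoints: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self):
        if np.any(self.semivariance < 0) or np.any(self.pair_counts < 1):
            raise ValueError("invalid empirical variogram")


def empirical_variogram(values, coords, n_lags: int = 12,
                        max_lag: float | None = None) -> EmpiricalVariogram:
    """Matheron semivariance estimator in distance-lag bins.

    gamma(h) = mean over pairs in the bin of (v_i - v_j)^2 / 2.  Default
    ``max_lag`` is half the maximum inter-site distance; empty bins are
    dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least two sites")
    d = pdist(coords)
    if max_lag is None:
        max_lag = d.max() / 2
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    i, j = np.triu_indices(values.size, k=1)
    sq = 0.5 * (values[i] - values[j]) ** 2
    edges = np.linspace(0, max_lag, n_lags + 1)
    which = np.digitize(d, edges) - 1
    mids, gamma, counts = [], [], []
    for b in range(n_lags):
        m = which == b
        if not m.any():
            warnings.warn(f"empty variogram lag bin {b}")
            continue
        mids.append(0.5 * (edges[b] + edges[b + 1]))
        gamma.append(sq[m].mean())
        counts.append(int(m.sum()))
    return EmpiricalVariogram(np.asarray(mids), np.asarray(gamma),
                              np.asarray(counts))


def spherical(h, c0, c1, a):
    h = np.asarray(h, dtype=float)
    inside = np.clip(h / a, 0, 1)
    return c0 + c1 * (1.5 * inside - 0.5 * inside ** 3)


def exponential(h, c0, c1, a):
    h = np.asarray(h, dtype=float)
    return c0 + c1 * (1.0 - np.exp(-h / a))


_MODELS = {"spherical": spherical, "exponential": exponential}


@dataclass
class VariogramModel:
    model: str
    nugget: float          # c0
    partial_sill: float    # c1
    range_: float          # a
    converged: bool = True

    @property
    def nugget_sill_ratio(self) -> float:
        total = self.nugget + self.partial_sill
        return 100.0 * self.nugget / total if total > 0 else 100.0

    @property
    def dependence_class(self) -> str:
        return classify_dependence(self.nugget_sill_ratio)

    def __call__(self, h):
        return _MODELS[self.model](h, self.nugget, self.partial_sill, self.range_)


def fit_variogram(ev: EmpiricalVariogram, model: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of a variogram model.

    Cressie weights N(h) / gamma_model(h)^2 downweight poorly estimated,
    high-semivariance lags.  Several starting points are tried; negative
    parameter estimates are clipped to zero with a ``converged=False``
    flag.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if ev.lag_midpoints.size < 4:
        raise ValueError("need at least 4 usable lags")
    fn = _MODELS[model]
    h, g, npairs = ev.lag_midpoints, ev.semivariance, ev.pair_counts.astype(float)
    sill0 = max(g.max(), 1e-12)
    hmax = h.max()

    def residuals(p):
        c0, c1, a = p
        mod = np.maximum(fn(h, c0, c1, a), 1e-12 * sill0)
        w = np.sqrt(npairs) / mod
        return w * (g - mod)

    best = None
    for c0_0 in (0.0, 0.5 * g[0]):
        for a_0 in (hmax / 3, 2 * hmax / 3, hmax):
            try:
                res = least_squares(
                    residuals, x0=[c0_0, max(sill0 - c0_0, 1e-6 * sill0), a_0],
                    bounds=([0, 0, 1e-9 * hmax], [np.inf, np.inf, 10 * hmax]),
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("variogram fit failed from all starting points")
    c0, c1, a = best.x
    converged = bool(best.success)
    if c0 < 0 or c1 < 0:
        c0, c1 = max(c0, 0.0), max(c1, 0.0)
        converged = False
    return VariogramModel(model, float(c0), float(c1), float(a), converged)


def classify_dependence(ratio: float) -> str:
    """Cambardella spatial-dependence class from the nugget/sill ratio (%).

    <25 strong, 25-75 (closed interval) moderate, >75 weak.
    """
    if not 0 <= ratio <= 100:
        raise ValueError("ratio must be a percentage in [0, 100]")
    if ratio < 25:
        return "strong"
    if ratio <= 75:
        return "moderate"
    return "weak"


def fit_variogram_ml(values, coords, model: str = "spherical") -> VariogramModel:
    """Gaussian-likelihood fit of (c0, c1, a) from the raw field values.

    Maximizes the multivariate-normal log-likelihood of the (demeaned)
    values with covariance ``c1 * rho(h) + c0 * I``, where rho is the
    correlation function implied by the chosen variogram model.  Intended
    for modest site counts; the WLS fit on the empirical variogram is the
    default route.
    """
    from scipy.optimize import minimize
    from scipy.spatial.distance import squareform

    values = np.asarray(values, dtype=float)
    values = values - values.mean()
    H = squareform(pdist(np.asarray(coords, dtype=float)))
    n = values.size
    var0 = values.var(ddof=1)
    fn = _MODELS[model]

    def nll(logp):
        c0, c1, a = np.exp(logp)
        sill = c0 + c1
        cov = sill - fn(H, c0, c1, a)   # gamma -> covariance
        np.fill_diagonal(cov, sill)
        try:
            L = np.linalg.cholesky(cov + 1e-10 * sill * np.eye(n))
        except np.linalg.LinAlgError:
            return 1e12
        alpha = np.linalg.solve(L, values)
        return float(np.sum(np.log(np.diag(L))) + 0.5 * alpha @ alpha)

    hmax = H.max()
    res = minimize(nll, x0=np.log([0.1 * var0 + 1e-9, 0.9 * var0 + 1e-9, hmax / 3]),
                   method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8,
                                                  "maxiter": 2000})
    c0, c1, a = np.exp(res.x)
    return VariogramModel(model, float(c0), float(c1), float(a), bool(res.success))
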