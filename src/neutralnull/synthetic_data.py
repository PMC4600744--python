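"""Synthetic landscapes with controlled ground truth.

Everything the pipeline consumes can be generated here: gridded or random
site layouts with several vertical soil layers, habitat variables drawn
as Gaussian random fields with exponential spatial covariance, and
community matrices assembled anywhere on the continuum from pure neutral
(``niche_strength = 0``) to pure niche assembly (``niche_strength = 1``).

The default configuration emulates the sampling regime of a national
20 km soil grid: 183 sites, four layers per site, 51 habitat variables,
a biodiversity number theta of ~40 with per-layer immigration declining
with depth, and habitat spatial autocorrelation with a ~140 km range.
Deeper layers get larger habitat variance and lower immigration, the
regime reported for vertically structured soils.

Communities mix two recruitment routes at the individual level: a share
``niche_strength`` of the J individuals is drawn multinomially from a
Gaussian species response to the first habitat gradient (random optima,
common width), the remainder is a without-replacement subsample of a
neutral urn community, so ``niche_strength = 0`` reproduces the neutral
simulator exactly.  A T-RFLP-style observation layer maps taxa to
fragment sizes, coalescing taxa that co-bin, and applies the standard
peak filters, emulating the limited taxonomic resolution of fingerprint
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_io import (
    LAND_USE_CLASSES,
    CommunityMatrix,
    HabitatMatrix,
    PeakTable,
    SiteTable,
    bin_fragments,
    filter_peaks,
)
from .neutral_model import simulate_neutral


@dataclass
class ScenarioConfig:
    """Ground-truth parameters of a synthetic landscape."""

    n_sites: int = 183
    layout: str = "grid"              # or "random"
    grid_spacing: float = 20_000.0    # metres
    n_layers: int = 4
    theta: float = 40.0
    I: tuple = (18.60, 14.43, 10.12, 11.88)  # per layer; scalar allowed
    J: int = 1000
    niche_strength: float = 0.5       # lambda in [0, 1]
    niche_width: float = 0.25         # response width as fraction of gradient range
    n_habitat_vars: int = 51
    habitat_range: float = 140_000.0  # autocorrelation range, metres
    habitat_nugget: float = 0.3       # spatially unstructured variance fraction
    layer_var_multiplier: float = 1.3  # habitat variance inflation per layer
    land_use_labels: tuple = LAND_USE_CLASSES
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.niche_strength <= 1.0:
            raise ValueError("niche_strength must be in [0, 1]")
        if min(self.n_sites, self.n_layers, self.J, self.n_habitat_vars) < 1:
            raise ValueError("all sizes must be positive")
        if self.layout not in ("grid", "random"):
            raise ValueError(f"unknown layout {self.layout!r}")

    def I_for_layer(self, layer: int) -> float:
        I = np.atleast_1d(np.asarray(self.I, dtype=float))
        return float(I[(layer - 1) % I.size])

    def _seeds(self, n: int, stream: int):
        ss = np.random.SeedSequence([int(self.seed), stream])
        return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def sample_id(site: int, layer: int) -> str:
    return f"site{site:03d}_L{layer}"


def make_sites(config: ScenarioConfig) -> SiteTable:
    """Site layout with per-layer samples and spatially blocked land use.

    Grid sites fill a square lattice row-major at ``grid_spacing``; random
    layouts draw uniform coordinates over the same extent.  Land-use
    classes are assigned as contiguous strips along x, so land use
    correlates with space as in real landscapes.
    """
    n = config.n_sites
    rng = np.random.default_rng(config._seeds(1, 0)[0])
    if config.layout == "grid":
        side = int(np.ceil(np.sqrt(n)))
        ii, jj = np.divmod(np.arange(n), side)
        x = jj * config.grid_spacing
        y = ii * config.grid_spacing
    else:
        side = int(np.ceil(np.sqrt(n)))
        extent = side * config.grid_spacing
        x = rng.uniform(0, extent, n)
        y = rng.uniform(0, extent, n)
    labels = list(config.land_use_labels)
    strip = np.clip(
        np.searchsorted(np.quantile(x, np.linspace(0, 1, len(labels) + 1))[1:-1],
                        x, side="right"),
        0, len(labels) - 1,
    )
    rows = []
    for s in range(n):
        for layer in range(1, config.n_layers + 1):
            rows.append({
                "sample_id": sample_id(s, layer),
                "site_id": f"site{s:03d}",
                "x": float(x[s]),
                "y": float(y[s]),
                "layer": layer,
                "land_use": labels[strip[s]],
            })
    return SiteTable(pd.DataFrame(rows))


def make_habitat(sites: SiteTable, config: ScenarioConfig) -> HabitatMatrix:
    """Habitat variables as Gaussian random fields over the sites.

    Each variable, independently per layer, has covariance
    ``(1 - nugget) * exp(-h / range) + nugget * delta(h)`` scaled by a
    per-layer variance multiplier, so deeper layers show larger
    sample-to-sample variation.
    """
    frame = sites.frame
    site_ids = list(dict.fromkeys(frame["site_id"]))
    coords = (frame.drop_duplicates("site_id")
              .set_index("site_id").loc[site_ids, ["x", "y"]].to_numpy(float))
    h = squareform(pdist(coords))
    n = len(site_ids)
    rho = max(config.habitat_range, 1e-9)
    C = (1 - config.habitat_nugget) * np.exp(-h / rho) \
        + config.habitat_nugget * np.eye(n)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n))

    layers = sorted(set(frame["layer"]))
    seeds = config._seeds(len(layers), 1)
    all_ids, blocks = [], []
    for seed, layer in zip(seeds, layers):
        rng = np.random.default_rng(seed)
        sd = config.layer_var_multiplier ** (layer - 1)
        vals = sd * (L @ rng.standard_normal((n, config.n_habitat_vars)))
        blocks.append(vals)
        all_ids += [sample_id(s, layer) for s in range(n)]
    names = [f"var{v:02d}" for v in range(config.n_habitat_vars)]
    return HabitatMatrix(all_ids, names, np.vstack(blocks), standardized=False)


def _niche_relative(habitat_col: np.ndarray, meta_abundance: np.ndarray,
                    width_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian species responses to one gradient -> samples x species
    relative abundances.

    Each species' response is its metacommunity relative abundance times a
    Gaussian filter around a random optimum with common width, so niche
    assembly preserves a realistic uneven abundance distribution while
    selecting different subsets of the pool along the gradient.
    """
    lo, hi = habitat_col.min(), habitat_col.max()
    span = max(hi - lo, 1e-12)
    optima = rng.uniform(lo, hi, meta_abundance.size)
    sigma = width_frac * span
    w = np.exp(-0.5 * ((habitat_col[:, None] - optima[None, :]) / sigma) ** 2)
    w = w * (meta_abundance / meta_abundance.sum())[None, :]
    w += 1e-300  # guard fully filtered samples
    return w / w.sum(axis=1, keepdims=True)


def make_communities(sites: SiteTable, habitat: HabitatMatrix,
                     config: ScenarioConfig) -> CommunityMatrix:
    """Neutral / niche mixture communities, one per sample.

    Per layer: a shared-metacommunity neutral simulation at the layer's
    immigration parameter supplies the species pool and the neutral
    component; each sample then receives ``round(lambda * J)`` individuals
    from the niche response to the layer's first habitat variable and the
    remaining individuals as a without-replacement subsample of its
    neutral community.  Layers are independent metacommunities, so taxon
    ids are layer-prefixed.
    """
    frame = sites.frame
    layers = sorted(set(frame["layer"]))
    lam = config.niche_strength
    seeds = config._seeds(2 * len(layers), 2)
    sample_rows, sample_ids, taxa_all = [], [], []
    hab = habitat.to_frame()
    for li, layer in enumerate(layers):
        ids = [r["sample_id"] for _, r in frame.iterrows() if r["layer"] == layer]
        n_comm = len(ids)
        neutral = simulate_neutral(
            n_comm, config.J, config.theta, config.I_for_layer(layer),
            seed=seeds[2 * li], shared_metacommunity=True,
        )
        counts = neutral.abundance.astype(np.int64)
        if lam > 0:
            rng = np.random.default_rng(seeds[2 * li + 1])
            grad = hab.loc[ids, habitat.variable_names[0]].to_numpy(float)
            meta = counts.sum(axis=0).astype(float)
            p_niche = _niche_relative(grad, meta, config.niche_width, rng)
            k_niche = int(round(lam * config.J))
            mixed = np.empty_like(counts)
            for c in range(n_comm):
                keep = rng.multivariate_hypergeometric(
                    counts[c], config.J - k_niche)
                mixed[c] = keep + rng.multinomial(k_niche, p_niche[c])
            counts = mixed
        taxa = [f"L{layer}_{t}" for t in neutral.taxon_ids]
        sample_rows.append(counts)
        sample_ids += ids
        taxa_all.append(taxa)

    n_total_taxa = sum(len(t) for t in taxa_all)
    out = np.zeros((len(sample_ids), n_total_taxa), dtype=np.int64)
    col = 0
    row = 0
    for counts, taxa in zip(sample_rows, taxa_all):
        out[row:row + counts.shape[0], col:col + len(taxa)] = counts
        row += counts.shape[0]
        col += len(taxa)
    flat_taxa = [t for taxa in taxa_all for t in taxa]
    present = out.sum(axis=0) > 0
    return CommunityMatrix(sample_ids,
                           [t for t, k in zip(flat_taxa, present) if k],
                           out[:, present], is_counts=True)


def add_fingerprint_noise(cm: CommunityMatrix, config: ScenarioConfig,
                          height_per_count: float = 10.0,
                          clustering_threshold: float = 0.99,
                          min_size: float = 35.0, max_size: float = 550.0,
                          min_height: float = 50.0, min_frac: float = 0.02,
                          apply_filters: bool = True):
    """Emulate T-RFLP observation of a true community matrix.

    Each taxon is assigned a uniform random fragment size in the analysis
    window; peak height is proportional to abundance.  The peak table is
    passed through the standard filters and fragment binning, which
    coalesces taxa landing in the same bin — fingerprint observation loses
    both rare taxa (detection thresholds) and taxonomic resolution.
    Returns ``(peaks, observed)`` where ``observed`` is the post-filter
    relative-abundance matrix.
    """
    if not cm.is_counts:
        raise ValueError("fingerprint emulation expects integer counts")
    rng = np.random.default_rng(config._seeds(1, 3)[0])
    sizes = rng.uniform(min_size, max_size, cm.n_taxa)
    rows = []
    for i, sid in enumerate(cm.sample_ids):
        pos = np.flatnonzero(cm.abundance[i] > 0)
        for j in pos:
            rows.append({
                "sample_id": sid,
                "fragment_size": float(sizes[j]),
                "height": float(cm.abundance[i, j] * height_per_count),
            })
    peaks = PeakTable(pd.DataFrame(rows))
    if apply_filters:
        peaks = filter_peaks(peaks, min_size=min_size, max_size=max_size,
                             min_height=min_height, min_frac=min_frac)
    observed = bin_fragments(peaks, clustering_threshold=clustering_threshold,
                             min_size=min_size, max_size=max_size)
    return peaks, observed
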