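"""Similarity indices, distance decay, neighbourhoods, model-II fits, Mantel."""

import numpy as np
import pandas as pd
import pytest

from neutralnull.data_io import CommunityMatrix, HabitatMatrix, SiteTable
from neutralnull.turnover import (
    DecayConfig,
    SimilarityMatrix,
    fit_distance_decay,
    geographic_distance,
    habitat_similarity,
    mantel_test,
    neighborhood_analysis,
    sorensen_similarity,
    typeII_regression,
)


def sim_from(values, kind="community_sorensen"):
    values = np.asarray(values, dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(ids, values, kind=kind)


def grid_sites(nx, ny, spacing):
    rows = []
    for i in range(ny):
        for j in range(nx):
            rows.append({"sample_id": f"s{i}_{j}", "site_id": f"s{i}_{j}",
                         "x": j * spacing, "y": i * spacing,
                         "layer": 1, "land_use": "bog"})
    return SiteTable(pd.DataFrame(rows))


class TestSorensen:
    def test_identical_and_disjoint(self):
        cm = CommunityMatrix(["a", "b", "c"], list("wxyz"),
                             [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 3, 4]])
        sim = sorensen_similarity(cm)
        assert sim.values[0, 1] == 1.0
        assert sim.values[0, 2] == 0.0

    def test_hand_computed_binary_value(self):
        # A={w,x,y}, B={x,y,z}: 2*2 / (3+3)
        cm = CommunityMatrix(["A", "B"], list("wxyz"),
                             [[5, 1, 2, 0], [0, 9, 1, 4]])
        sim = sorensen_similarity(cm, mode="binary")
        assert sim.values[0, 1] == pytest.approx(2 / 3)

    def test_abundance_mode_is_one_minus_bray_curtis(self):
        cm = CommunityMatrix(["A", "B"], ["t1", "t2"], [[6, 2], [2, 2]])
        sim = sorensen_similarity(cm, mode="abundance")
        # BC = (|6-2| + |2-2|) / (8 + 4) = 1/3
        assert sim.values[0, 1] == pytest.approx(2 / 3)

    def test_values_bounded_and_symmetric(self):
        rng = np.random.default_rng(0)
        cm = CommunityMatrix([f"s{i}" for i in range(8)],
                             [f"t{j}" for j in range(30)],
                             rng.poisson(2.0, (8, 30)) + np.eye(8, 30))
        sim = sorensen_similarity(cm)
        assert np.all(sim.values >= 0) and np.all(sim.values <= 1)
        np.testing.assert_allclose(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)


class TestHabitatSimilarity:
    def test_one_dimensional_formula(self):
        # pre-standardized values {0,1,2}: distances {1,1,2}, Euc_max=2
        hm = HabitatMatrix(["a", "b", "c"], ["v"], [[0.0], [1.0], [2.0]],
                           standardized=True)
        E = habitat_similarity(hm, standardize=False)
        assert E.values[0, 1] == pytest.approx(0.5)
        assert E.values[1, 2] == pytest.approx(0.5)
        assert E.values[0, 2] == pytest.approx(0.0)

    def test_identical_rows_score_one_and_max_pair_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 4))
        vals[1] = vals[0]
        hm = HabitatMatrix([f"s{i}" for i in range(6)],
                           [f"v{j}" for j in range(4)], vals, standardized=True)
        E = habitat_similarity(hm, standardize=False)
        assert E.values[0, 1] == pytest.approx(1.0)
        assert E.lower_triangle().min() == pytest.approx(0.0)

    def test_pairwise_complete_with_missing(self):
        vals = np.array([[0.0, 0.0], [1.0, np.nan], [2.0, 1.0]])
        hm = HabitatMatrix(["a", "b", "c"], ["v1", "v2"], vals, standardized=True)
        E = habitat_similarity(hm, standardize=False)
        # a-b distance uses v1 only, rescaled by sqrt(2/1)
        d_ab = np.sqrt(2.0)
        d_ac = np.sqrt(4.0 + 1.0)
        assert E.values[0, 1] == pytest.approx(1 - d_ab / d_ac)


class TestGeographicDistance:
    def test_pythagorean_triple(self):
        sites = SiteTable(pd.DataFrame({
            "sample_id": ["a", "b"], "site_id": ["a", "b"],
            "x": [0.0, 3000.0], "y": [0.0, 4000.0],
            "layer": [1, 1], "land_use": ["bog", "bog"]}))
        d = geographic_distance(sites)
        assert d[0, 1] == pytest.approx(5000.0)
        assert d[0, 0] == 0.0
        np.testing.assert_allclose(d, d.T)


class TestDistanceDecay:
    def make_power_law(self, b=-0.1, z=-0.05, n=15, scale=1.0):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 200_000, (n, 2)) * scale
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(coords))
        sim = np.ones_like(d)
        off = d > 0
        sim[off] = 10.0 ** b * d[off] ** z
        ids = [f"s{i}" for i in range(n)]
        return SimilarityMatrix(ids, sim), d

    def test_noiseless_power_law_exact(self):
        sim, d = self.make_power_law()
        fit = fit_distance_decay(sim, d, DecayConfig(binned=False))
        assert fit.z == pytest.approx(-0.05, abs=1e-12)
        assert fit.b == pytest.approx(-0.1, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_invariant_under_distance_rescaling(self):
        sim, d = self.make_power_law()
        z1 = fit_distance_decay(sim, d, DecayConfig(binned=False)).z
        z2 = fit_distance_decay(sim, d * 1000.0, DecayConfig(binned=False)).z
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_constant_similarity_gives_zero_slope(self):
        n = 10
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 1e5, (n, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(coords))
        sim = sim_from(np.full((n, n), 0.4) + 0.6 * np.eye(n))
        for binned in (True, False):
            fit = fit_distance_decay(sim, d, DecayConfig(binned=binned, n_bins=5))
            assert fit.z == pytest.approx(0.0, abs=1e-12)

    def test_binned_weighted_fit_runs(self):
        sim, d = self.make_power_law(n=40)
        fit = fit_distance_decay(sim, d, DecayConfig(binned=True, n_bins=10))
        assert fit.z < 0
        assert fit.weighting == "pair_count"

    def test_too_few_pairs_rejected(self):
        sim, d = self.make_power_law(n=3)
        with pytest.raises(ValueError, match="usable"):
            fit_distance_decay(sim, d, DecayConfig(binned=False, min_points=99))


class TestNeighborhoods:
    def setup_method(self):
        self.sites = grid_sites(10, 10, 20_000.0)
        rng = np.random.default_rng(7)
        n = 100
        v = np.clip(rng.uniform(0.2, 0.9, (n, n)), 0, 1)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = self.sites.sample_ids
        self.sim = SimilarityMatrix(ids, v)
        self.dist = geographic_distance(self.sites)

    def test_corner_site_has_44_neighbors_at_140km(self):
        recs = neighborhood_analysis(self.sim, self.sim, self.dist,
                                     radius=140_000.0)
        corner = [r for r in recs if r.focal_site_id == "s0_0"][0]
        assert corner.n_neighbors == 44

    def test_radius_beyond_extent_reproduces_global_fit(self):
        recs = neighborhood_analysis(self.sim, self.sim, self.dist,
                                     radius=1e9)
        zs = {round(r.z_community, 12) for r in recs}
        assert len(zs) == 1
        global_z = fit_distance_decay(self.sim, self.dist,
                                      DecayConfig(binned=False)).z
        assert zs.pop() == pytest.approx(global_z, abs=1e-12)

    def test_tiny_radius_flags_everything(self):
        recs = neighborhood_analysis(self.sim, self.sim, self.dist,
                                     radius=1.0)
        assert all(r.flagged for r in recs)


class TestTypeII:
    def test_exact_line_all_methods(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        for method in ("OLS", "MA", "SMA"):
            fit = typeII_regression(x, y, method=method)
            assert fit.slope == pytest.approx(2.0)
            assert fit.intercept == pytest.approx(1.0)
            assert fit.r_squared == pytest.approx(1.0)
            assert fit.method == method

    def test_sma_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        fit = typeII_regression(x, y, method="SMA")
        r = np.corrcoef(x, y)[0, 1]
        expected = np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1)
        assert fit.slope == pytest.approx(expected)

    def test_independent_noise_ci_covers_zero(self):
        # OLS slope t-CI should cover 0 in >= 90% of replicates
        rng = np.random.default_rng(11)
        from scipy.stats import linregress
        hits = 0
        reps = 50
        for _ in range(reps):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            fit = linregress(x, y)
            lo = fit.slope - 1.96 * fit.stderr
            hi = fit.slope + 1.96 * fit.stderr
            hits += lo <= 0 <= hi
        assert hits / reps >= 0.85

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            typeII_regression([1, 1, 1], [1, 2, 3])


class TestMantel:
    def random_sim(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 1, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return sim_from(v)

    def test_self_correlation_is_one(self):
        a = self.random_sim(12, 0)
        r, p = mantel_test(a, a, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_affine_inverse_is_minus_one(self):
        a = self.random_sim(12, 2)
        b = sim_from(np.where(np.eye(12, dtype=bool), 1.0, 1.0 - a.values))
        r, _ = mantel_test(a, b, n_perm=49, seed=1)
        assert r == pytest.approx(-1.0)

    def test_p_invariant_under_joint_relabeling(self):
        a = self.random_sim(10, 3)
        b = self.random_sim(10, 4)
        r1, p1 = mantel_test(a, b, n_perm=999, seed=9)
        perm = np.random.default_rng(5).permutation(10)
        ids = [a.sample_ids[i] for i in perm]
        a2 = sim_from(a.values[np.ix_(perm, perm)])
        b2 = sim_from(b.values[np.ix_(perm, perm)])
        a2.sample_ids = ids
        b2.sample_ids = ids
        r2, p2 = mantel_test(a2, b2, n_perm=999, seed=9)
        assert r1 == pytest.approx(r2)
        # p-values come from the same permutation distribution; allow ~4 sigma
        # of Monte-Carlo noise at n_perm = 999
        assert abs(p1 - p2) < 4 * np.sqrt(0.5 * 0.5 / 999)

    def test_type_I_error_rate_near_nominal(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 40
        for k in range(reps):
            a = self.random_sim(15, 100 + k)
            b = self.random_sim(15, 500 + k)
            _, p = mantel_test(a, b, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        # binomial(40, 0.05): >= 8 rejections has probability < 1e-3
        assert rejections <= 7

    def test_mismatched_ids_rejected(self):
        a = self.random_sim(5, 0)
        b = self.random_sim(5, 1)
        b.sample_ids = [f"x{i}" for i in range(5)]
        with pytest.raises(ValueError, match="sample set"):
            mantel_test(a, b, n_perm=9)
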