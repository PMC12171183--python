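import numpy as np
import pytest
from scipy.spatial import Delaunay

from imfspat.spatial import (
    RipleyResult,
    csr_envelope,
    csr_expectation,
    delaunay_summary,
    group_ripley,
    l_function,
    max_clustering_distance,
    ripley_analysis,
    ripley_k,
)
from imfspat.volumes import BoundingDomain, MusclePointCloud


def make_cloud(points, volume=None, low=None, high=None):
    points = np.asarray(points, float)
    low = points.min(axis=0) if low is None else np.asarray(low, float)
    high = points.max(axis=0) if high is None else np.asarray(high, float)
    dom = BoundingDomain(low=low, high=high)
    if volume is None:
        volume = max(dom.box_volume, 1.0)
    return MusclePointCloud(points, volume, dom)


def brute_delaunay_oracle(points):
    """Independent re-enumeration: tessellate, walk every simplex with python
    loops, collect the unique edge set and volumes via explicit determinants."""
    tri = Delaunay(points)
    edges = set()
    vols = []
    for simplex in tri.simplices:
        s = sorted(int(v) for v in simplex)
        for i in range(4):
            for j in range(i + 1, 4):
                edges.add((s[i], s[j]))
        mat = np.column_stack([points[s[k]] - points[s[0]] for k in (1, 2, 3)])
        vols.append(abs(np.linalg.det(mat)) / 6.0)
    lengths = [np.sqrt(((points[a] - points[b]) ** 2).sum()) for a, b in edges]
    return float(np.mean(lengths)), float(np.mean(vols)), len(edges)


def brute_k_oracle(points, radii, volume):
    """O(n^2) pair counting."""
    n = len(points)
    out = []
    for r in radii:
        c = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.linalg.norm(points[i] - points[j]) <= r:
                    c += 1
        out.append(volume / n ** 2 * c)
    return np.array(out)


class TestDelaunay:
    def test_unit_cube_matches_enumeration_oracle(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                           dtype=float)
        cloud = make_cloud(corners, volume=1.0)
        summ = delaunay_summary(cloud)
        mean_edge, mean_vol, n_edges = brute_delaunay_oracle(corners)
        assert summ.mean_edge_length == pytest.approx(mean_edge, abs=1e-12)
        assert summ.mean_tet_volume == pytest.approx(mean_vol, abs=1e-12)
        assert summ.n_edges == n_edges
        # all 5 (or 6) tetrahedra of a cube triangulation fill the unit volume
        assert summ.mean_tet_volume * summ.n_tetrahedra == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_clouds_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (30, 3))
        cloud = make_cloud(pts, volume=1000.0)
        summ = delaunay_summary(cloud)
        mean_edge, mean_vol, _ = brute_delaunay_oracle(pts)
        assert summ.mean_edge_length == pytest.approx(mean_edge, abs=1e-9)
        assert summ.mean_tet_volume == pytest.approx(mean_vol, abs=1e-9)

    def test_similarity_scaling(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 5, (40, 3))
        a = delaunay_summary(make_cloud(pts, volume=125.0))
        b = delaunay_summary(make_cloud(2 * pts, volume=1000.0))
        assert b.mean_edge_length == pytest.approx(2 * a.mean_edge_length, rel=1e-9)
        assert b.mean_tet_volume == pytest.approx(8 * a.mean_tet_volume, rel=1e-9)
        # normalization cancels the scale change
        assert b.normalized_mean_edge == pytest.approx(a.normalized_mean_edge, rel=1e-9)
        assert b.normalized_mean_volume == pytest.approx(a.normalized_mean_volume, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            delaunay_summary(make_cloud(np.zeros((4, 3))))

    def test_coplanar_cloud_jitter_retry(self):
        pts = np.array([[x, y, 0.0] for x in range(3) for y in range(3)])
        summ = delaunay_summary(make_cloud(pts, volume=10.0))
        assert summ.mean_edge_length > 0


class TestRipleyK:
    def test_two_point_direct_count(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], float)
        cloud = make_cloud(pts, volume=8.0, low=[0, 0, 0], high=[2, 2, 2])
        k = ripley_k(cloud, [2.0])
        assert k[0] == pytest.approx(8.0 / 4 * 2)  # V/n^2 * 2 ordered pairs

    def test_radius_below_minimum_distance_gives_zero(self):
        pts = np.array([[0, 0, 0], [5, 5, 5]], float)
        cloud = make_cloud(pts, low=[0, 0, 0], high=[10, 10, 10])
        assert ripley_k(cloud, [1.0])[0] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (25, 3))
        cloud = make_cloud(pts, low=[0, 0, 0], high=[1, 1, 1])
        radii = np.array([0.1, 0.3, 0.6])
        np.testing.assert_allclose(
            ripley_k(cloud, radii), brute_k_oracle(pts, radii, 1.0), atol=1e-9)

    def test_k_nondecreasing(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 1, (50, 3))
        cloud = make_cloud(pts, low=[0, 0, 0], high=[1, 1, 1])
        k = ripley_k(cloud, np.linspace(0.05, 1.0, 20))
        assert np.all(np.diff(k) >= 0)

    def test_invalid_radii_rejected(self):
        cloud = make_cloud(np.random.default_rng(0).uniform(0, 1, (5, 3)),
                           low=[0, 0, 0], high=[1, 1, 1])
        with pytest.raises(ValueError):
            ripley_k(cloud, [0.3, 0.2])


class TestCSREnvelope:
    def test_single_simulation_low_equals_high(self):
        dom = BoundingDomain(low=np.zeros(3), high=np.ones(3))
        low, high = csr_envelope(20, dom, [0.2, 0.4], n_sims=1, seed=0)
        np.testing.assert_allclose(low, high)

    def test_envelope_contains_closed_form_at_moderate_radius(self):
        dom = BoundingDomain(low=np.zeros(3), high=np.ones(3))
        radii = np.array([0.15])
        low, high = csr_envelope(200, dom, radii, n_sims=99, seed=3)
        csr = csr_expectation(radii)
        # uncorrected K is biased low near boundaries; the envelope is wide
        # enough to cover the closed form at a small-to-moderate radius
        assert low[0] < csr[0] < high[0] * 1.5

    def test_deterministic_for_seed(self):
        dom = BoundingDomain(low=np.zeros(3), high=np.ones(3))
        a = csr_envelope(30, dom, [0.2], n_sims=19, seed=5)
        b = csr_envelope(30, dom, [0.2], n_sims=19, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_mask_domain_sampling(self, young_phantom):
        from imfspat.volumes import mask_to_point_cloud
        from imfspat.extraction import extract_imf

        res = extract_imf(young_phantom.ff, young_phantom.muscle)
        cloud = mask_to_point_cloud(res.imf_mask, young_phantom.muscle)
        low, high = csr_envelope(30, cloud.bounding_domain, [5.0],
                                 n_sims=9, seed=0, mode="mask")
        assert np.all(high >= low)


class TestLFunction:
    def test_csr_input_centers_to_zero_in_both_modes(self):
        r = np.linspace(0.5, 3, 10)
        k = csr_expectation(r)
        np.testing.assert_allclose(l_function(k, r, "paper"), 0, atol=1e-12)
        np.testing.assert_allclose(l_function(k, r, "standard3d"), 0, atol=1e-12)

    def test_uncentered_unit_case(self):
        assert l_function([np.pi], [1.0], "paper", center=False)[0] == pytest.approx(1.0)

    def test_standard3d_closed_form_inversion(self):
        r = np.array([1.0])
        k = 4.0 / 3.0 * np.pi * r ** 3
        assert l_function(k, r, "standard3d")[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            l_function([-1.0], [1.0])


class TestMaxClusteringDistance:
    def make_result(self, radii, env_high):
        radii = np.asarray(radii, float)
        return RipleyResult(
            radii=radii,
            K=np.zeros_like(radii),
            L=np.zeros_like(radii),
            csr=csr_expectation(radii),
            envelope_low=np.zeros_like(radii),
            envelope_high=np.asarray(env_high, float),
        )

    def test_constructed_crossing_recovered(self):
        radii = np.linspace(1, 30, 59)
        csr = csr_expectation(radii)
        r_star = 17.5
        env = csr + (r_star - radii)  # linear excess, crosses exactly at 17.5
        res = self.make_result(radii, env)
        assert max_clustering_distance(res) == pytest.approx(r_star, abs=1e-9)

    def test_never_above_returns_zero_with_flag(self):
        radii = np.linspace(1, 10, 10)
        res = self.make_result(radii, csr_expectation(radii) - 1.0)
        assert max_clustering_distance(res) == 0.0
        assert res.no_clustering

    def test_above_everywhere_returns_last_radius(self):
        radii = np.linspace(1, 10, 10)
        res = self.make_result(radii, csr_expectation(radii) + 1.0)
        assert max_clustering_distance(res) == pytest.approx(10.0)


class TestPhantomClustering:
    def test_clustered_cloud_exceeds_envelope_at_small_r(self, old_phantom,
                                                         old_extraction):
        from imfspat.volumes import mask_to_point_cloud

        cloud = mask_to_point_cloud(old_extraction.imf_mask, old_phantom.muscle)
        radii = np.arange(2.0, 12.0, 2.0)
        res = ripley_analysis(cloud, radii, n_sims=39, seed=0)
        assert np.any(res.K[:3] > res.envelope_high[:3])
        assert res.max_clustering_distance > 0

    def test_group_ripley_envelope_rule(self):
        radii = np.linspace(1, 10, 19)
        csr = csr_expectation(radii)
        curves = np.stack([csr * f for f in (1.2, 1.4, 1.6)])
        res = group_ripley(curves, radii)
        assert res.envelope_source == "participants"
        assert res.max_clustering_distance == pytest.approx(10.0)
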