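"""Cluster segmentation, alpha shapes, local density, nanocluster detection."""

import numpy as np
import pytest
from dataclasses import replace

from calyxnano.clusters import (
    alpha_shape,
    alpha_shape_volume,
    cluster_report,
    detect_nanoclusters,
    local_density,
    make_synaptic_cluster,
    nearest_neighbor_distances,
    remove_background,
)
from calyxnano.localizations import LocalizationSet
from calyxnano.synth import SyntheticClusterSpec, generate_synaptic_cluster


def brute_force_nnd(xyz):
    d = np.linalg.norm(xyz[:, None] - xyz[None], axis=2)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_counts(xyz, radius):
    d = np.linalg.norm(xyz[:, None] - xyz[None], axis=2)
    np.fill_diagonal(d, np.inf)
    return (d <= radius).sum(axis=1)


class TestNearestNeighborDistances:
    def test_matches_brute_force(self, rng):
        xyz = rng.uniform(-100, 100, size=(200, 3))
        np.testing.assert_allclose(nearest_neighbor_distances(xyz), brute_force_nnd(xyz))

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            nearest_neighbor_distances(np.zeros((1, 3)))


class TestRemoveBackground:
    def test_isolated_points_removed(self, rng):
        core = rng.uniform(-50, 50, size=(200, 3))
        # five stragglers, mutually distant and far from the core
        outliers = np.array([[300.0, 0, 0], [0, 600.0, 0], [0, 0, 900.0], [-400.0, 400.0, 0], [500.0, 0, 500.0]])
        locs = LocalizationSet(np.vstack([core, outliers]))
        kept, bg_mask = remove_background(locs)
        assert len(kept) == 200
        assert bg_mask.sum() == 5
        assert np.all(np.flatnonzero(bg_mask) >= 200)

    def test_agrees_with_brute_force_components(self, rng):
        """Kept set equals the largest single-linkage component from an O(n^2) oracle."""
        xyz = np.vstack(
            [
                rng.uniform(-40, 40, size=(120, 3)),
                rng.uniform(-20, 20, size=(40, 3)) + 500.0,
            ]
        )
        nnd = brute_force_nnd(xyz)
        cutoff = nnd.mean() + 2 * nnd.std()
        d = np.linalg.norm(xyz[:, None] - xyz[None], axis=2)
        adj = d <= cutoff
        labels = -np.ones(len(xyz), dtype=int)
        for i in range(len(xyz)):
            if labels[i] >= 0:
                continue
            stack, labels[i] = [i], i
            while stack:
                j = stack.pop()
                for k in np.flatnonzero(adj[j]):
                    if labels[k] < 0:
                        labels[k] = i
                        stack.append(k)
        largest = max(set(labels), key=lambda l: (labels == l).sum())
        kept, bg = remove_background(LocalizationSet(xyz))
        np.testing.assert_array_equal(~bg, labels == largest)

    def test_uniform_grid_fully_retained(self):
        g = np.arange(6, dtype=float)
        xyz = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T * 10.0
        kept, bg = remove_background(LocalizationSet(xyz))
        # homogeneous NND (zero variance): cutoff equals the spacing, all linked
        assert len(kept) == len(xyz)
        assert bg.sum() == 0

    def test_equal_size_tie_is_deterministic(self, rng):
        g = np.array(np.meshgrid(np.arange(4.0), np.arange(5.0), np.arange(5.0))).reshape(3, -1).T * 10.0
        a = g + np.array([30.0, 0, 0])
        b = g + np.array([2000.0, 0, 0])
        kept, _ = remove_background(LocalizationSet(np.vstack([a, b])))
        # tie broken toward the component closer to the origin
        assert len(kept) == 100
        assert kept.xyz[:, 0].mean() < 1000


class TestAlphaShape:
    def test_ball_volume_within_15_percent(self, rng):
        r = 150.0
        pts = rng.normal(size=(5000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= r * rng.uniform(size=(5000, 1)) ** (1 / 3)
        _, vol = alpha_shape_volume(pts, alpha=150.0)
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.15)

    def test_infinite_alpha_equals_convex_hull(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.uniform(0, 100, size=(300, 3))
        _, vol = alpha_shape_volume(pts, alpha=1e9)
        assert vol == pytest.approx(ConvexHull(pts).volume, rel=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            alpha_shape(np.zeros((3, 3)))
        coplanar = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2, np.zeros(10)])
        with pytest.raises(ValueError):
            alpha_shape(coplanar)

    def test_uniform_sampling_stays_inside(self, rng):
        pts = rng.uniform(0, 100, size=(400, 3))
        shape = alpha_shape(pts, alpha=150.0)
        samples = shape.sample_uniform(500, rng)
        assert len(samples) == 500
        assert shape.contains(samples).all()


class TestLocalDensity:
    def test_matches_brute_force(self, rng):
        xyz = rng.uniform(-50, 50, size=(300, 3))
        field = local_density(xyz)
        np.testing.assert_array_equal(field.counts, brute_force_counts(xyz, field.radius))

    def test_scale_free(self, rng):
        """Doubling all coordinates leaves counts unchanged: the radius tracks the NND."""
        xyz = rng.uniform(-50, 50, size=(250, 3))
        np.testing.assert_array_equal(local_density(xyz).counts, local_density(2.0 * xyz).counts)

    def test_grid_interior_counts_identical(self):
        g = np.arange(8, dtype=float)
        xyz = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T * 10.0
        field = local_density(xyz)
        interior = np.all((xyz >= 20) & (xyz <= 50), axis=1)
        assert len(np.unique(field.counts[interior])) == 1


class TestDetectNanoclusters:
    def test_planted_pair_recovered(self, two_nc_spec, two_nc_cluster):
        cluster = make_synaptic_cluster(two_nc_cluster, clean_background=False)
        ncs = detect_nanoclusters(cluster, seed=1)
        assert len(ncs) == 2
        planted = np.asarray(two_nc_spec.nanocluster_centers)
        for nc in ncs:
            d = np.min(np.hypot(nc.peak[0] - planted[:, 0], nc.peak[1] - planted[:, 1]))
            assert d < 30.0
            assert nc.localization_number >= 8
            assert nc.localization_density * nc.volume == pytest.approx(nc.localization_number)

    def test_uniform_cluster_rarely_yields_nanoclusters(self, uniform_spec):
        """False-positive rate under the 4-SD randomized null stays at or below 10%."""
        false_pos = 0
        n_trials = 25
        for s in range(n_trials):
            locs = generate_synaptic_cluster(replace(uniform_spec, seed=1000 + s, n_localizations=800))
            cluster = make_synaptic_cluster(locs, clean_background=False)
            if detect_nanoclusters(cluster, seed=s, n_null=8):
                false_pos += 1
        assert false_pos <= 0.10 * n_trials

    def test_min_member_filter(self, uniform_spec):
        """Supra-threshold groups below the membership floor are rejected."""
        locs = generate_synaptic_cluster(replace(uniform_spec, seed=5))
        cluster = make_synaptic_cluster(locs, clean_background=False)
        ncs_lenient = detect_nanoclusters(cluster, seed=2, min_locs=1, threshold_sd=2.0)
        ncs_strict = detect_nanoclusters(cluster, seed=2, min_locs=10_000, threshold_sd=2.0)
        assert len(ncs_lenient) >= 0  # lenient settings may flag noise peaks
        assert ncs_strict == []

    def test_peak_separation_enforced(self, two_nc_cluster):
        cluster = make_synaptic_cluster(two_nc_cluster, clean_background=False)
        ncs = detect_nanoclusters(cluster, seed=3, min_separation=80.0)
        peaks = np.array([nc.peak for nc in ncs])
        if len(peaks) > 1:
            d = np.linalg.norm(peaks[:, None] - peaks[None], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 80.0

    def test_determinism(self, two_nc_cluster):
        cluster = make_synaptic_cluster(two_nc_cluster, clean_background=False)
        a = detect_nanoclusters(cluster, seed=9)
        b = detect_nanoclusters(cluster, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.member_idx, y.member_idx)


class TestClusterReport:
    def test_zero_nanoclusters(self, uniform_spec):
        locs = generate_synaptic_cluster(uniform_spec)
        cluster = make_synaptic_cluster(locs, clean_background=False)
        rep = cluster_report(cluster, [])
        assert rep.n_nanoclusters == 0
        assert rep.fraction_locs_in_nc == 0.0
        assert rep.fraction_volume_in_nc == 0.0
        assert rep.density * rep.volume == pytest.approx(rep.localization_number)

    def test_fractions_bounded(self, two_nc_cluster):
        cluster = make_synaptic_cluster(two_nc_cluster, clean_background=False)
        ncs = detect_nanoclusters(cluster, seed=4)
        rep = cluster_report(cluster, ncs)
        assert 0.0 <= rep.fraction_locs_in_nc <= 1.0
        assert 0.0 <= rep.fraction_volume_in_nc <= 1.0
        assert rep.fraction_locs_in_nc > 0.2  # strongly enriched plant

    def test_volume_scaling_recovered(self, two_nc_cluster):
        """Scaling coordinates by 1.4^(1/3) scales the reported volume by 1.4."""
        c1 = make_synaptic_cluster(two_nc_cluster, clean_background=False)
        scaled = LocalizationSet(two_nc_cluster.xyz * 1.4 ** (1 / 3))
        c2 = make_synaptic_cluster(scaled, clean_background=False)
        assert c2.volume / c1.volume == pytest.approx(1.4, rel=0.05)
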