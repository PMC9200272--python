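"""En face projection and cross-channel enrichment profiles."""

import numpy as np
import pytest
from dataclasses import replace

from calyxnano.alignment import (
    average_profiles,
    cross_enrichment_profile,
    en_face_project,
    render_density_map,
)
from calyxnano.localizations import LocalizationSet
from calyxnano.synth import PairedChannelSpec, SyntheticClusterSpec, generate_paired_channels, generate_synaptic_cluster


def _flat_disc(rng, n=2000, radius=150.0, thickness=40.0):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    z = rng.uniform(-thickness / 2, thickness / 2, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def _rotation_about_x(deg):
    a = np.deg2rad(deg)
    return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


class TestEnFaceProject:
    def test_flat_disc_normal_is_z(self, rng):
        frame, xy = en_face_project(_flat_disc(rng))
        assert not frame.flagged
        assert abs(frame.rotation[2] @ np.array([0, 0, 1.0])) > 0.99
        assert xy.shape == (2000, 2)

    def test_known_rotation_recovered(self, rng):
        disc = _flat_disc(rng)
        rot = _rotation_about_x(30.0)
        frame, xy = en_face_project(disc @ rot.T)
        # the fitted normal must align with the rotated z axis
        true_normal = rot @ np.array([0, 0, 1.0])
        assert abs(frame.rotation[2] @ true_normal) > 0.99
        # in-plane variance dominates out-of-plane variance
        assert frame.variances[1] / frame.variances[2] > 5.0

    def test_spherical_cloud_flagged(self, rng):
        frame, _ = en_face_project(rng.normal(0, 50, size=(3000, 3)))
        assert frame.flagged

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            en_face_project(np.zeros((5, 3)))


class TestCrossEnrichmentProfile:
    def test_uniform_target_is_flat_at_one(self):
        xy = _flat_disc(np.random.default_rng(0), n=30_000)[:, :2]
        prof = cross_enrichment_profile(np.array([[0.0, 0.0]]), xy, r_max=140.0)
        ok = ~np.isnan(prof.values)
        assert np.allclose(prof.values[ok], 1.0, atol=0.15)

    def test_self_profile_peaks_at_zero(self):
        spec = SyntheticClusterSpec(
            n_localizations=6000, nanocluster_centers=((0.0, 0.0),), nanocluster_radius=50.0,
            enrichment_factor=6.0, background_fraction=0.0, noise_sigma_xy=0.0, noise_sigma_z=0.0, seed=2,
        )
        locs = generate_synaptic_cluster(spec)
        prof = cross_enrichment_profile(np.array([[0.0, 0.0]]), locs.xyz[:, :2])
        assert np.nanargmax(prof.values) == 0
        # non-increasing over the nanocluster scale (first four 20-nm bins)
        assert np.all(np.diff(prof.values[:4]) <= 1e-9)

    def test_aligned_pair_center_to_annulus_ratio(self):
        ref_spec = SyntheticClusterSpec(
            n_localizations=6000, nanocluster_centers=((0.0, 0.0),), nanocluster_radius=60.0,
            background_fraction=0.0, noise_sigma_xy=0.0, noise_sigma_z=0.0, seed=3,
        )
        spec = PairedChannelSpec(
            reference=ref_spec, target=replace(ref_spec, seed=8), alignment_mode="aligned", cross_enrichment=3.0
        )
        _, tgt = generate_paired_channels(spec)
        prof = cross_enrichment_profile(np.array([[0.0, 0.0]]), tgt.xyz[:, :2], r_max=140.0)
        inner = np.nanmean(prof.values[:3])  # 0-60 nm
        outer = np.nanmean(prof.values[3:7])  # 60-140 nm
        assert inner / outer == pytest.approx(3.0, rel=0.2)

    def test_offset_pair_peak_displaced(self):
        ref_spec = SyntheticClusterSpec(
            n_localizations=8000, nanocluster_centers=((0.0, 0.0),), nanocluster_radius=40.0,
            background_fraction=0.0, noise_sigma_xy=0.0, noise_sigma_z=0.0, seed=4,
        )
        spec = PairedChannelSpec(
            reference=ref_spec, target=replace(ref_spec, seed=9), alignment_mode="offset",
            offset_nm=100.0, cross_enrichment=6.0,
        )
        _, tgt = generate_paired_channels(spec)
        prof = cross_enrichment_profile(np.array([[0.0, 0.0]]), tgt.xyz[:, :2])
        peak_r = prof.bin_centers[np.nanargmax(prof.values)]
        assert peak_r == pytest.approx(100.0, abs=25.0)

    def test_independent_channels_flat_within_3se(self):
        """Monte Carlo independence null: profile within 3 SE of 1 in every bin."""
        profiles = []
        for s in range(8):
            ref_spec = SyntheticClusterSpec(
                n_localizations=2500, nanocluster_centers=((40.0, 0.0),), nanocluster_radius=50.0,
                background_fraction=0.0, noise_sigma_xy=0.0, noise_sigma_z=0.0, seed=100 + s,
            )
            spec = PairedChannelSpec(
                reference=ref_spec, target=replace(ref_spec, seed=200 + s),
                alignment_mode="independent", cross_enrichment=3.0,
            )
            _, tgt = generate_paired_channels(spec)
            profiles.append(
                cross_enrichment_profile(np.array([[40.0, 0.0]]), tgt.xyz[:, :2], r_max=140.0)
            )
        mean = average_profiles(profiles)
        ok = mean.n > 2
        dev = np.abs(mean.values[ok] - 1.0)
        assert np.all(dev <= np.maximum(3.0 * mean.se[ok], 0.05) + 0.15)

    def test_rotation_invariance(self, rng):
        """Rigidly rotating both channels leaves the en face profile unchanged."""
        spec = SyntheticClusterSpec(
            n_localizations=4000, nanocluster_centers=((50.0, 0.0),), nanocluster_radius=50.0,
            enrichment_factor=4.0, background_fraction=0.0, noise_sigma_xy=0.0, noise_sigma_z=0.0, seed=6,
        )
        locs = generate_synaptic_cluster(spec)
        rot = _rotation_about_x(37.0)

        def profile_of(xyz, peak3d):
            frame, xy = en_face_project(xyz)
            peak2d = frame.project(peak3d[None, :])
            return cross_enrichment_profile(peak2d, xy, r_max=140.0).values

        p0 = profile_of(locs.xyz, np.array([50.0, 0.0, 0.0]))
        p1 = profile_of(locs.xyz @ rot.T, rot @ np.array([50.0, 0.0, 0.0]))
        np.testing.assert_allclose(p0, p1, rtol=0.05, atol=0.03)

    def test_errors(self):
        with pytest.raises(ValueError):
            cross_enrichment_profile(np.empty((0, 2)), np.ones((5, 2)))
        with pytest.raises(ValueError):
            cross_enrichment_profile(np.array([[0.0, 0.0]]), np.empty((0, 2)))


def test_render_density_map_shape(rng):
    img, edges = render_density_map(rng.uniform(-100, 100, size=(500, 2)), pixel_nm=5.0)
    assert img.shape == (len(edges) - 1, len(edges) - 1)
    assert img.sum() > 0
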