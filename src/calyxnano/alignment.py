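"""Trans-synaptic alignment: en face projection and cross-channel enrichment.

A synapse is projected onto its own disc plane (the two principal axes of
largest variance), and the density of a target channel is profiled as a
function of lateral distance from reference-channel nanocluster peaks.
Densities are normalized to the synapse-wide mean of the target channel, so
a value of 1 means no enrichment.  Annulus areas are intersected with the
synapse footprint so edge bins are not biased low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point

DEFAULT_BIN_WIDTH = 20.0  # nm
DEFAULT_R_MAX = 200.0  # nm
PLANARITY_MIN_RATIO = 1.2


@dataclass
class EnFaceFrame:
    """Rigid frame whose first two axes span the synaptic disc plane."""

    rotation: np.ndarray  # (3, 3), rows = axes, descending variance
    origin: np.ndarray  # (3,) centroid
    variances: np.ndarray  # (3,) descending
    flagged: bool  # True when no well-defined disc plane exists

    def project(self, xyz: np.ndarray) -> np.ndarray:
        """Project 3D points to 2D coordinates in the disc plane."""
        return (np.asarray(xyz, float) - self.origin) @ self.rotation[:2].T


def en_face_project(locs) -> tuple[EnFaceFrame, np.ndarray]:
    """Principal-axes rotation of a synapse into its en face plane.

    The disc plane is spanned by the two largest-variance principal axes;
    the third axis (minimal variance) is the synapse normal.  If the
    in-plane-to-normal variance ratio is below 1.2 the cloud has no
    well-defined plane and the frame is flagged (projection still returned).
    """
    xyz = locs.xyz if hasattr(locs, "xyz") else np.asarray(locs, float)
    if len(xyz) < 10:
        raise ValueError("need at least 10 localizations for a stable plane fit")
    origin = xyz.mean(axis=0)
    cov = np.cov((xyz - origin).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    # deterministic sign convention: largest-magnitude component positive
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    flagged = bool(evals[1] / max(evals[2], 1e-300) < PLANARITY_MIN_RATIO)
    frame = EnFaceFrame(axes, origin, evals, flagged)
    return frame, frame.project(xyz)


@dataclass
class EnrichmentProfile:
    """Normalized target density vs distance from reference peaks.

    ``values`` are dimensionless (1 = synapse-mean density); ``n`` counts the
    peak-annulus samples averaged into each bin; bins with no usable annulus
    area are NaN and excluded from any further averaging.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    se: np.ndarray
    n: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_nm": self.bin_centers,
                "normalized_density": self.values,
                "se": self.se,
                "n": self.n,
            }
        )


def cross_enrichment_profile(
    ref_peaks: np.ndarray,
    target_xy: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
    footprint=None,
) -> EnrichmentProfile:
    """Target areal density in annuli around reference peaks, normalized.

    ``ref_peaks`` are 2D peak positions (nm) in the same en face frame as the
    projected target localizations ``target_xy``.  For every peak and every
    annulus [r, r + bin_width) the target count is divided by the annulus
    area clipped to the synapse footprint (default: convex hull of the
    target), then by the synapse-wide mean target density.
    """
    ref_peaks = np.atleast_2d(np.asarray(ref_peaks, float))
    target_xy = np.asarray(target_xy, float)
    if len(ref_peaks) == 0:
        raise ValueError("need at least one reference peak")
    if len(target_xy) == 0:
        raise ValueError("target channel is empty")

    if footprint is None:
        footprint = MultiPoint(target_xy).convex_hull
    mean_density = len(target_xy) / footprint.area

    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    nb = len(edges) - 1
    samples: list[list[float]] = [[] for _ in range(nb)]

    for peak in ref_peaks:
        r = np.hypot(target_xy[:, 0] - peak[0], target_xy[:, 1] - peak[1])
        counts = np.histogram(r, bins=edges)[0]
        center = Point(peak)
        outer_prev = None
        area_prev = 0.0
        for k in range(nb):
            outer = center.buffer(edges[k + 1], quad_segs=64).intersection(footprint)
            area = outer.area
            ring_area = area - area_prev
            outer_prev, area_prev = outer, area
            if ring_area <= 1e-9:
                continue
            samples[k].append(counts[k] / ring_area / mean_density)

    values = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for k, s in enumerate(samples):
        if s:
            arr = np.asarray(s)
            values[k] = arr.mean()
            n[k] = len(arr)
            se[k] = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return EnrichmentProfile(edges, values, se, n)


def average_profiles(profiles: list[EnrichmentProfile]) -> EnrichmentProfile:
    """Average per-synapse profiles bin-wise (each synapse weighted equally)."""
    if not profiles:
        raise ValueError("no profiles to average")
    edges = profiles[0].bin_edges
    stack = np.vstack([p.values for p in profiles])
    with np.errstate(invalid="ignore"):
        values = np.nanmean(stack, axis=0)
        n = np.sum(~np.isnan(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return EnrichmentProfile(edges, values, se, n)


def rescale_reference(profile: EnrichmentProfile, r_ref: float = 140.0, value_at_ref: float = 0.5) -> np.ndarray:
    """Rescale a profile so the bin containing ``r_ref`` reads ``value_at_ref``.

    Used only when exporting measured profiles as simulator placement
    densities, which are defined up to an overall scale.
    """
    k = int(np.clip(np.searchsorted(profile.bin_edges, r_ref, side="right") - 1, 0, len(profile.values) - 1))
    ref = profile.values[k]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("reference bin has no defined density")
    return profile.values * (value_at_ref / ref)


def render_density_map(xy: np.ndarray, pixel_nm: float = 5.0, sigma_nm: float = 15.0, half_extent: float = 250.0):
    """Diagnostic 2D density image (Gaussian-smoothed histogram); visualization only."""
    edges = np.arange(-half_extent, half_extent + pixel_nm, pixel_nm)
    img, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges, edges])
    return gaussian_filter(img, sigma_nm / pixel_nm), edges
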