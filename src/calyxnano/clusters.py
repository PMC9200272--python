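"""Synaptic-cluster segmentation and nanocluster detection.

The analysis chain mirrors the standard localization-microscopy workflow for
subsynaptic protein organization:

1. background removal — nearest-neighbor distances (NND) are computed, the
   mean + 2 SD of NND is used as a linkage cutoff, and only the primary
   (largest) connected subcluster is kept;
2. the synaptic-cluster border and volume come from the 3D alpha shape of
   the retained localizations (alpha = 150 nm);
3. a local density is assigned to every localization — the number of other
   localizations within 2.5x the median NND;
4. nanoclusters are localizations whose local density exceeds
   mean(LD0) + 4 x std(LD0), where LD0 is the local density of uniformly
   randomized clusters with the same point count inside the same border,
   split at density peaks no closer than 80 nm and kept only if they retain
   at least 8 members.

All distances are plain 3D Euclidean distances in nm; the anisotropic axial
precision of the input data is deliberately not rescaled (set
``z_weight`` < 1 to shrink the z axis for sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .localizations import LocalizationSet

DEFAULT_ALPHA = 150.0  # nm
NC_MIN_LOCS = 8
NC_MIN_SEPARATION = 80.0  # nm
NC_THRESHOLD_SD = 4.0
N_NULL = 20


# ---------------------------------------------------------------------------
# nearest neighbours and background removal
# ---------------------------------------------------------------------------


def nearest_neighbor_distances(xyz: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest neighbour."""
    xyz = np.asarray(xyz, float)
    if len(xyz) < 2:
        raise ValueError("need at least 2 localizations")
    d, _ = cKDTree(xyz).query(xyz, k=2)
    return d[:, 1]


def remove_background(locs: LocalizationSet) -> tuple[LocalizationSet, np.ndarray]:
    """Keep the primary subcluster; flag everything else as background.

    Localizations are linked when closer than mean(NND) + 2 sd(NND)
    (single linkage); the connected component with the most members is the
    primary subcluster.  Equal-size ties go to the component whose centroid
    is closest to the origin, which makes the choice deterministic.

    Returns the retained set and a boolean background mask aligned with the
    input.
    """
    xyz = locs.xyz
    nnd = nearest_neighbor_distances(xyz)
    cutoff = nnd.mean() + 2.0 * nnd.std()

    pairs = cKDTree(xyz).query_pairs(cutoff, output_type="ndarray")
    n = len(xyz)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)

    sizes = np.bincount(labels, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        norms = [np.linalg.norm(xyz[labels == b].mean(axis=0)) for b in best]
        primary = best[int(np.argmin(norms))]
    else:
        primary = best[0]

    keep = labels == primary
    return locs.subset(keep), ~keep


# ---------------------------------------------------------------------------
# alpha shapes
# ---------------------------------------------------------------------------


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay tetrahedron (vectorized)."""
    p = points[simplices]  # (m, 4, 3)
    a = p[:, 1:, :] - p[:, :1, :]  # (m, 3, 3)
    b = 0.5 * (p[:, 1:, :] ** 2 - p[:, :1, :] ** 2).sum(axis=2)  # (m, 3)
    det = np.linalg.det(a)
    r = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        center = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        r[ok] = np.linalg.norm(center - p[ok, 0, :], axis=1)
    return r


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    p = points[simplices]
    return np.abs(np.linalg.det(p[:, 1:, :] - p[:, :1, :])) / 6.0


@dataclass
class AlphaShape:
    """Alpha complex of a 3D point set at a fixed alpha (nm)."""

    points: np.ndarray
    alpha: float
    delaunay: Delaunay = field(repr=False)
    kept: np.ndarray = field(repr=False)  # bool per Delaunay simplex
    volume: float = 0.0
    boundary_faces: np.ndarray = field(default=None, repr=False)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        simplex = self.delaunay.find_simplex(np.asarray(pts, float))
        inside = simplex >= 0
        inside[inside] = self.kept[simplex[inside]]
        return inside

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the alpha complex, by per-tetrahedron sampling."""
        simp = self.delaunay.simplices[self.kept]
        vols = _tet_volumes(self.points, simp)
        counts = rng.multinomial(n, vols / vols.sum())
        out = []
        for s, k in zip(simp, counts):
            if k == 0:
                continue
            # uniform barycentric coordinates in a tetrahedron
            e = -np.log(rng.uniform(size=(k, 4)))
            w = e / e.sum(axis=1, keepdims=True)
            out.append(w @ self.points[s])
        pts = np.vstack(out) if out else np.empty((0, 3))
        return pts[rng.permutation(len(pts))]


def alpha_shape(xyz: np.ndarray, alpha: float = DEFAULT_ALPHA) -> AlphaShape:
    """Alpha complex of the point set: Delaunay tetrahedra with circumradius <= alpha."""
    xyz = np.asarray(xyz, float)
    if len(xyz) < 4:
        raise ValueError("alpha shape needs at least 4 points")
    try:
        tri = Delaunay(xyz)
    except QhullError as exc:  # coplanar / collinear input
        raise ValueError("degenerate point set (coplanar or collinear)") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate point set (no tetrahedra)")
    kept = _circumradii(xyz, tri.simplices) <= alpha
    if not kept.any():
        raise ValueError(f"alpha complex empty at alpha={alpha}")
    volume = float(_tet_volumes(xyz, tri.simplices[kept]).sum())

    # boundary = triangular faces used by exactly one kept tetrahedron
    faces = np.sort(
        tri.simplices[kept][:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3),
        axis=1,
    )
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    return AlphaShape(xyz, alpha, tri, kept, volume, boundary)


def alpha_shape_volume(locs, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, float]:
    """Border (boundary triangles, index triplets) and enclosed volume in nm^3."""
    xyz = locs.xyz if isinstance(locs, LocalizationSet) else np.asarray(locs, float)
    shape = alpha_shape(xyz, alpha)
    return shape.boundary_faces, shape.volume


def _robust_volume(xyz: np.ndarray, alpha: float) -> float:
    """Alpha-shape volume with convex-hull fallback for small/degenerate sets."""
    try:
        return alpha_shape(xyz, alpha).volume
    except ValueError:
        try:
            return float(ConvexHull(xyz).volume)
        except QhullError:
            return 0.0


# ---------------------------------------------------------------------------
# local density
# ---------------------------------------------------------------------------


@dataclass
class LocalDensityField:
    """Per-localization neighbour counts within ``radius`` (self excluded)."""

    counts: np.ndarray
    radius: float
    median_nnd: float


def local_density(locs, radius: float | None = None) -> LocalDensityField:
    """Number of localizations within 2.5x the median NND of each point.

    The point itself is excluded from its own count, so on a homogeneous
    Poisson cluster the counts follow the Poisson expectation
    rho * (4/3) pi radius^3.  Pass ``radius`` to reuse a radius computed on
    another point set (used for the randomized null).
    """
    xyz = locs.xyz if isinstance(locs, LocalizationSet) else np.asarray(locs, float)
    nnd = nearest_neighbor_distances(xyz)
    med = float(np.median(nnd))
    if radius is None:
        radius = 2.5 * med
    tree = cKDTree(xyz)
    counts = tree.query_ball_point(xyz, radius, return_length=True) - 1
    return LocalDensityField(counts.astype(int), float(radius), med)


# ---------------------------------------------------------------------------
# synaptic clusters and nanoclusters
# ---------------------------------------------------------------------------


@dataclass
class SynapticCluster:
    """One synapse's retained localizations with border and volume."""

    locs: LocalizationSet
    shape: AlphaShape = field(repr=False)
    alpha: float = DEFAULT_ALPHA

    @property
    def volume(self) -> float:
        return self.shape.volume

    @property
    def localization_number(self) -> int:
        return len(self.locs)

    @property
    def localization_density(self) -> float:
        return self.localization_number / self.volume


def make_synaptic_cluster(
    locs: LocalizationSet, alpha: float = DEFAULT_ALPHA, clean_background: bool = True
) -> SynapticCluster:
    if clean_background:
        locs, _ = remove_background(locs)
    return SynapticCluster(locs, alpha_shape(locs.xyz, alpha), alpha)


@dataclass
class Nanocluster:
    """A subsynaptic high-density region."""

    member_idx: np.ndarray  # indices into the parent cluster's localizations
    peak: np.ndarray  # (3,) nm, local-density-weighted centroid
    volume: float  # nm^3
    localization_number: int
    localization_density: float


def _candidate_peaks(xyz: np.ndarray, counts: np.ndarray, supra_idx: np.ndarray, radius: float) -> np.ndarray:
    """Supra-threshold points that are local maxima of the density field."""
    sub = xyz[supra_idx]
    tree = cKDTree(sub)
    peaks = []
    for i in range(len(sub)):
        nb = tree.query_ball_point(sub[i], radius)
        ci = counts[supra_idx[i]]
        if all(counts[supra_idx[j]] <= ci for j in nb):
            peaks.append(i)
    return supra_idx[np.asarray(peaks, int)]


def _merge_peaks(xyz: np.ndarray, counts: np.ndarray, peak_idx: np.ndarray, min_sep: float) -> np.ndarray:
    """Iteratively drop the weaker peak of the closest pair until all >= min_sep apart."""
    peaks = list(peak_idx)
    while len(peaks) > 1:
        pts = xyz[peaks]
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= min_sep:
            break
        # keep the denser peak; ties keep the lower original index
        ci, cj = counts[peaks[i]], counts[peaks[j]]
        drop = j if (cj < ci or (cj == ci and peaks[j] > peaks[i])) else i
        peaks.pop(drop)
    return np.asarray(peaks, int)


def nanocluster_threshold(
    cluster: SynapticCluster,
    field_obs: LocalDensityField,
    seed: int,
    n_null: int = N_NULL,
    threshold_sd: float = NC_THRESHOLD_SD,
) -> float:
    """Detection threshold mean(LD0) + k sd(LD0) from uniform randomizations.

    LD0 pools the local densities of ``n_null`` clusters of the same size
    resampled uniformly inside the observed cluster's alpha-shape border,
    evaluated with the observed counting radius.
    """
    rng = np.random.default_rng(seed)
    n = cluster.localization_number
    ld0 = []
    for _ in range(n_null):
        pts = cluster.shape.sample_uniform(n, rng)
        ld0.append(local_density(pts, radius=field_obs.radius).counts)
    ld0 = np.concatenate(ld0)
    return float(ld0.mean() + threshold_sd * ld0.std())


def detect_nanoclusters(
    cluster: SynapticCluster,
    seed: int = 0,
    min_locs: int = NC_MIN_LOCS,
    min_separation: float = NC_MIN_SEPARATION,
    threshold_sd: float = NC_THRESHOLD_SD,
    n_null: int = N_NULL,
    z_weight: float = 1.0,
) -> list[Nanocluster]:
    """Detect nanoclusters inside one synaptic cluster.

    Local density is thresholded against the randomized null
    (mean + ``threshold_sd`` x sd); supra-threshold localizations are split
    top-down: candidate peaks are local maxima of the density field, the
    closest peak pair is merged (weaker peak dropped) until all peaks are at
    least ``min_separation`` apart, members go to the nearest surviving
    peak, and groups with fewer than ``min_locs`` members are discarded.
    """
    xyz = cluster.locs.xyz.copy()
    if z_weight != 1.0:
        xyz[:, 2] *= z_weight

    field_obs = local_density(xyz)
    thr = nanocluster_threshold(cluster, field_obs, seed, n_null, threshold_sd)

    supra = np.flatnonzero(field_obs.counts > thr)
    if len(supra) < min_locs:
        return []

    # candidate peaks are density maxima within the peak-separation radius:
    # using the (much smaller) counting radius here admits tie-level maxima
    # at nanocluster edges whose pairwise merging can bridge genuine peaks
    peak_idx = _candidate_peaks(xyz, field_obs.counts, supra, min_separation)
    peak_idx = _merge_peaks(xyz, field_obs.counts, peak_idx, min_separation)
    if len(peak_idx) == 0:
        return []

    # assign supra-threshold members to the nearest surviving peak
    d = np.linalg.norm(xyz[supra][:, None, :] - xyz[peak_idx][None, :, :], axis=2)
    assign = np.argmin(d, axis=1)

    out = []
    for k in range(len(peak_idx)):
        members = supra[assign == k]
        if len(members) < min_locs:
            continue
        mx = cluster.locs.xyz[members]
        w = field_obs.counts[members].astype(float)
        w = w / w.sum()
        peak = (w[:, None] * mx).sum(axis=0)
        vol = _robust_volume(mx, cluster.alpha)
        dens = len(members) / vol if vol > 0 else np.nan
        out.append(Nanocluster(members, peak, vol, len(members), dens))
    out.sort(key=lambda nc: -nc.localization_number)
    return out


# ---------------------------------------------------------------------------
# per-synapse report
# ---------------------------------------------------------------------------


@dataclass
class ClusterReport:
    """Per-synapse summary metrics.

    Fractions are computed against the synaptic-cluster totals, so they lie
    in [0, 1]; nanocluster volumes may overlap in pathological cases, in
    which case the volume fraction is clipped at 1.
    """

    synapse_id: str
    localization_number: int
    volume: float
    density: float
    n_nanoclusters: int
    nc_localization_numbers: list
    nc_volumes: list
    nc_densities: list
    fraction_locs_in_nc: float
    fraction_volume_in_nc: float

    def to_row(self) -> dict:
        return {
            "synapse_id": self.synapse_id,
            "localization_number": self.localization_number,
            "volume_nm3": self.volume,
            "density_per_nm3": self.density,
            "n_nanoclusters": self.n_nanoclusters,
            "nc_mean_localizations": float(np.mean(self.nc_localization_numbers)) if self.n_nanoclusters else 0.0,
            "nc_mean_volume_nm3": float(np.mean(self.nc_volumes)) if self.n_nanoclusters else 0.0,
            "nc_mean_density_per_nm3": float(np.mean(self.nc_densities)) if self.n_nanoclusters else 0.0,
            "fraction_locs_in_nc": self.fraction_locs_in_nc,
            "fraction_volume_in_nc": self.fraction_volume_in_nc,
        }


def cluster_report(
    cluster: SynapticCluster, nanoclusters: list[Nanocluster], synapse_id: str = "synapse"
) -> ClusterReport:
    n_in_nc = int(sum(nc.localization_number for nc in nanoclusters))
    v_in_nc = float(sum(nc.volume for nc in nanoclusters))
    return ClusterReport(
        synapse_id=synapse_id,
        localization_number=cluster.localization_number,
        volume=cluster.volume,
        density=cluster.localization_density,
        n_nanoclusters=len(nanoclusters),
        nc_localization_numbers=[nc.localization_number for nc in nanoclusters],
        nc_volumes=[nc.volume for nc in nanoclusters],
        nc_densities=[nc.localization_density for nc in nanoclusters],
        fraction_locs_in_nc=min(n_in_nc / cluster.localization_number, 1.0),
        fraction_volume_in_nc=min(v_in_nc / cluster.volume, 1.0),
    )


def reports_to_frame(reports: list[ClusterReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def nanocluster_table(reports_and_ncs: list[tuple[ClusterReport, list[Nanocluster]]]) -> pd.DataFrame:
    rows = []
    for rep, ncs in reports_and_ncs:
        for k, nc in enumerate(ncs):
            rows.append(
                {
                    "synapse_id": rep.synapse_id,
                    "nanocluster_id": k,
                    "peak_x_nm": nc.peak[0],
                    "peak_y_nm": nc.peak[1],
                    "peak_z_nm": nc.peak[2],
                    "localization_number": nc.localization_number,
                    "volume_nm3": nc.volume,
                    "density_per_nm3": nc.localization_density,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "synapse_id",
            "nanocluster_id",
            "peak_x_nm",
            "peak_y_nm",
            "peak_z_nm",
            "localization_number",
            "volume_nm3",
            "density_per_nm3",
        ],
    )
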