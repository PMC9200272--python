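"""Synthetic localization data and receptor placements.

The generators here emulate the statistical structure of 3D STORM data at
calyx of Held synapses: disc-shaped synaptic clusters (~100-200 nm radius)
containing a few high-density nanoclusters, a uniform background, and
anisotropic localization noise (sigma 10-15 nm laterally, 40-50 nm axially).
They provide planted ground truth for the detection and alignment stages and
the receptor placements consumed by the quantal simulator.

What is deliberately NOT modelled: raw camera frames, PSF shape, fluorophore
blinking/photoswitching and drift — the generators produce ideal localization
tables, not microscope output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from shapely.geometry import Point
from shapely.ops import unary_union

from .localizations import LocalizationSet

__all__ = [
    "SyntheticClusterSpec",
    "PairedChannelSpec",
    "ReceptorMap",
    "generate_synaptic_cluster",
    "generate_paired_channels",
    "generate_receptor_map",
    "place_nanocluster_centers",
    "largest_remainder",
]


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts proportionally to ``weights``.

    Floors the exact quotas and hands the leftover units to the largest
    fractional remainders (ties broken by lower index), so the result always
    sums exactly to ``total``.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - counts.sum()
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


# ---------------------------------------------------------------------------
# synthetic synaptic clusters
# ---------------------------------------------------------------------------


@dataclass
class SyntheticClusterSpec:
    """Recipe for one synthetic synaptic cluster.

    ``enrichment_factor`` is the areal density inside nanoclusters divided by
    the density in the rest of the disc; ``background_fraction`` of the
    localizations are spread uniformly over a box 1.5x the disc in x/y and
    3x the axial thickness in z.
    """

    n_localizations: int = 2000
    disc_radius: float = 150.0  # nm
    axial_thickness: float = 60.0  # nm
    nanocluster_centers: tuple = ((0.0, 0.0),)
    nanocluster_radius: float = 40.0  # nm
    enrichment_factor: float = 5.0
    background_fraction: float = 0.05
    noise_sigma_xy: float = 12.0  # nm
    noise_sigma_z: float = 45.0  # nm
    seed: int = 0
    channel: str = "ch0"

    def validate(self) -> None:
        if self.n_localizations <= 0:
            raise ValueError("n_localizations must be positive")
        if self.disc_radius <= 0 or self.axial_thickness <= 0:
            raise ValueError("disc_radius and axial_thickness must be positive")
        if self.nanocluster_radius < 0:
            raise ValueError("nanocluster_radius must be non-negative")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        if self.noise_sigma_xy < 0 or self.noise_sigma_z < 0:
            raise ValueError("noise sigmas must be non-negative")
        for cx, cy in self.nanocluster_centers:
            if np.hypot(cx, cy) > self.disc_radius:
                raise ValueError("nanocluster centers must lie inside the disc")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nanocluster_centers"] = [list(c) for c in self.nanocluster_centers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticClusterSpec":
        d = dict(d)
        d["nanocluster_centers"] = tuple(tuple(c) for c in d.get("nanocluster_centers", ()))
        return cls(**d)


def place_nanocluster_centers(
    n: int,
    disc_radius: float,
    nanocluster_radius: float,
    rng: np.random.Generator,
    min_separation: float = 100.0,
    max_tries: int = 10_000,
) -> tuple:
    """Uniform rejection sampling of nanocluster centers inside the disc.

    Centers keep a minimum mutual separation (default 100 nm, above the
    80-nm peak-merging limit of the detector) and stay ``nanocluster_radius``
    away from the disc edge so planted discs are fully contained.
    """
    rmax = max(disc_radius - nanocluster_radius, 0.0)
    centers: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        r = rmax * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cand = (r * np.cos(th), r * np.sin(th))
        if all(np.hypot(cand[0] - cx, cand[1] - cy) >= min_separation for cx, cy in centers):
            centers.append(cand)
    if len(centers) < n:
        raise RuntimeError("could not place nanocluster centers; disc too crowded")
    return tuple(centers)


def _nc_region_area(spec: SyntheticClusterSpec) -> float:
    """Area of (union of nanocluster discs) intersected with the synaptic disc."""
    if not spec.nanocluster_centers or spec.nanocluster_radius == 0:
        return 0.0
    discs = [Point(c).buffer(spec.nanocluster_radius, quad_segs=128) for c in spec.nanocluster_centers]
    synapse = Point(0, 0).buffer(spec.disc_radius, quad_segs=256)
    return unary_union(discs).intersection(synapse).area


def _in_nanocluster(xy: np.ndarray, spec: SyntheticClusterSpec) -> np.ndarray:
    if not spec.nanocluster_centers or spec.nanocluster_radius == 0:
        return np.zeros(len(xy), dtype=bool)
    centers = np.asarray(spec.nanocluster_centers, float)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= spec.nanocluster_radius**2).any(axis=1)


def _sample_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _sample_region(n: int, spec: SyntheticClusterSpec, inside: bool, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly in the disc, in or out of nanoclusters."""
    out = np.empty((0, 2))
    while len(out) < n:
        cand = _sample_disc(max(4 * (n - len(out)), 64), spec.disc_radius, rng)
        mask = _in_nanocluster(cand, spec)
        if not inside:
            mask = ~mask
        out = np.vstack([out, cand[mask]])
    return out[:n]


def generate_synaptic_cluster(spec: SyntheticClusterSpec) -> LocalizationSet:
    """Generate one synthetic synaptic cluster of localizations.

    Exactly ``n_localizations`` points: a ``background_fraction`` share
    uniform in a bounding box, the rest in the disc with the planted
    nanocluster enrichment, plus anisotropic Gaussian localization noise.
    Identical specs (including seed) give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_bg = int(round(spec.background_fraction * spec.n_localizations))
    n_sig = spec.n_localizations - n_bg

    a_in = _nc_region_area(spec)
    a_out = np.pi * spec.disc_radius**2 - a_in
    w_in = spec.enrichment_factor * a_in
    p_in = w_in / (w_in + a_out) if (w_in + a_out) > 0 else 0.0
    n_in = rng.binomial(n_sig, p_in)

    xy_in = _sample_region(n_in, spec, inside=True, rng=rng)
    xy_out = _sample_region(n_sig - n_in, spec, inside=False, rng=rng)
    xy = np.vstack([xy_in, xy_out])
    z = rng.uniform(-spec.axial_thickness / 2, spec.axial_thickness / 2, size=n_sig)
    pts = np.column_stack([xy, z])

    if n_bg:
        half = 1.5 * spec.disc_radius
        bg = np.column_stack(
            [
                rng.uniform(-half, half, size=n_bg),
                rng.uniform(-half, half, size=n_bg),
                rng.uniform(-1.5 * spec.axial_thickness, 1.5 * spec.axial_thickness, size=n_bg),
            ]
        )
        pts = np.vstack([pts, bg])

    if spec.noise_sigma_xy > 0:
        pts[:, :2] += rng.normal(0, spec.noise_sigma_xy, size=(len(pts), 2))
    if spec.noise_sigma_z > 0:
        pts[:, 2] += rng.normal(0, spec.noise_sigma_z, size=len(pts))

    return LocalizationSet(pts, spec.channel, {"spec": spec.to_dict()})


# ---------------------------------------------------------------------------
# paired channels
# ---------------------------------------------------------------------------


@dataclass
class PairedChannelSpec:
    """Two-channel fixture emulating trans-synaptically paired proteins.

    The reference channel (e.g. presynaptic RIM1) is generated from
    ``reference``; the target channel reuses the reference nanocluster
    positions (``aligned``), displaces them laterally by ``offset_nm`` in a
    seeded random direction (``offset``), or draws fresh positions
    (``independent``).  ``cross_enrichment`` sets the target density contrast
    around those positions.
    """

    reference: SyntheticClusterSpec = field(default_factory=SyntheticClusterSpec)
    target: SyntheticClusterSpec = field(default_factory=SyntheticClusterSpec)
    alignment_mode: str = "aligned"  # aligned | offset | independent
    offset_nm: float = 0.0
    cross_enrichment: float = 3.0

    def validate(self) -> None:
        self.reference.validate()
        if self.alignment_mode not in ("aligned", "offset", "independent"):
            raise ValueError(f"unknown alignment_mode {self.alignment_mode!r}")
        if self.offset_nm < 0:
            raise ValueError("offset must be >= 0")
        if self.cross_enrichment < 1:
            raise ValueError("cross_enrichment must be >= 1")


def generate_paired_channels(spec: PairedChannelSpec) -> tuple[LocalizationSet, LocalizationSet]:
    spec.validate()
    ref = generate_synaptic_cluster(spec.reference)

    rng = np.random.default_rng(spec.target.seed + 1_000_003)
    from dataclasses import replace

    if spec.alignment_mode == "aligned":
        centers = spec.reference.nanocluster_centers
    elif spec.alignment_mode == "offset":
        centers = []
        rmax = spec.target.disc_radius
        for cx, cy in spec.reference.nanocluster_centers:
            for _ in range(1000):
                th = rng.uniform(0, 2 * np.pi)
                cand = (cx + spec.offset_nm * np.cos(th), cy + spec.offset_nm * np.sin(th))
                if np.hypot(*cand) <= rmax:
                    break
            centers.append(cand)
        centers = tuple(centers)
    else:  # independent
        centers = place_nanocluster_centers(
            len(spec.reference.nanocluster_centers),
            spec.target.disc_radius,
            spec.target.nanocluster_radius,
            rng,
        )

    tgt_spec = replace(
        spec.target,
        nanocluster_centers=centers,
        enrichment_factor=spec.cross_enrichment,
    )
    tgt = generate_synaptic_cluster(tgt_spec)
    return ref, tgt


# ---------------------------------------------------------------------------
# receptor placements for the simulator
# ---------------------------------------------------------------------------


@dataclass
class ReceptorMap:
    """Postsynaptic receptor placement on the PSD disc.

    ``positions`` are 2D points (nm) on the postsynaptic face; ``is_fast``
    marks fast-gating receptors.  Each receptor is a flat disc of radius
    ``receptor_disc_radius`` that counts glutamate impacts.
    """

    positions: np.ndarray  # (n, 2) nm
    is_fast: np.ndarray  # (n,) bool
    receptor_disc_radius: float = 10.0  # nm
    boundaries: tuple = (0.0, 60.0, 100.0, 140.0)  # nm
    relative_densities: tuple = (3.0, 1.0, 1.0)
    slow_fast_ratio: tuple = (0.45, 0.55)

    @property
    def n_total(self) -> int:
        return len(self.positions)

    @property
    def n_fast(self) -> int:
        return int(self.is_fast.sum())

    @property
    def n_slow(self) -> int:
        return int((~self.is_fast).sum())

    def subregion_counts(self) -> np.ndarray:
        r = np.hypot(self.positions[:, 0], self.positions[:, 1])
        edges = np.asarray(self.boundaries)
        return np.histogram(r, bins=edges)[0]

    def areal_density_ratio(self, split: float = 60.0) -> float:
        """Areal density inside r < split over the density from split to the edge."""
        r = np.hypot(self.positions[:, 0], self.positions[:, 1])
        outer = self.boundaries[-1]
        n_in = int((r < split).sum())
        n_out = self.n_total - n_in
        a_in = np.pi * split**2
        a_out = np.pi * (outer**2 - split**2)
        if n_out == 0:
            return np.inf
        return (n_in / a_in) / (n_out / a_out)


def generate_receptor_map(
    relative_densities=(3.0, 1.0, 1.0),
    n_total: int = 100,
    slow_fast_ratio=(0.45, 0.55),
    seed: int = 0,
    boundaries=(0.0, 60.0, 100.0, 140.0),
    receptor_disc_radius: float = 10.0,
    allow_overlap: bool = True,
) -> ReceptorMap:
    """Place receptors on concentric PSD subregions.

    Expected counts per annulus are proportional to annulus area times the
    relative density, realized exactly by largest-remainder rounding.  Within
    each annulus positions are uniform; slow/fast labels are assigned by a
    seeded permutation independent of position, with counts from
    largest-remainder rounding of the ratio.  With the default control
    profile (3, 1, 1) over 0-60/60-100/100-140 nm this yields a threefold
    areal density inside 60 nm relative to the 60-140 nm annulus.

    The permutation trick keeps placements maximally correlated across
    different ratios under a common seed: changing the slow:fast ratio
    relabels the minimum number of receptors.
    """
    relative_densities = np.asarray(relative_densities, float)
    boundaries = np.asarray(boundaries, float)
    if len(relative_densities) != len(boundaries) - 1:
        raise ValueError("need one density per annulus")
    if np.any(relative_densities < 0) or relative_densities.sum() == 0:
        raise ValueError("densities must be non-negative and not all zero")
    if n_total <= 0:
        raise ValueError("n_total must be positive")

    areas = np.pi * (boundaries[1:] ** 2 - boundaries[:-1] ** 2)
    counts = largest_remainder(areas * relative_densities, n_total)

    rng = np.random.default_rng(seed)
    pos = []
    for (r0, r1), k in zip(zip(boundaries[:-1], boundaries[1:]), counts):
        if k == 0:
            continue
        attempts = 0
        placed: list[np.ndarray] = []
        while len(placed) < k:
            r = np.sqrt(rng.uniform(r0**2, r1**2))
            th = rng.uniform(0, 2 * np.pi)
            p = np.array([r * np.cos(th), r * np.sin(th)])
            if not allow_overlap:
                prior = np.array(placed + [q for q in pos]) if (placed or pos) else np.empty((0, 2))
                if len(prior) and np.min(np.hypot(*(prior - p).T)) < 2 * receptor_disc_radius:
                    attempts += 1
                    if attempts > 100_000:
                        raise RuntimeError("cannot place non-overlapping receptors")
                    continue
            placed.append(p)
        pos.extend(placed)
    positions = np.array(pos)

    n_slow, n_fast = largest_remainder(np.asarray(slow_fast_ratio, float), n_total)
    is_fast = np.zeros(n_total, dtype=bool)
    perm = np.random.default_rng(seed + 77_777).permutation(n_total)
    is_fast[perm[:n_fast]] = True

    return ReceptorMap(
        positions=positions,
        is_fast=is_fast,
        receptor_disc_radius=receptor_disc_radius,
        boundaries=tuple(boundaries),
        relative_densities=tuple(relative_densities),
        slow_fast_ratio=tuple(slow_fast_ratio),
    )


def save_spec(spec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_spec(path) -> SyntheticClusterSpec:
    with open(path) as fh:
        return SyntheticClusterSpec.from_dict(yaml.safe_load(fh))
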