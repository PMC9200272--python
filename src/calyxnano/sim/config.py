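"""Configuration objects for the quantal-release simulator.

One ``SimConfig`` fully parameterizes a single quantal event: cleft
geometry, vesicle source, diffusion parameters, the receptor placement and
the two gating schemes.  Everything round-trips through YAML so a simulation
is reproducible from a plain-text document plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ..synth import ReceptorMap, generate_receptor_map
from .kinetics import KineticScheme, default_scheme


@dataclass
class SynapseGeometry:
    """Cleft and PSD geometry (nm).

    The synapse is modelled as the 28-nm gap between two coaxial discs of
    radius ``cleft_radius`` (the 0.5-um lateral extent of a single
    active-zone unit).  A glial sheath surrounds the cleft ``glial_gap``
    beyond the synaptic edge and carries uptake transporters at
    ``transporter_density``.
    """

    cleft_height: float = 28.0
    cleft_radius: float = 250.0
    psd_radius: float = 140.0
    nanocluster_radius: float = 60.0
    glial_gap: float = 40.0
    transporter_density_per_um2: float = 5000.0
    transporter_capture_radius: float = 5.0  # nm

    def validate(self) -> None:
        for name in ("cleft_height", "cleft_radius", "psd_radius", "nanocluster_radius", "glial_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.nanocluster_radius <= self.psd_radius <= self.cleft_radius):
            raise ValueError("require nanocluster_radius <= psd_radius <= cleft_radius")

    @property
    def glial_radius(self) -> float:
        return self.cleft_radius + self.glial_gap

    @property
    def uptake_probability(self) -> float:
        """Absorption probability per glial-wall contact.

        Area-coverage approximation: the transporter surface density times
        the capture disc of one transporter, capped at 1 (~0.39 at the
        default 5000/um^2 with a 5-nm capture radius).
        """
        rho = self.transporter_density_per_um2 * 1e-6  # per nm^2
        return float(min(1.0, rho * np.pi * self.transporter_capture_radius**2))


@dataclass
class VesicleSource:
    """Single-vesicle glutamate source.

    The vesicle empties through its fusion pore at a constant rate over
    tau = 73 / gamma microseconds (gamma = pore conductance in nS); with the
    measured calyx pore conductance of 0.375 nS this is ~0.2 ms.  Release
    sites are drawn uniformly from a disc whose radius is the synaptic
    cluster for spontaneous events (mEPSC) or the nanocluster for evoked
    events (EPSC).
    """

    n_glutamate: int = 8000
    pore_conductance_nS: float = 0.375
    release_site_mode: str = "synaptic_cluster"  # or "nanocluster"
    exponential_emptying: bool = False

    @property
    def release_tau_us(self) -> float:
        return 73.0 / self.pore_conductance_nS

    def validate(self) -> None:
        if self.n_glutamate < 0:
            raise ValueError("n_glutamate must be >= 0")
        if self.pore_conductance_nS <= 0:
            raise ValueError("pore conductance must be positive")
        if self.release_site_mode not in ("synaptic_cluster", "nanocluster"):
            raise ValueError("release_site_mode must be synaptic_cluster or nanocluster")


@dataclass
class DiffusionParams:
    """Brownian dynamics parameters (D = 0.4 um^2/ms, dt = 0.5 us)."""

    D_um2_per_ms: float = 0.4
    dt_us: float = 0.5

    @property
    def sigma_nm(self) -> float:
        """Per-axis displacement s.d. per step, sqrt(2 D dt), in nm."""
        d_nm2_per_us = self.D_um2_per_ms * 1e6 / 1e3
        return float(np.sqrt(2.0 * d_nm2_per_us * self.dt_us))

    def validate(self, cleft_height: float) -> bool:
        """True (with a warning condition) when the rms step is not << cleft height."""
        if self.D_um2_per_ms < 0 or self.dt_us <= 0:
            raise ValueError("D must be >= 0 and dt > 0")
        rms3d = float(np.sqrt(3.0) * self.sigma_nm)
        return rms3d > cleft_height  # caller may warn


@dataclass
class SimConfig:
    """Full parameterization of one quantal event."""

    geometry: SynapseGeometry = field(default_factory=SynapseGeometry)
    vesicle: VesicleSource = field(default_factory=VesicleSource)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    receptor_map: ReceptorMap | None = None
    fast_scheme: KineticScheme = field(default_factory=lambda: default_scheme("fast"))
    slow_scheme: KineticScheme = field(default_factory=lambda: default_scheme("slow"))
    rate_scale: float = 1.0  # global kinetic scale; the KO fit uses 0.6
    vm_mV: float = -60.0
    vrev_mV: float = 0.0
    duration_ms: float = 6.0
    record_stride: int = 20  # persist every Nth step (10 us at dt=0.5)

    def __post_init__(self) -> None:
        if self.receptor_map is None:
            self.receptor_map = generate_receptor_map(seed=0)

    def validate(self) -> None:
        self.geometry.validate()
        self.vesicle.validate()
        self.diffusion.validate(self.geometry.cleft_height)
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        outer = self.receptor_map.boundaries[-1]
        if outer > self.geometry.cleft_radius:
            raise ValueError("receptor placement extends beyond the cleft")
        dt_ms = self.diffusion.dt_us * 1e-3
        for scheme in (self.fast_scheme, self.slow_scheme):
            scheme.check_reversibility()
            if scheme.max_independent_rate() * self.rate_scale * dt_ms > 0.1:
                raise ValueError("rate*dt exceeds 0.1; use a smaller time step")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        rm = self.receptor_map
        return {
            "geometry": vars(self.geometry).copy(),
            "vesicle": {
                "n_glutamate": self.vesicle.n_glutamate,
                "pore_conductance_nS": self.vesicle.pore_conductance_nS,
                "release_site_mode": self.vesicle.release_site_mode,
                "exponential_emptying": self.vesicle.exponential_emptying,
            },
            "diffusion": vars(self.diffusion).copy(),
            "receptor_map": {
                "relative_densities": list(rm.relative_densities),
                "boundaries": list(rm.boundaries),
                "n_total": rm.n_total,
                "slow_fast_ratio": list(rm.slow_fast_ratio),
                "receptor_disc_radius": rm.receptor_disc_radius,
            },
            "fast_scheme": self.fast_scheme.to_dict(),
            "slow_scheme": self.slow_scheme.to_dict(),
            "rate_scale": self.rate_scale,
            "vm_mV": self.vm_mV,
            "vrev_mV": self.vrev_mV,
            "duration_ms": self.duration_ms,
            "record_stride": self.record_stride,
        }

    @classmethod
    def from_dict(cls, d: dict, receptor_seed: int = 0) -> "SimConfig":
        rm = d.get("receptor_map", {})
        return cls(
            geometry=SynapseGeometry(**d.get("geometry", {})),
            vesicle=VesicleSource(**d.get("vesicle", {})),
            diffusion=DiffusionParams(**d.get("diffusion", {})),
            receptor_map=generate_receptor_map(
                relative_densities=tuple(rm.get("relative_densities", (3.0, 1.0, 1.0))),
                n_total=int(rm.get("n_total", 100)),
                slow_fast_ratio=tuple(rm.get("slow_fast_ratio", (0.45, 0.55))),
                seed=receptor_seed,
                boundaries=tuple(rm.get("boundaries", (0.0, 60.0, 100.0, 140.0))),
                receptor_disc_radius=float(rm.get("receptor_disc_radius", 10.0)),
            ),
            fast_scheme=KineticScheme.from_dict(d["fast_scheme"]) if "fast_scheme" in d else default_scheme("fast"),
            slow_scheme=KineticScheme.from_dict(d["slow_scheme"]) if "slow_scheme" in d else default_scheme("slow"),
            rate_scale=float(d.get("rate_scale", 1.0)),
            vm_mV=float(d.get("vm_mV", -60.0)),
            vrev_mV=float(d.get("vrev_mV", 0.0)),
            duration_ms=float(d.get("duration_ms", 6.0)),
            record_stride=int(d.get("record_stride", 20)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, receptor_seed: int = 0) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), receptor_seed=receptor_seed)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)
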