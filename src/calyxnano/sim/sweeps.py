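"""Condition sweeps: development, receptor redistribution and rate scaling.

The developmental sweep replays the quantal simulation with the fast:slow
receptor ratios reported for MNTB principal neurons at five ages; receptor
positions and all random streams are shared across conditions (common
random numbers), so between-condition differences reflect the parameter
change, not sampling noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..synth import generate_receptor_map
from .config import SimConfig
from .engine import average_traces
from .metrics import metrics_of

# fast:slow GluA counts per 100 receptors at each age (P4 ... P30)
DEVELOPMENTAL_RATIOS = {
    "P4": (3, 17),
    "P8": (3, 7),
    "P12": (11, 9),
    "P16": (29, 21),
    "P30": (3, 1),
}

CONTROL_DENSITIES = (3.0, 1.0, 1.0)
KO_DENSITIES = (1.5, 1.0, 1.0)
KO_RATE_SCALE = 0.6


def _map_for_ratio(config: SimConfig, fast: int, slow: int, seed: int):
    rm = config.receptor_map
    tot = fast + slow
    return generate_receptor_map(
        relative_densities=rm.relative_densities,
        n_total=rm.n_total,
        slow_fast_ratio=(slow / tot, fast / tot),
        seed=seed,
        boundaries=rm.boundaries,
        receptor_disc_radius=rm.receptor_disc_radius,
    )


def developmental_sweep(
    base_config: SimConfig | None = None,
    n_runs: int = 40,
    seed: int = 0,
    ratios: dict | None = None,
    placement_seed: int = 0,
) -> pd.DataFrame:
    """Amplitude / rise / decay of the mean mEPSC at each developmental ratio."""
    if base_config is None:
        base_config = SimConfig()
    if ratios is None:
        ratios = DEVELOPMENTAL_RATIOS
    rows = []
    for age, (fast, slow) in ratios.items():
        cfg = base_config.with_(receptor_map=_map_for_ratio(base_config, fast, slow, placement_seed))
        trace, _ = average_traces(cfg, n_runs=n_runs, seed=seed)
        m = metrics_of(trace)
        rows.append(
            {
                "age": age,
                "n_fast": fast,
                "n_slow": slow,
                "fast_fraction": fast / (fast + slow),
                "peak_amplitude_pA": m.peak_amplitude_pA,
                "rise_10_90_us": m.rise_10_90_us,
                "decay_tau_us": m.decay_tau_us,
                "fast_share_at_peak": trace.fast_share_at_peak(),
            }
        )
    return pd.DataFrame(rows)


def glutamate_transient(config: SimConfig, seed: int = 0, n_runs: int = 4):
    """Volume-averaged free-glutamate concentration (mM) over time (ms).

    Averages the free-molecule count of a few seeded runs and divides by the
    cleft volume; used as the driving concentration for the well-mixed
    (rate-equation) route.
    """
    from .engine import AVOGADRO_MM_PER_NM3, run_quantal_event

    children = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    free = None
    for s in children:
        tr = run_quantal_event(config, seed=int(s))
        free = tr.free if free is None else free + tr.free
    free = free / n_runs
    volume = np.pi * config.geometry.glial_radius**2 * config.geometry.cleft_height
    conc_mM = free / volume / AVOGADRO_MM_PER_NM3
    return tr.t_us * 1e-3, conc_mM


def developmental_sweep_well_mixed(
    base_config: SimConfig | None = None,
    ratios: dict | None = None,
    seed: int = 0,
    transient_runs: int = 4,
) -> pd.DataFrame:
    """Expected mEPSC metrics per developmental ratio, noise-free.

    Integrates the fast and slow rate equations once against the seeded
    volume-averaged glutamate transient and mixes the per-type open
    probabilities according to each age's receptor counts.  Because the two
    open-probability curves are shared across ages, the resulting decay
    times vary smoothly and strictly monotonically with the fast fraction —
    the deterministic counterpart of the stochastic sweep, whose adjacent
    ratios (11:9 vs 29:21) differ by less than its sampling noise.
    """
    from scipy.interpolate import interp1d

    from .metrics import trace_metrics

    if base_config is None:
        base_config = SimConfig()
    if ratios is None:
        ratios = DEVELOPMENTAL_RATIOS
    t_ms, conc = glutamate_transient(base_config, seed=seed, n_runs=transient_runs)
    conc_of_t = interp1d(t_ms, conc, bounds_error=False, fill_value=0.0)
    drive_mV = base_config.vm_mV - base_config.vrev_mV
    open_p = {}
    for name, scheme in (("fast", base_config.fast_scheme), ("slow", base_config.slow_scheme)):
        sch = scheme.scaled(base_config.rate_scale) if base_config.rate_scale != 1.0 else scheme
        p = sch.integrate(conc_of_t, t_ms)
        open_p[name] = p[:, sch.state_index("O")]
    rows = []
    n_total = base_config.receptor_map.n_total
    for age, (fast, slow) in ratios.items():
        nf = n_total * fast / (fast + slow)
        ns = n_total - nf
        cur = (
            base_config.fast_scheme.conductance_pS * nf * open_p["fast"]
            + base_config.slow_scheme.conductance_pS * ns * open_p["slow"]
        ) * drive_mV * 1e-3
        m = trace_metrics(t_ms * 1e3, cur)
        rows.append(
            {
                "age": age,
                "fast_fraction": fast / (fast + slow),
                "peak_amplitude_pA": m.peak_amplitude_pA,
                "rise_10_90_us": m.rise_10_90_us,
                "decay_tau_us": m.decay_tau_us,
            }
        )
    return pd.DataFrame(rows)


def ko_comparison(
    base_config: SimConfig | None = None,
    n_runs: int = 40,
    seed: int = 0,
    control_densities=CONTROL_DENSITIES,
    ko_densities=KO_DENSITIES,
    rate_scale: float = KO_RATE_SCALE,
    placement_seed: int = 0,
) -> pd.DataFrame:
    """Control vs receptor-redistribution vs redistribution + rate scaling.

    Three conditions sharing random streams: the control placement (3:1:1
    radial density profile), the KO-like flattened placement with unchanged
    kinetics (redistribution only), and the same placement with all rate
    constants multiplied by ``rate_scale`` (default 0.6).
    """
    if base_config is None:
        base_config = SimConfig()
    rm = base_config.receptor_map
    conditions = {
        "control": (control_densities, 1.0),
        "ko_redistributed": (ko_densities, 1.0),
        "ko_redistributed_scaled": (ko_densities, rate_scale),
    }
    rows = []
    for name, (dens, scale) in conditions.items():
        cfg = base_config.with_(
            receptor_map=generate_receptor_map(
                relative_densities=dens,
                n_total=rm.n_total,
                slow_fast_ratio=rm.slow_fast_ratio,
                seed=placement_seed,
                boundaries=rm.boundaries,
                receptor_disc_radius=rm.receptor_disc_radius,
            ),
            rate_scale=scale,
        )
        trace, _ = average_traces(cfg, n_runs=n_runs, seed=seed)
        m = metrics_of(trace)
        rows.append(
            {
                "condition": name,
                "rate_scale": scale,
                "peak_amplitude_pA": m.peak_amplitude_pA,
                "rise_10_90_us": m.rise_10_90_us,
                "decay_tau_us": m.decay_tau_us,
            }
        )
    return pd.DataFrame(rows)
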