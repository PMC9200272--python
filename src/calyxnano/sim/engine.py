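"""Monte Carlo engine: vesicle release, cleft diffusion, receptor gating.

One quantal event couples four processes at a 0.5-us time step:

* the vesicle empties at a constant rate over tau = 73/gamma us;
* free glutamate performs Brownian motion between the reflecting pre- and
  postsynaptic membranes; at the surrounding glial wall each contact is
  absorbed with the transporter-coverage probability, otherwise reflected;
* a "hit" is a step whose path crosses the postsynaptic plane inside a
  receptor disc (the molecule is reflected, not consumed);
* each receptor runs its nine-state Markov chain, with binding transitions
  driven by the hit count: every hit on a 10-nm disc in one step represents
  a fixed glutamate concentration increment chosen so the expected binding
  rate under a homogeneous concentration C equals k_on * C exactly.

The inner loops are numba-compiled; a seeded run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .config import SimConfig
from .kinetics import KineticScheme

AVOGADRO_MM_PER_NM3 = 6.02214076e-4  # molecules per nm^3 at 1 mM
SQRT_2PI = float(np.sqrt(2.0 * np.pi))


# ---------------------------------------------------------------------------
# release schedule
# ---------------------------------------------------------------------------


def release_schedule(source, dt_us: float) -> np.ndarray:
    """Per-step released molecule counts; sums exactly to n_glutamate.

    Constant-rate emptying over tau = 73/gamma us by default (the vesicle's
    full content leaves by the end of the schedule); optional exponential
    emptying with time constant tau, truncated at 5 tau.  Integerization is
    by accumulated-remainder rounding of the cumulative release curve.
    """
    n = int(source.n_glutamate)
    tau = source.release_tau_us
    if n == 0:
        return np.zeros(1, dtype=np.int64)
    if tau <= dt_us and not source.exponential_emptying:
        return np.array([n], dtype=np.int64)
    if source.exponential_emptying:
        t_end = 5.0 * tau
        edges = np.arange(dt_us, t_end + dt_us, dt_us)
        frac = (1.0 - np.exp(-edges / tau)) / (1.0 - np.exp(-5.0))
    else:
        edges = np.arange(dt_us, tau + dt_us, dt_us)
        frac = np.minimum(edges / tau, 1.0)
    cum = np.floor(n * frac + 1e-9).astype(np.int64)
    cum[-1] = n
    return np.diff(cum, prepend=0)


def hit_concentration_mM(receptor_radius_nm: float, sigma_nm: float) -> float:
    """Concentration equivalent of one disc hit in one step.

    Under a homogeneous concentration C the expected number of plane
    crossings through a disc of area A per step is
    C * A * sigma / sqrt(2 pi) (sigma = per-axis step s.d.), so one hit
    stands for 1 / (that expression at C = 1 mM) millimolar.
    """
    if sigma_nm == 0.0:
        return 0.0  # immobile molecules never cross the plane; hits cannot occur
    area = np.pi * receptor_radius_nm**2
    return 1.0 / (AVOGADRO_MM_PER_NM3 * area * sigma_nm / SQRT_2PI)


def expected_hits_per_step(conc_mM: float, receptor_radius_nm: float, sigma_nm: float) -> float:
    return conc_mM / hit_concentration_mM(receptor_radius_nm, sigma_nm)


# ---------------------------------------------------------------------------
# scheme -> flat arrays for the kernel
# ---------------------------------------------------------------------------


def _scheme_arrays(scheme: KineticScheme, rate_scale: float, dt_us: float, c_hit_mM: float):
    """CSR-by-source-state transition arrays with per-step probabilities."""
    n = scheme.n_states
    dt_ms = dt_us * 1e-3
    order = sorted(range(len(scheme.transitions)), key=lambda i: scheme.state_index(scheme.transitions[i].source))
    ptr = np.zeros(n + 1, dtype=np.int64)
    to = np.empty(len(order), dtype=np.int64)
    qdt = np.zeros(len(order))
    qhit = np.zeros(len(order))
    for k, i in enumerate(order):
        t = scheme.transitions[i]
        ptr[scheme.state_index(t.source) + 1] += 1
        to[k] = scheme.state_index(t.target)
        r = t.rate * rate_scale
        if t.glu_dependent:
            qhit[k] = r * c_hit_mM * dt_ms
        else:
            qdt[k] = r * dt_ms
    ptr = np.cumsum(ptr)
    is_open = np.zeros(n, dtype=np.bool_)
    for s in scheme.open_states:
        is_open[scheme.state_index(s)] = True
    init = scheme.state_index(scheme.initial_state)
    return ptr, to, qdt, qhit, is_open, init


def _receptor_grid(rx: np.ndarray, ry: np.ndarray, radius: float, cell: float = 20.0):
    """Uniform lookup grid mapping a hit position to candidate receptors."""
    ext = float(np.max(np.hypot(rx, ry), initial=0.0) + radius + cell)
    nx = max(int(np.ceil(2 * ext / cell)), 1)
    gx0 = -ext
    cells: list[list[int]] = [[] for _ in range(nx * nx)]
    for r in range(len(rx)):
        i0 = max(int((rx[r] - radius - gx0) / cell), 0)
        i1 = min(int((rx[r] + radius - gx0) / cell), nx - 1)
        j0 = max(int((ry[r] - radius - gx0) / cell), 0)
        j1 = min(int((ry[r] + radius - gx0) / cell), nx - 1)
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                cells[i * nx + j].append(r)
    ptr = np.zeros(nx * nx + 1, dtype=np.int64)
    for c, lst in enumerate(cells):
        ptr[c + 1] = ptr[c] + len(lst)
    items = np.empty(ptr[-1], dtype=np.int64)
    for c, lst in enumerate(cells):
        items[ptr[c]: ptr[c + 1]] = lst
    return gx0, cell, nx, ptr, items


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False, inline="always")
def _jump(st, h, ptr, to, qdt, qhit):
    # Consumes exactly two random draws regardless of outcome so that runs
    # with the same seed but different rate tables keep their random streams
    # in lockstep (common random numbers across conditions).
    u1 = np.random.random()
    u2 = np.random.random()
    lo, hi = ptr[st], ptr[st + 1]
    q = 0.0
    for j in range(lo, hi):
        q += qdt[j] + qhit[j] * h
    if q <= 0.0:
        return st
    if u1 >= 1.0 - np.exp(-q):
        return st
    u = u2 * q
    acc = 0.0
    for j in range(lo, hi):
        acc += qdt[j] + qhit[j] * h
        if u <= acc:
            return to[j]
    return to[hi - 1]


@njit(cache=False)
def _simulate_kernel(
    seed,
    n_steps,
    release_counts,
    rel_x,
    rel_y,
    sigma,
    r_glia,
    height,
    p_uptake,
    rec_x,
    rec_y,
    rec_r2,
    rec_is_fast,
    gx0,
    cell,
    nx,
    grid_ptr,
    grid_items,
    f_ptr,
    f_to,
    f_qdt,
    f_qhit,
    f_open,
    f_init,
    s_ptr,
    s_to,
    s_qdt,
    s_qhit,
    s_open,
    s_init,
):
    np.random.seed(seed)
    n_rec = len(rec_x)
    n_total = 0
    for i in range(len(release_counts)):
        n_total += release_counts[i]
    mx = np.empty(n_total)
    my = np.empty(n_total)
    mz = np.empty(n_total)
    states = np.empty(n_rec, dtype=np.int64)
    for r in range(n_rec):
        states[r] = f_init if rec_is_fast[r] else s_init
    hits = np.zeros(n_rec, dtype=np.int64)
    hits_total = np.zeros(n_rec, dtype=np.int64)

    n_open_fast = np.zeros(n_steps, dtype=np.int32)
    n_open_slow = np.zeros(n_steps, dtype=np.int32)
    free = np.zeros(n_steps, dtype=np.int32)
    absorbed_arr = np.zeros(n_steps, dtype=np.int32)

    n_active = 0
    absorbed = 0

    for t in range(n_steps):
        if t < len(release_counts):
            for _ in range(release_counts[t]):
                mx[n_active] = rel_x
                my[n_active] = rel_y
                mz[n_active] = height
                n_active += 1

        i = 0
        while i < n_active:
            dx = sigma * np.random.normal()
            dy = sigma * np.random.normal()
            dz = sigma * np.random.normal()
            x0 = mx[i]
            y0 = my[i]
            z0 = mz[i]
            x1 = x0 + dx
            y1 = y0 + dy
            z1 = z0 + dz

            hit_bottom = False
            tf = 1.0
            if z1 < 0.0:
                hit_bottom = True
                tf = z0 / (z0 - z1) if z0 != z1 else 0.0
            zb = z1
            guard = 0
            while (zb < 0.0 or zb > height) and guard < 64:
                if zb < 0.0:
                    zb = -zb
                    hit_bottom = True
                else:
                    zb = 2.0 * height - zb
                guard += 1
            if zb < 0.0:
                zb = 0.0
            elif zb > height:
                zb = height

            if hit_bottom and n_rec > 0:
                hx = x0 + tf * dx
                hy = y0 + tf * dy
                ci = int((hx - gx0) / cell)
                cj = int((hy - gx0) / cell)
                if 0 <= ci < nx and 0 <= cj < nx:
                    c = ci * nx + cj
                    for q in range(grid_ptr[c], grid_ptr[c + 1]):
                        r = grid_items[q]
                        ddx = hx - rec_x[r]
                        ddy = hy - rec_y[r]
                        if ddx * ddx + ddy * ddy <= rec_r2:
                            # overlapping discs each register the crossing:
                            # reflection does not consume the molecule
                            hits[r] += 1
                            hits_total[r] += 1

            removed = False
            rr = np.sqrt(x1 * x1 + y1 * y1)
            if rr > r_glia:
                if np.random.random() < p_uptake:
                    n_active -= 1
                    mx[i] = mx[n_active]
                    my[i] = my[n_active]
                    mz[i] = mz[n_active]
                    absorbed += 1
                    removed = True
                else:
                    s = (2.0 * r_glia - rr) / rr
                    if s < 0.0:
                        s = 0.0
                    x1 *= s
                    y1 *= s
            if not removed:
                mx[i] = x1
                my[i] = y1
                mz[i] = zb
                i += 1

        nf = 0
        ns = 0
        for r in range(n_rec):
            h = hits[r]
            hits[r] = 0
            if rec_is_fast[r]:
                st = _jump(states[r], h, f_ptr, f_to, f_qdt, f_qhit)
                states[r] = st
                if f_open[st]:
                    nf += 1
            else:
                st = _jump(states[r], h, s_ptr, s_to, s_qdt, s_qhit)
                states[r] = st
                if s_open[st]:
                    ns += 1
        n_open_fast[t] = nf
        n_open_slow[t] = ns
        free[t] = n_active
        absorbed_arr[t] = absorbed

    return n_open_fast, n_open_slow, free, absorbed_arr, hits_total


@njit(cache=False)
def _clamped_kernel(seed, n_steps, n_rec, lam, ptr, to, qdt, qhit, init, n_states):
    np.random.seed(seed)
    states = np.full(n_rec, init, dtype=np.int64)
    occ = np.zeros((n_steps, n_states), dtype=np.int32)
    for t in range(n_steps):
        for r in range(n_rec):
            h = np.random.poisson(lam) if lam > 0.0 else 0
            states[r] = _jump(states[r], h, ptr, to, qdt, qhit)
            occ[t, states[r]] += 1
    return occ


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """A (possibly averaged) simulated quantal current.

    ``current_pA`` follows I(t) = sum_type g_type n_type(t) (Vm - Vrev);
    open counts are floats after averaging.  ``free`` / ``absorbed`` /
    ``released_cum`` audit glutamate conservation at every step.
    """

    t_us: np.ndarray
    current_pA: np.ndarray
    n_open_fast: np.ndarray
    n_open_slow: np.ndarray
    free: np.ndarray
    absorbed: np.ndarray
    released_cum: np.ndarray
    vm_mV: float = -60.0
    vrev_mV: float = 0.0
    g_fast_pS: float = 45.0
    g_slow_pS: float = 31.0
    n_runs: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def dt_us(self) -> float:
        return float(self.t_us[1] - self.t_us[0]) if len(self.t_us) > 1 else 0.0

    @property
    def fast_component_pA(self) -> np.ndarray:
        return self.g_fast_pS * self.n_open_fast * (self.vm_mV - self.vrev_mV) * 1e-3

    @property
    def slow_component_pA(self) -> np.ndarray:
        return self.g_slow_pS * self.n_open_slow * (self.vm_mV - self.vrev_mV) * 1e-3

    def conservation_ok(self) -> bool:
        return bool(np.all(self.free + self.absorbed == self.released_cum))

    def fast_share_at_peak(self) -> float:
        """Fast-receptor fraction of the current at the trace peak."""
        i = int(np.argmax(np.abs(self.current_pA)))
        tot = abs(self.fast_component_pA[i]) + abs(self.slow_component_pA[i])
        return float(abs(self.fast_component_pA[i]) / tot) if tot > 0 else np.nan

    @property
    def peak_amplitude_pA(self) -> float:
        return float(np.max(np.abs(self.current_pA)))

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        s = slice(None, None, max(int(stride), 1))
        return pd.DataFrame(
            {
                "t_us": self.t_us[s],
                "current_pA": self.current_pA[s],
                "n_open_fast": self.n_open_fast[s],
                "n_open_slow": self.n_open_slow[s],
                "free_glutamate": self.free[s],
                "absorbed_glutamate": self.absorbed[s],
                "released_cum": self.released_cum[s],
            }
        )


def current_pA(n_open_fast, n_open_slow, g_fast_pS, g_slow_pS, vm_mV, vrev_mV) -> np.ndarray:
    """Ohmic current: I = sum over types of g * n * (Vm - Vrev), in pA."""
    drive_mV = vm_mV - vrev_mV
    return (
        np.asarray(n_open_fast, float) * g_fast_pS + np.asarray(n_open_slow, float) * g_slow_pS
    ) * drive_mV * 1e-3


def count_hits(p0: np.ndarray, p1: np.ndarray, receptor_map) -> np.ndarray:
    """Hits per receptor for one set of steps (reference implementation).

    A hit is a step whose straight segment from ``p0`` to ``p1`` crosses the
    postsynaptic plane z = 0 inside a receptor disc; the crossing point is
    linearly interpolated.  Overlapping discs each register the crossing:
    the molecule is reflected, not consumed, so receptors do not compete.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    hits = np.zeros(receptor_map.n_total, dtype=np.int64)
    crosses = (p0[:, 2] > 0) & (p1[:, 2] <= 0)
    if not crosses.any():
        return hits
    a, b = p0[crosses], p1[crosses]
    tf = a[:, 2] / (a[:, 2] - b[:, 2])
    cx = a[:, 0] + tf * (b[:, 0] - a[:, 0])
    cy = a[:, 1] + tf * (b[:, 1] - a[:, 1])
    d2 = (cx[:, None] - receptor_map.positions[None, :, 0]) ** 2 + (
        cy[:, None] - receptor_map.positions[None, :, 1]
    ) ** 2
    return (d2 <= receptor_map.receptor_disc_radius**2).sum(axis=0).astype(np.int64)


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------


def _draw_release_site(config: SimConfig, rng: np.random.Generator) -> tuple[float, float]:
    radius = (
        config.geometry.psd_radius
        if config.vesicle.release_site_mode == "synaptic_cluster"
        else config.geometry.nanocluster_radius
    )
    r = radius * np.sqrt(rng.uniform())
    th = rng.uniform(0.0, 2.0 * np.pi)
    return float(r * np.cos(th)), float(r * np.sin(th))


def run_quantal_event(config: SimConfig, seed: int = 0, release_site=None) -> Trace:
    """Simulate one quantal event; deterministic under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    if release_site is None:
        release_site = _draw_release_site(config, rng)

    dt = config.diffusion.dt_us
    n_steps = int(round(config.duration_ms * 1e3 / dt))
    counts = release_schedule(config.vesicle, dt)
    sigma = config.diffusion.sigma_nm
    rm = config.receptor_map
    c_hit = hit_concentration_mM(rm.receptor_disc_radius, sigma)

    f_arr = _scheme_arrays(config.fast_scheme, config.rate_scale, dt, c_hit)
    s_arr = _scheme_arrays(config.slow_scheme, config.rate_scale, dt, c_hit)
    gx0, cell, nx, gptr, gitems = _receptor_grid(
        rm.positions[:, 0], rm.positions[:, 1], rm.receptor_disc_radius
    )

    nf, ns, free, absorbed, hits_total = _simulate_kernel(
        kernel_seed,
        n_steps,
        counts.astype(np.int64),
        float(release_site[0]),
        float(release_site[1]),
        sigma,
        config.geometry.glial_radius,
        config.geometry.cleft_height,
        config.geometry.uptake_probability,
        rm.positions[:, 0].astype(np.float64),
        rm.positions[:, 1].astype(np.float64),
        float(rm.receptor_disc_radius**2),
        rm.is_fast.astype(np.bool_),
        gx0,
        cell,
        nx,
        gptr,
        gitems,
        *f_arr,
        *s_arr,
    )

    released_cum = np.cumsum(
        np.pad(counts, (0, max(n_steps - len(counts), 0)))[:n_steps]
    ).astype(np.int64)
    t_us = np.arange(n_steps) * dt
    cur = current_pA(
        nf, ns, config.fast_scheme.conductance_pS, config.slow_scheme.conductance_pS,
        config.vm_mV, config.vrev_mV,
    )
    return Trace(
        t_us=t_us,
        current_pA=cur,
        n_open_fast=nf.astype(float),
        n_open_slow=ns.astype(float),
        free=free.astype(np.int64),
        absorbed=absorbed.astype(np.int64),
        released_cum=released_cum,
        vm_mV=config.vm_mV,
        vrev_mV=config.vrev_mV,
        g_fast_pS=config.fast_scheme.conductance_pS,
        g_slow_pS=config.slow_scheme.conductance_pS,
        meta={
            "seed": seed,
            "release_site": tuple(release_site),
            "hits_total": int(hits_total.sum()),
        },
    )


def average_traces(config: SimConfig, n_runs: int = 160, seed: int = 0):
    """Average ``n_runs`` independently seeded quantal events pointwise.

    Release sites are redrawn per run.  Returns the mean trace (metrics are
    computed on it by the caller) and a per-run metrics table with each
    run's peak amplitude.  One global seed fans out deterministically to
    per-run child seeds, so two conditions simulated with the same seed
    share their random streams run-for-run (common random numbers).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    children = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    acc: Trace | None = None
    rows = []
    for i in range(n_runs):
        tr = run_quantal_event(config, seed=int(children[i]))
        rows.append(
            {
                "run": i,
                "seed": int(children[i]),
                "peak_amplitude_pA": tr.peak_amplitude_pA,
                "release_x_nm": tr.meta["release_site"][0],
                "release_y_nm": tr.meta["release_site"][1],
                "conservation_ok": tr.conservation_ok(),
            }
        )
        if acc is None:
            acc = tr
            acc.meta = {"seed": seed, "n_runs": n_runs}
        else:
            acc.current_pA = acc.current_pA + tr.current_pA
            acc.n_open_fast = acc.n_open_fast + tr.n_open_fast
            acc.n_open_slow = acc.n_open_slow + tr.n_open_slow
            acc.free = acc.free + tr.free
            acc.absorbed = acc.absorbed + tr.absorbed
            acc.released_cum = acc.released_cum + tr.released_cum
    for name in ("current_pA", "n_open_fast", "n_open_slow", "free", "absorbed", "released_cum"):
        setattr(acc, name, getattr(acc, name) / n_runs)
    acc.n_runs = n_runs
    return acc, pd.DataFrame(rows)


def run_clamped(
    scheme: KineticScheme,
    conc_mM: float,
    duration_ms: float,
    n_receptors: int = 1000,
    seed: int = 0,
    dt_us: float = 0.5,
    rate_scale: float = 1.0,
    receptor_radius_nm: float = 10.0,
    sigma_nm: float | None = None,
) -> np.ndarray:
    """Stochastic receptors under a clamped uniform glutamate concentration.

    Diffusion is bypassed: per-step hit counts are Poisson with the mean the
    cleft geometry would produce at ``conc_mM``.  Returns state-occupancy
    fractions of shape (n_steps, n_states) — the Monte Carlo side of the
    well-mixed oracle check against deterministic rate-equation integration.
    """
    if sigma_nm is None:
        sigma_nm = np.sqrt(2.0 * 400.0 * dt_us)  # default D = 0.4 um^2/ms
    c_hit = hit_concentration_mM(receptor_radius_nm, sigma_nm)
    lam = expected_hits_per_step(conc_mM, receptor_radius_nm, sigma_nm)
    ptr, to, qdt, qhit, _, init = _scheme_arrays(scheme, rate_scale, dt_us, c_hit)
    n_steps = int(round(duration_ms * 1e3 / dt_us))
    occ = _clamped_kernel(
        int(seed) % (2**31 - 1), n_steps, int(n_receptors), float(lam),
        ptr, to, qdt, qhit, init, scheme.n_states,
    )
    return occ / float(n_receptors)
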