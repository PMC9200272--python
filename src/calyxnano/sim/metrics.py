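"""Quantification of simulated quantal currents.

Amplitude is the absolute peak of the trace; the 10-90% rise time is
interpolated on the rising phase; the decay time comes from an
amplitude-weighted double-exponential fit of the decay phase,
A1 exp(-t/tau1) + A2 exp(-t/tau2), reported as
(A1 tau1 + A2 tau2)/(A1 + A2).  When the fit fails the 1/e decay time is
used instead and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class TraceMetrics:
    peak_amplitude_pA: float
    rise_10_90_us: float
    decay_tau_us: float
    tau1_us: float = np.nan
    tau2_us: float = np.nan
    a1: float = np.nan
    a2: float = np.nan
    decay_fit_rms: float = np.nan
    fallback_used: bool = False

    def to_row(self) -> dict:
        return {
            "peak_amplitude_pA": self.peak_amplitude_pA,
            "rise_10_90_us": self.rise_10_90_us,
            "decay_tau_us": self.decay_tau_us,
            "decay_tau1_us": self.tau1_us,
            "decay_tau2_us": self.tau2_us,
            "decay_fit_rms": self.decay_fit_rms,
            "fallback_used": self.fallback_used,
        }


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, i_peak: int) -> float:
    """Last upward crossing of ``level`` before the peak, interpolated."""
    below = np.flatnonzero(y[: i_peak + 1] < level)
    if len(below) == 0:
        return float(t[0])
    i = below[-1]
    if i == i_peak:
        return float(t[i])
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t[i + 1])
    f = (level - y0) / (y1 - y0)
    return float(t[i] + f * (t[i + 1] - t[i]))


def _double_exp(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def trace_metrics(t_us: np.ndarray, current_pA: np.ndarray) -> TraceMetrics:
    """Amplitude, 10-90% rise, and weighted double-exponential decay time."""
    t = np.asarray(t_us, float)
    y = np.abs(np.asarray(current_pA, float))
    i_peak = int(np.argmax(y))
    amp = float(y[i_peak])
    if amp == 0.0:
        raise ValueError("trace has no nonzero extremum")

    t10 = _crossing_time(t, y, 0.1 * amp, i_peak)
    t90 = _crossing_time(t, y, 0.9 * amp, i_peak)
    rise = max(t90 - t10, 0.0)

    td = t[i_peak:] - t[i_peak]
    yd = y[i_peak:]
    # fit only down to 1% of the peak: the sub-percent tail (rare reopenings
    # from desensitized states) otherwise drags tau2 to arbitrarily large values
    below_floor = np.flatnonzero(yd < 0.01 * amp)
    if len(below_floor) > 2:
        td = td[: below_floor[0] + 1]
        yd = yd[: below_floor[0] + 1]
    span = float(td[-1]) if len(td) > 1 else float(t[-1] - t[i_peak])
    # 1/e estimate seeds the fit and is the fallback
    below_e = np.flatnonzero(yd <= amp / np.e)
    tau_e = float(td[below_e[0]]) if len(below_e) else span
    tau_e = max(tau_e, max(float(t[1] - t[0]), 1e-6))

    try:
        if len(td) < 8:
            raise RuntimeError("decay segment too short to fit")
        p0 = [0.6 * amp, min(0.5 * tau_e, span), 0.4 * amp, min(3.0 * tau_e, 2.0 * span)]
        popt, _ = curve_fit(
            _double_exp, td, yd, p0=p0,
            bounds=([0, 1e-6, 0, 1e-6], [1.5 * amp, 2.0 * span, 1.5 * amp, 2.0 * span]),
            maxfev=20000,
        )
        a1, tau1, a2, tau2 = popt
        if tau1 > tau2:  # report the fast component first
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        w = a1 + a2
        if w <= 0:
            raise RuntimeError("degenerate fit")
        decay = float((a1 * tau1 + a2 * tau2) / w)
        rms = float(np.sqrt(np.mean((_double_exp(td, a1, tau1, a2, tau2) - yd) ** 2)))
        return TraceMetrics(amp, rise, decay, float(tau1), float(tau2), float(a1), float(a2), rms, False)
    except (RuntimeError, ValueError):
        return TraceMetrics(amp, rise, tau_e, fallback_used=True)


def metrics_of(trace) -> TraceMetrics:
    return trace_metrics(trace.t_us, trace.current_pA)
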