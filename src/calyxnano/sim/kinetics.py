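"""Nine-state stochastic AMPAR gating scheme.

The receptor model is a Markov chain with nine states: an unbound closed
state C0, singly and doubly liganded closed states C1/C2, the open state O
reached from C2, a desensitized state entered from the open state (OD), and
a chain of liganded desensitized states D1 (from C1), D2 (from C2), and the
deeper D3/D4.  Two glutamate binding steps (C0->C1, C1->C2, and D1->D2 on
the desensitized branch) carry concentration dependence; all other
transitions are concentration independent.

The C1-C2-D2-D1 square is the scheme's single cycle; its rates must satisfy
microscopic reversibility (equal clockwise and counter-clockwise rate
products), which ``nine_state_scheme`` enforces by construction and
``KineticScheme.check_reversibility`` verifies for arbitrary rate tables.

Rates are data, not code: the tables below are defaults for fast-gating
(GluA4-like, 45 pS) and slow-gating (GluA1-like, 31 pS) receptors,
calibrated to give deactivation/desensitization kinetics in the ranges
reported for calyx-type AMPARs; any table with the same state vocabulary can
be supplied through the configuration file.

Units: concentration-independent rates in 1/ms; binding rates in 1/(mM*ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp

STATE_NAMES = ("C0", "C1", "C2", "O", "OD", "D1", "D2", "D3", "D4")
REVERSIBILITY_RTOL = 1e-6


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate: float  # 1/ms, or 1/(mM*ms) if glu_dependent
    glu_dependent: bool = False


@dataclass
class KineticScheme:
    """A receptor gating scheme: states, transitions and channel conductance."""

    states: tuple = STATE_NAMES
    transitions: tuple = ()
    conductance_pS: float = 45.0
    open_states: tuple = ("O",)
    initial_state: str = "C0"
    label: str = "fast"

    # -- structure ---------------------------------------------------------

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def scaled(self, factor: float) -> "KineticScheme":
        """All rate constants multiplied by ``factor`` (KO fit uses 0.6).

        Uniform scaling preserves microscopic reversibility exactly (both
        cycle products pick up the same power of the factor).
        """
        return replace(
            self,
            transitions=tuple(replace(t, rate=t.rate * factor) for t in self.transitions),
            label=f"{self.label}*{factor:g}",
        )

    # -- numerics ----------------------------------------------------------

    def rate_matrix(self, conc_mM: float) -> np.ndarray:
        """Generator matrix Q (1/ms) at glutamate concentration ``conc_mM``.

        Q[i, j] is the i->j rate; diagonal entries make rows sum to zero.
        """
        n = self.n_states
        q = np.zeros((n, n))
        for t in self.transitions:
            r = t.rate * conc_mM if t.glu_dependent else t.rate
            q[self.state_index(t.source), self.state_index(t.target)] += r
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q

    def stationary_distribution(self, conc_mM: float) -> np.ndarray:
        q = self.rate_matrix(conc_mM)
        evals, evecs = np.linalg.eig(q.T)
        k = int(np.argmin(np.abs(evals)))
        pi = np.real(evecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def integrate(self, conc_of_t, t_eval_ms: np.ndarray, p0: np.ndarray | None = None) -> np.ndarray:
        """Deterministic integration of dP/dt = Q(C(t))^T P.

        ``conc_of_t`` maps time (ms) to glutamate concentration (mM).  Serves
        as the well-mixed oracle for the stochastic engine.
        """
        if p0 is None:
            p0 = np.zeros(self.n_states)
            p0[self.state_index(self.initial_state)] = 1.0

        def rhs(t, p):
            return self.rate_matrix(float(conc_of_t(t))).T @ p

        sol = solve_ivp(
            rhs, (t_eval_ms[0], t_eval_ms[-1]), p0, t_eval=t_eval_ms,
            method="LSODA", rtol=1e-8, atol=1e-10,
        )
        return sol.y.T

    # -- validation --------------------------------------------------------

    def max_independent_rate(self) -> float:
        return max((t.rate for t in self.transitions if not t.glu_dependent), default=0.0)

    def check_reversibility(self, rtol: float = REVERSIBILITY_RTOL) -> None:
        """Verify every cycle has equal forward and backward rate products.

        Glutamate-dependent rates are evaluated at 1 mM; a cycle is only
        reversible at all concentrations if it has equally many binding
        steps in each direction, which this numeric check then covers.
        """
        g = nx.Graph()
        rates: dict[tuple[str, str], float] = {}
        nglu: dict[tuple[str, str], int] = {}
        for t in self.transitions:
            g.add_edge(t.source, t.target)
            rates[(t.source, t.target)] = t.rate
            nglu[(t.source, t.target)] = int(t.glu_dependent)
        for cycle in nx.cycle_basis(g):
            fwd = bwd = 1.0
            gf = gb = 0
            edges = list(zip(cycle, cycle[1:] + cycle[:1]))
            for a, b in edges:
                if (a, b) not in rates or (b, a) not in rates:
                    raise ValueError(f"cycle edge {a}<->{b} is not bidirectional")
                fwd *= rates[(a, b)]
                bwd *= rates[(b, a)]
                gf += nglu[(a, b)]
                gb += nglu[(b, a)]
            if gf != gb:
                raise ValueError(f"cycle {cycle}: unbalanced binding steps ({gf} vs {gb})")
            if not np.isclose(fwd, bwd, rtol=rtol):
                raise ValueError(
                    f"cycle {cycle} violates microscopic reversibility: {fwd:g} vs {bwd:g}"
                )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "states": list(self.states),
            "conductance_pS": self.conductance_pS,
            "open_states": list(self.open_states),
            "initial_state": self.initial_state,
            "transitions": [
                {"from": t.source, "to": t.target, "rate": t.rate, "glu": t.glu_dependent}
                for t in self.transitions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            states=tuple(d["states"]),
            transitions=tuple(
                Transition(t["from"], t["to"], float(t["rate"]), bool(t.get("glu", False)))
                for t in d["transitions"]
            ),
            conductance_pS=float(d["conductance_pS"]),
            open_states=tuple(d.get("open_states", ("O",))),
            initial_state=d.get("initial_state", "C0"),
            label=d.get("label", "custom"),
        )


def nine_state_scheme(
    kon: float,
    koff: float,
    beta: float,
    alpha: float,
    kod: float,
    kdo: float,
    kd1: float,
    kr1: float,
    kd2: float,
    kr2: float,
    kond: float,
    k23: float,
    k32: float,
    k34: float,
    k43: float,
    conductance_pS: float,
    label: str,
) -> KineticScheme:
    """Build the nine-state scheme with reversibility enforced by construction.

    The unbinding rate on the desensitized branch (D2 -> D1) is derived from
    the other seven rates of the C1-C2-D2-D1 cycle so the cycle's rate
    products balance exactly.
    """
    koffd = 2.0 * koff * kr2 * kond * kd1 / (kon * kd2 * kr1)
    trans = (
        Transition("C0", "C1", 2.0 * kon, True),
        Transition("C1", "C0", koff),
        Transition("C1", "C2", kon, True),
        Transition("C2", "C1", 2.0 * koff),
        Transition("C2", "O", beta),
        Transition("O", "C2", alpha),
        Transition("O", "OD", kod),
        Transition("OD", "O", kdo),
        Transition("C1", "D1", kd1),
        Transition("D1", "C1", kr1),
        Transition("C2", "D2", kd2),
        Transition("D2", "C2", kr2),
        Transition("D1", "D2", kond, True),
        Transition("D2", "D1", koffd),
        Transition("D2", "D3", k23),
        Transition("D3", "D2", k32),
        Transition("D3", "D4", k34),
        Transition("D4", "D3", k43),
    )
    scheme = KineticScheme(STATE_NAMES, trans, conductance_pS, ("O",), "C0", label)
    scheme.check_reversibility()
    return scheme


# Default rate tables for the two gating classes (1/ms; binding 1/(mM*ms)).
FAST_RATES = dict(
    kon=3.0, koff=6.0, beta=17.0, alpha=3.0,
    kod=0.3, kdo=0.005, kd1=0.2, kr1=0.02, kd2=0.6, kr2=0.05,
    kond=3.0, k23=0.2, k32=0.02, k34=0.05, k43=0.01,
)
SLOW_RATES = dict(
    kon=3.0, koff=2.0, beta=5.5, alpha=1.25,
    kod=0.175, kdo=0.004, kd1=0.125, kr1=0.015, kd2=0.4, kr2=0.04,
    kond=3.0, k23=0.15, k32=0.015, k34=0.04, k43=0.008,
)

FAST_CONDUCTANCE_PS = 45.0
SLOW_CONDUCTANCE_PS = 31.0


def default_scheme(kind: str) -> KineticScheme:
    """Default fast- or slow-gating receptor scheme."""
    if kind == "fast":
        return nine_state_scheme(**FAST_RATES, conductance_pS=FAST_CONDUCTANCE_PS, label="fast")
    if kind == "slow":
        return nine_state_scheme(**SLOW_RATES, conductance_pS=SLOW_CONDUCTANCE_PS, label="slow")
    raise ValueError(f"unknown scheme kind {kind!r}")
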