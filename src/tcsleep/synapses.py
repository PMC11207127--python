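"""Synaptic receptor models.

Four receptor types drive the network.  AMPA, NMDA and GABA_A follow a
first-order binding scheme driven by a rectangular transmitter pulse T
released at each presynaptic spike:

    dO/dt = alpha * T * (1 - O) - beta * O
    T(t)  = A * theta(t0 + t_max - t) * theta(t - t0)

GABA_B uses a second-order G-protein cascade

    dR/dt = K1 * T * (1 - R) - K2 * R
    dG/dt = K3 * R - K4 * G
    I     = g * G^4 / (G^4 + Kd) * (V - E_K)

(The constant sometimes quoted as "K4 = 100 uM^4" has the units of a
dissociation constant and enters as Kd; the decay rate K4 is 0.033 ms^-1.)

Intracortical AMPA and GABA_A conductances are scaled by a short-term
depression resource D, updated once per presynaptic spike:

    D_{n+1} = 1 - (1 - D_n * (1 - U)) * exp(-dt / tau_rec)

NMDA additionally carries the voltage gate f(V) = 1/(1+exp(-(V-Vth)/sigma)).

All updates are exact exponential solutions over a step with T held
piecewise-constant, so they are unconditionally stable and match a finely
sub-stepped integration to high accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Receptor",
    "GababParams",
    "ReceptorParams",
    "DepressionParams",
    "SynapseState",
    "RECEPTOR_DEFAULTS",
    "transmitter_pulse",
    "step_first_order",
    "nmda_gate",
    "depression_update",
    "step_gabab",
    "synaptic_current",
]


class Receptor(str, Enum):
    AMPA = "AMPA"
    NMDA = "NMDA"
    GABA_A = "GABA_A"
    GABA_B = "GABA_B"


@dataclass(frozen=True)
class GababParams:
    K1: float = 0.52     # mM^-1 ms^-1 (canonical; see kinetics note)
    K2: float = 0.0013   # ms^-1
    K3: float = 0.098    # uM ms^-1
    K4: float = 0.033    # ms^-1 (G-protein decay rate)
    Kd: float = 100.0    # uM^4
    n: int = 4


@dataclass(frozen=True)
class ReceptorParams:
    receptor: Receptor
    g_syn: float             # maximal conductance, uS
    E_syn: float             # mV
    alpha: float = 0.0       # binding rate, ms^-1 mM^-1
    beta: float = 0.0        # unbinding rate, ms^-1
    A: float = 0.5           # transmitter pulse amplitude (mM-like)
    t_max: float = 0.3       # transmitter pulse duration, ms (see note below)
    nmda_sigma: float = 12.5
    nmda_Vth: float = -25.0
    gabab: GababParams = field(default_factory=GababParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.A <= 1.0):
            raise ValueError("A must be in (0, 1]")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")


#: per-receptor kinetic defaults (conductance
#: is projection-specific and filled from the connection table)
RECEPTOR_DEFAULTS: dict[Receptor, ReceptorParams] = {
    Receptor.AMPA: ReceptorParams(Receptor.AMPA, 0.0, 0.0, alpha=1.1, beta=0.19),
    Receptor.NMDA: ReceptorParams(Receptor.NMDA, 0.0, 0.0, alpha=1.0, beta=0.0067),
    Receptor.GABA_A: ReceptorParams(Receptor.GABA_A, 0.0, -70.0, alpha=10.5, beta=0.166),
    Receptor.GABA_B: ReceptorParams(Receptor.GABA_B, 0.0, -95.0),
}


@dataclass(frozen=True)
class DepressionParams:
    U: float = 0.07          # resource fraction used per spike (AMPA); GABA_A 0.073
    tau_rec: float = 700.0   # recovery time constant, ms

    def __post_init__(self) -> None:
        if not (0.0 < self.U < 1.0):
            raise ValueError("U must be in (0, 1)")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be > 0")


@dataclass
class SynapseState:
    """Kinetic state of one connection (or of one presynaptic release site)."""

    O: float = 0.0           # open fraction (first-order receptors)
    D: float = 1.0           # available resources
    R: float = 0.0           # activated GABA_B receptor fraction
    G: float = 0.0           # G-protein concentration, uM
    pulse_t0: float = -math.inf   # last presynaptic activation time, ms
    last_spike_t: float = -math.inf


def transmitter_pulse(t: float, pulse_t0: float, params: ReceptorParams) -> float:
    """Rectangular transmitter concentration: A while t in [t0, t0+t_max]."""
    if pulse_t0 <= t <= pulse_t0 + params.t_max:
        return params.A
    return 0.0


def step_first_order(
    O: float, T: float, alpha: float, beta: float, dt: float
) -> float:
    """Exact exponential update of dO/dt = alpha*T*(1-O) - beta*O with T
    constant over the step."""
    lam = alpha * T + beta
    if lam == 0.0:
        return O
    O_inf = alpha * T / lam
    return O_inf + (O - O_inf) * math.exp(-lam * dt)


def nmda_gate(V: float, sigma: float = 12.5, Vth: float = -25.0) -> float:
    """Voltage dependence of the NMDA conductance (1 for AMPA/GABA_A)."""
    x = -(V - Vth) / sigma
    if x > 50.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def depression_update(
    D: float, dt_since_spike: float, params: DepressionParams
) -> float:
    """Resource level seen by the (n+1)-th spike, given level D used by the
    n-th spike and the inter-spike interval."""
    if not (0.0 < D <= 1.0):
        raise ValueError("D must be in (0, 1]")
    return 1.0 - (1.0 - D * (1.0 - params.U)) * math.exp(
        -dt_since_spike / params.tau_rec
    )


def step_gabab(
    R: float, G: float, T: float, dt: float, params: GababParams = GababParams()
) -> tuple[float, float]:
    """Advance the G-protein cascade by ``dt`` with T piecewise-constant.

    R has the exact exponential solution; G is integrated in closed form
    against the exponential trajectory of R over the step.
    """
    lamR = params.K1 * T + params.K2
    R_inf = params.K1 * T / lamR if lamR > 0 else 0.0
    R_new = R_inf + (R - R_inf) * math.exp(-lamR * dt)

    # dG/dt = K3*R(t) - K4*G  with R(t) = R_inf + (R - R_inf) e^{-lamR t}
    k4 = params.K4
    eK4 = math.exp(-k4 * dt)
    G_new = G * eK4 + params.K3 * R_inf / k4 * (1.0 - eK4)
    dR0 = R - R_inf
    if dR0 != 0.0:
        if abs(lamR - k4) > 1e-12:
            G_new += params.K3 * dR0 * (math.exp(-lamR * dt) - eK4) / (k4 - lamR)
        else:
            G_new += params.K3 * dR0 * dt * eK4
    return R_new, max(G_new, 0.0)


def gabab_fraction(G: float, params: GababParams = GababParams()) -> float:
    """Saturating conductance fraction G^n / (G^n + Kd)."""
    Gn = G ** params.n
    return Gn / (Gn + params.Kd)


def synaptic_current(
    state: SynapseState, params: ReceptorParams, V_post: float
) -> float:
    """Postsynaptic current in nA (g in uS, V in mV); negative = inward.

    AMPA/GABA_A: I = D*g*O*(V-E); NMDA: I = g*O*f(V)*(V-E) (undepressed);
    GABA_B: I = g*G^4/(G^4+Kd)*(V-E_K).
    """
    r = params.receptor
    if r is Receptor.GABA_B:
        return params.g_syn * gabab_fraction(state.G, params.gabab) * (
            V_post - params.E_syn
        )
    f = 1.0
    if r is Receptor.NMDA:
        f = nmda_gate(V_post, params.nmda_sigma, params.nmda_Vth)
        return params.g_syn * state.O * f * (V_post - params.E_syn)
    return state.D * params.g_syn * state.O * (V_post - params.E_syn)
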