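"""Intrinsic membrane currents of the thalamocortical sleep model.

Every voltage- (and calcium-) dependent current used by the cortical
(PY, IN) and thalamic (TC, RE) cells is defined here as a set of
Hodgkin-Huxley rate functions plus a :class:`ChannelSpec` describing gate
powers, maximal conductance and reversal potential.  Currents follow the
generic form

    I_c = g_c * m^M * h^N * (V - E_c)        [uA/cm^2 for density channels]

with gating dynamics dx/dt = -(x - x_inf)/tau_x and, where a temperature
factor applies, tau_x = (1/(alpha+beta))/Q_T with Q_T = 2.9529.

Rates with removable singularities (terms like a*x/(1-exp(-x/q))) are
guarded at the pole by their analytic limit a*q, so each rate is continuous
in V.

The hyperpolarization-activated cation current I_h of TC cells uses a
voltage-gated open fraction O plus a calcium-regulated "open-locked"
fraction OL (P0 + 2Ca <-> P1, O + P1 <-> OL); its state lives in
:class:`IhState`.  The intracellular calcium pool feeding I_KCa and the I_h
regulation is a first-order influx/decay model (:class:`CalciumPool`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable

__all__ = [
    "QT",
    "E_NA",
    "E_K",
    "E_H",
    "E_CA",
    "NAP_TAU_M",
    "ChannelId",
    "ChannelSpec",
    "GatingState",
    "IhParams",
    "IhState",
    "CalciumPool",
    "CHANNELS",
    "PARAM_LEDGER",
    "eval_kinetics",
    "channel_current",
    "step_gating",
    "step_ih",
    "step_calcium",
]

# ---------------------------------------------------------------------------
# constants
# ---------------------------------------------------------------------------

#: temperature scale factor dividing cortical time constants
QT = 2.9529

# Reversal potentials (mV), fixed model constants (E_K matches the K-leak
# reversal).  E_Ca is a Nernst-like fixed value; no per-step update.
E_NA = 50.0
E_K = -95.0
E_H = -40.0
E_CA = 180.0

#: time constant (ms) for the persistent Na activation, which is given only
#: as a steady state; effectively instantaneous.
NAP_TAU_M = 0.2

#: amplitude of the persistent-Na activation sigmoid.  An amplitude of 0.2
#: at the default conductances would leave the quiescent (Down-state)
#: membrane with a net inward current at every voltage — no stable silent
#: state could exist; 0.02 gives a stable resting state.
NAP_M_SCALE = 0.02

_INF = math.inf


class ChannelId(str, Enum):
    PY_NA_SOMA = "PY_Na_soma"
    PY_NA_DEND = "PY_Na_dend"
    PY_K = "PY_K"
    PY_NAP = "PY_Nap"
    PY_KM = "PY_Km"
    PY_KCA = "PY_KCa"
    PY_HVA = "PY_HVA"
    PY_KL = "PY_KL"
    TC_NA = "TC_Na"
    TC_K = "TC_K"
    TC_H = "TC_h"
    TC_T = "TC_T"
    TC_KL = "TC_KL"
    RE_NA = "RE_Na"
    RE_K = "RE_K"
    RE_T = "RE_T"
    RE_KL = "RE_KL"
    LEAK = "leak"


@dataclass(frozen=True)
class ChannelSpec:
    """Static description of one intrinsic current."""

    channel_id: ChannelId
    M: int                     # activation gate power
    N: int                     # inactivation (or single delayed-rectifier) gate power
    g_max: float               # default maximal conductance
    E_rev: float               # reversal potential, mV
    units: str = "mS/cm2"
    Q_T: float = 1.0           # temperature divisor applied to tau (1.0 = none)
    tau_divisors: tuple[float, float] | None = None  # fixed (tau_m, tau_h) divisors
    note: str = ""

    def __post_init__(self) -> None:
        if self.M < 0 or self.N not in (0, 1, 4):
            raise ValueError(f"invalid gate powers M={self.M}, N={self.N}")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass
class GatingState:
    """Activation/inactivation pair for one channel."""

    m: float = 0.0
    h: float = 1.0


@dataclass(frozen=True)
class IhParams:
    """Rate constants of the calcium-regulated I_h scheme."""

    k1: float = 2.5e7   # mM^-4 ms^-1 (binding of 2 Ca^2+ pairs to the regulator)
    k2: float = 4e-4    # ms^-1
    k3: float = 0.1     # ms^-1
    k4: float = 0.001   # ms^-1
    g_inc: float = 2.0  # conductance factor of the open-locked state


@dataclass
class IhState:
    """Open / calcium-bound / open-locked fractions of the I_h scheme."""

    O: float = 0.0
    P1: float = 0.0
    OL: float = 0.0

    @property
    def C(self) -> float:
        return 1.0 - self.O - self.OL


@dataclass
class CalciumPool:
    """First-order intracellular calcium pool.

    d[Ca]/dt = -influx_scale * I_Ca - ([Ca] - Ca_rest)/tau_decay

    with I_Ca the total calcium current (inward = negative, so influx raises
    [Ca]).  A lumped first-order pool standing in for submembrane calcium
    handling; every constant is exposed in the configuration.
    """

    Ca_i: float = 2.4e-4
    influx_scale: float = 5.18e-5  # mM cm^2 / (uA ms); ~1 um shell depth
    tau_decay: float = 5.0         # ms
    Ca_rest: float = 2.4e-4        # mM


# ---------------------------------------------------------------------------
# guarded rate helpers
# ---------------------------------------------------------------------------

def _lin_frac(a: float, x: float, q: float) -> float:
    """a*x / (1 - exp(-x/q)) with the removable singularity at x = 0."""
    if abs(x) < 1e-7:
        return a * q
    return a * x / (1.0 - math.exp(-x / q))


def _lin_expm1(a: float, x: float, q: float) -> float:
    """a*x / (exp(x/q) - 1) with the removable singularity at x = 0."""
    if abs(x) < 1e-7:
        return a * q
    return a * x / math.expm1(x / q)


def _sig(x: float) -> float:
    # overflow-safe logistic 1/(1+exp(x))
    if x > 50.0:
        return 0.0
    if x < -50.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


# ---------------------------------------------------------------------------
# per-channel kinetics:  V, Ca -> (m_inf, tau_m, h_inf, tau_h)
# ---------------------------------------------------------------------------

def _py_na(V: float, Ca: float):
    # activation: both rates have their removable pole at V = -25, with
    # analytic limits 0.182*9 = 1.638 and 0.124*9 = 1.116
    a1 = _lin_frac(0.182, V + 25.0, 9.0)
    b1 = _lin_frac(0.124, -(V + 25.0), 9.0)
    tau_m = (1.0 / (a1 + b1)) / QT
    m_inf = a1 / (a1 + b1)
    # inactivation: tau from the rate pair, h_inf from a direct sigmoid
    a2 = _lin_frac(0.024, V + 40.0, 5.0)
    b2 = _lin_frac(0.0091, V - 85.0, 5.0)
    tau_h = (1.0 / (a2 + b2)) / QT
    h_inf = _sig((V + 55.0) / 6.2)
    return m_inf, tau_m, h_inf, tau_h


def _py_k(V: float, Ca: float):
    a = _lin_frac(0.02, V - 25.0, 9.0)
    b = _lin_frac(0.002, -(V - 25.0), 9.0)
    tau_n = (1.0 / (a + b)) / QT
    n_inf = a / (a + b)
    # single delayed-rectifier gate, carried in the N-slot (M=0, N=1)
    return 1.0, _INF, n_inf, tau_n


def _py_nap(V: float, Ca: float):
    m_inf = NAP_M_SCALE * _sig(-(V + 42.0) / 5.0)
    return m_inf, NAP_TAU_M, 1.0, _INF


def _py_km(V: float, Ca: float):
    a = _lin_frac(0.001, V + 30.0, 9.0)
    b = _lin_frac(0.001, -(V + 30.0), 9.0)
    tau_m = (1.0 / (a + b)) / QT
    m_inf = a / (a + b)
    return m_inf, tau_m, 1.0, _INF


def _py_kca(V: float, Ca: float):
    a = 0.01 * Ca
    b = 0.02
    tau_m = (1.0 / (a + b)) / QT
    m_inf = a / (a + b)
    return m_inf, tau_m, 1.0, _INF


def _py_hva(V: float, Ca: float):
    a1 = _lin_expm1(0.055, -27.0 - V, 3.8)
    b1 = 0.94 * math.exp((-75.0 - V) / 17.0)
    tau_m = (1.0 / (a1 + b1)) / QT
    m_inf = a1 / (a1 + b1)
    a2 = 0.000457 * math.exp((-13.0 - V) / 50.0)
    b2 = 0.0065 / (math.exp((-V - 15.0) / 28.0) + 1.0)
    tau_h = (1.0 / (a2 + b2)) / QT
    h_inf = a2 / (a2 + b2)
    return m_inf, tau_m, h_inf, tau_h


def _tc_na(V: float, Ca: float):
    # Traub-style kinetics with a consistent u = V + 50 shift (the same
    # shift as the TC/RE delayed-rectifier rates below).
    u = V + 50.0
    am = _lin_expm1(0.32, 13.0 - u, 4.0)
    bm = _lin_expm1(0.28, u - 40.0, 5.0)
    tau_m = 1.0 / (am + bm)
    m_inf = am / (am + bm)
    ah = 0.128 * math.exp((17.0 - u) / 18.0)
    bh = 4.0 * _sig((40.0 - u) / 5.0)
    tau_h = 1.0 / (ah + bh)
    h_inf = ah / (ah + bh)
    return m_inf, tau_m, h_inf, tau_h


def _tc_k(V: float, Ca: float):
    u = V + 50.0
    an = _lin_expm1(0.032, 15.0 - u, 5.0)
    bn = 0.5 * math.exp((10.0 - u) / 40.0)
    tau_n = 1.0 / (an + bn)
    n_inf = an / (an + bn)
    return 1.0, _INF, n_inf, tau_n


def _tc_h(V: float, Ca: float):
    # voltage branch of I_h: relaxation of the open fraction O toward h_inf
    # with time constant tau_s (alpha = h_inf/tau_s, beta = (1-h_inf)/tau_s)
    h_inf = _sig((V + 75.0) / 5.5)
    tau_s = 20.0 + 1000.0 / (
        math.exp((V + 71.5) / 14.2) + math.exp(-(V + 89.0) / 11.6)
    )
    return h_inf, tau_s, 1.0, _INF


def _tc_t(V: float, Ca: float):
    # canonical relay-cell low-threshold Ca kinetics (externally sourced;
    # the table gives I_T only for RE cells)
    m_inf = _sig(-(V + 57.0) / 6.2)
    h_inf = _sig((V + 81.0) / 4.0)
    tau_m = (
        0.612
        + 1.0 / (math.exp(-(V + 132.0) / 16.7) + math.exp((V + 16.8) / 18.2))
    ) / 3.7372
    if V < -80.0:
        tau_h = math.exp((V + 467.0) / 66.6) / 3.7372
    else:
        tau_h = (28.0 + math.exp(-(V + 22.0) / 10.5)) / 3.7372
    return m_inf, tau_m, h_inf, tau_h


def _re_t(V: float, Ca: float):
    m_inf = _sig(-(V + 52.0) / 7.4)
    tau_m = (
        3.0 + 1.0 / (math.exp((V + 27.0) / 10.0) + math.exp(-(V + 102.0) / 15.0))
    ) / 6.8986
    h_inf = _sig((V + 80.0) / 5.0)
    tau_h = (
        85.0 + 1.0 / (math.exp((V + 48.0) / 4.0) + math.exp(-(V + 407.0) / 50.0))
    ) / 3.7372
    return m_inf, tau_m, h_inf, tau_h


def _gateless(V: float, Ca: float):
    return 1.0, _INF, 1.0, _INF


_KINETICS: dict[ChannelId, Callable[[float, float], tuple]] = {
    ChannelId.PY_NA_SOMA: _py_na,
    ChannelId.PY_NA_DEND: _py_na,
    ChannelId.PY_K: _py_k,
    ChannelId.PY_NAP: _py_nap,
    ChannelId.PY_KM: _py_km,
    ChannelId.PY_KCA: _py_kca,
    ChannelId.PY_HVA: _py_hva,
    ChannelId.PY_KL: _gateless,
    ChannelId.TC_NA: _tc_na,
    ChannelId.TC_K: _tc_k,
    ChannelId.TC_H: _tc_h,
    ChannelId.TC_T: _tc_t,
    ChannelId.TC_KL: _gateless,
    ChannelId.RE_NA: _tc_na,
    ChannelId.RE_K: _tc_k,
    ChannelId.RE_T: _re_t,
    ChannelId.RE_KL: _gateless,
    ChannelId.LEAK: _gateless,
}


# Default channel registry (conductance densities in mS/cm^2; the dendritic
# persistent-Na density 2.5 mS/cm^2 is carried in the cells module since the
# registry holds one entry per channel id).
CHANNELS: dict[ChannelId, ChannelSpec] = {
    ChannelId.PY_NA_SOMA: ChannelSpec(ChannelId.PY_NA_SOMA, 3, 1, 2000.0, E_NA, Q_T=QT),
    ChannelId.PY_NA_DEND: ChannelSpec(ChannelId.PY_NA_DEND, 3, 1, 1.3, E_NA, Q_T=QT),
    ChannelId.PY_K: ChannelSpec(ChannelId.PY_K, 0, 1, 200.0, E_K, Q_T=QT),
    ChannelId.PY_NAP: ChannelSpec(ChannelId.PY_NAP, 1, 0, 15.0, E_NA,
                                  note="activation effectively instantaneous"),
    ChannelId.PY_KM: ChannelSpec(ChannelId.PY_KM, 1, 0, 0.014, E_K, Q_T=QT,
                                 note="0.03 mS/cm^2 in IN cells"),
    ChannelId.PY_KCA: ChannelSpec(ChannelId.PY_KCA, 1, 0, 0.4, E_K, Q_T=QT),
    ChannelId.PY_HVA: ChannelSpec(ChannelId.PY_HVA, 2, 1, 0.01, E_CA, Q_T=QT),
    ChannelId.PY_KL: ChannelSpec(ChannelId.PY_KL, 0, 0, 0.0033, E_K),
    ChannelId.TC_NA: ChannelSpec(ChannelId.TC_NA, 3, 1, 90.0, E_NA),
    ChannelId.TC_K: ChannelSpec(ChannelId.TC_K, 0, 4, 10.0, E_K),
    ChannelId.TC_H: ChannelSpec(ChannelId.TC_H, 1, 0, 0.011, E_H,
                                note="conducting fraction O + g_inc*OL"),
    ChannelId.TC_T: ChannelSpec(ChannelId.TC_T, 2, 1, 1.1, E_CA,
                                note="relay-cell kinetics externally sourced"),
    ChannelId.TC_KL: ChannelSpec(ChannelId.TC_KL, 0, 0, 0.03, E_K),
    ChannelId.RE_NA: ChannelSpec(ChannelId.RE_NA, 3, 1, 100.0, E_NA),
    ChannelId.RE_K: ChannelSpec(ChannelId.RE_K, 0, 4, 10.0, E_K),
    ChannelId.RE_T: ChannelSpec(ChannelId.RE_T, 2, 1, 2.0, E_CA,
                                tau_divisors=(6.8986, 3.7372)),
    ChannelId.RE_KL: ChannelSpec(ChannelId.RE_KL, 0, 0, 0.03, E_K),
    ChannelId.LEAK: ChannelSpec(ChannelId.LEAK, 0, 0, 0.033, -68.0),
}


#: human-readable parameter ledger for the dump-params CLI command
PARAM_LEDGER: list[tuple[str, str, str]] = [
    ("g_Na (PY/IN soma)", "2000 mS/cm^2", "maximal fast Na conductance"),
    ("g_K (PY/IN soma)", "200 mS/cm^2", "maximal delayed-rectifier K conductance"),
    ("g_Nap (PY soma)", "15 mS/cm^2", "persistent Na conductance (absent in IN)"),
    ("g_Na (PY/IN dendrite)", "1.3 mS/cm^2", "dendritic fast Na conductance"),
    ("g_Nap (PY dendrite)", "2.5 mS/cm^2", "dendritic persistent Na (absent in IN)"),
    ("g_KL (PY/IN dendrite)", "0.0033 mS/cm^2", "K leak conductance, E_KL = -95 mV"),
    ("g_L / E_L (PY/IN dendrite)", "0.033 mS/cm^2 / -68 mV", "leak"),
    ("g_HVA (PY/IN dendrite)", "0.01 mS/cm^2", "high-threshold Ca conductance"),
    ("g_KCa (PY/IN dendrite)", "0.4 mS/cm^2", "Ca-dependent K conductance"),
    ("g_Km", "0.014 (PY) / 0.03 (IN) mS/cm^2", "slow non-inactivating K"),
    ("C_m (cortex)", "0.75 uF/cm^2", "reduced-model standard value"),
    ("C_m (thalamus)", "1 uF/cm^2", "membrane capacitance"),
    ("g_Na (TC/RE)", "90 / 100 mS/cm^2", "fast Na conductance"),
    ("g_K (TC/RE)", "10 mS/cm^2", "fast K conductance"),
    ("g_KL (TC/RE)", "0.03 mS/cm^2", "K leak, E_KL = -95 mV"),
    ("g_L / E_L (TC)", "0.028 mS/cm^2 / -70 mV", "leak"),
    ("g_L / E_L (RE)", "0.08 mS/cm^2 / -77 mV", "leak"),
    ("g_T (TC/RE)", "1.1 / 2 mS/cm^2", "low-threshold Ca conductance"),
    ("g_h (TC)", "0.011 mS/cm^2", "hyperpolarization-activated cation conductance"),
    ("E_Na / E_K / E_h / E_Ca", "+50 / -95 / -40 / +180 mV",
     "fixed reversals (E_K matches E_KL; E_Ca Nernst-like, no update)"),
    ("Q_T", "2.9529", "temperature divisor of cortical time constants"),
    ("I_h k1..k4", "2.5e7 mM^-4, 4e-4, 0.1, 0.001 ms^-1",
     "calcium-regulation rate constants"),
    ("TC I_T kinetics", "canonical relay-cell sigmoids",
     "externally sourced; table prints I_T only for RE"),
    ("TC/RE I_Na shift", "u = V + 50 mV",
     "shift shared with the delayed-rectifier rates"),
    ("Ca pool", "Ca_rest 2.4e-4 mM; tau 165 ms (cortex) / 5 ms (TC)",
     "lumped first-order influx/decay pool, scales in config"),
]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def eval_kinetics(
    channel_id: ChannelId | str, V: float, Ca_i: float = 0.0
) -> tuple[float, float, float, float]:
    """Steady states and time constants of one channel at voltage ``V``.

    Returns ``(m_inf, tau_m, h_inf, tau_h)``.  Gateless slots report a
    steady state of 1 with an infinite time constant.  ``Ca_i`` only matters
    for the calcium-dependent K current.
    """
    cid = ChannelId(channel_id)
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    if Ca_i < 0:
        raise ValueError("Ca_i must be >= 0")
    try:
        fn = _KINETICS[cid]
    except KeyError:  # pragma: no cover - enum restricts this
        raise KeyError(f"unknown channel id {channel_id!r}") from None
    return fn(float(V), float(Ca_i))


def channel_current(spec: ChannelSpec, gating: GatingState, V: float) -> float:
    """I = g * m^M * h^N * (V - E); positive values are outward currents
    (they enter the voltage equation with a minus sign)."""
    g = spec.g_max
    if spec.M:
        g *= gating.m ** spec.M
    if spec.N:
        g *= gating.h ** spec.N
    return g * (V - spec.E_rev)


def step_gating(
    gating: GatingState,
    kinetics: tuple[float, float, float, float],
    dt: float,
) -> GatingState:
    """Exact exponential relaxation x <- x_inf + (x - x_inf)*exp(-dt/tau)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m_inf, tau_m, h_inf, tau_h = kinetics
    if tau_m <= 0 or tau_h <= 0:
        raise ValueError("non-positive time constant")
    m = m_inf if math.isinf(tau_m) and gating.m == m_inf else (
        m_inf + (gating.m - m_inf) * math.exp(-dt / tau_m)
    )
    h = h_inf + (gating.h - h_inf) * math.exp(-dt / tau_h)
    return GatingState(m=m, h=h)


def step_ih(
    state: IhState,
    V: float,
    Ca_i: float,
    dt: float,
    params: IhParams = IhParams(),
) -> IhState:
    """Advance the two-scheme I_h state by ``dt``.

    Voltage branch: C -> O at rate alpha = h_inf/tau_s, O -> C at
    beta = (1-h_inf)/tau_s.  Calcium branch: P0 + 2Ca <-> P1 (k1*Ca^4, k2)
    and O + P1 -> OL (k3), OL -> O + P1 (k4).  Each linear sub-ODE is
    integrated with its exact exponential update over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    h_inf, tau_s, _, _ = _tc_h(V, Ca_i)
    alpha = h_inf / tau_s
    beta = (1.0 - h_inf) / tau_s

    O, P1, OL = state.O, state.P1, state.OL
    # O: dO/dt = alpha*(1 - O - OL) - beta*O - k3*P1*O + k4*OL
    A = alpha * (1.0 - OL) + params.k4 * OL
    B = alpha + beta + params.k3 * P1
    O_new = A / B + (O - A / B) * math.exp(-B * dt)
    # P1: dP1/dt = k1*Ca^4*(1-P1) - k2*P1
    r = params.k1 * Ca_i ** 4
    lam = r + params.k2
    P1_new = r / lam + (P1 - r / lam) * math.exp(-lam * dt)
    # OL: dOL/dt = k3*P1*O - k4*OL
    drive = params.k3 * P1 * O
    OL_new = drive / params.k4 + (OL - drive / params.k4) * math.exp(-params.k4 * dt)

    O_new = min(max(O_new, 0.0), 1.0)
    OL_new = min(max(OL_new, 0.0), 1.0 - O_new)
    P1_new = min(max(P1_new, 0.0), 1.0)
    return IhState(O=O_new, P1=P1_new, OL=OL_new)


def step_calcium(pool: CalciumPool, I_Ca_total: float, dt: float) -> CalciumPool:
    """Forward step of the calcium pool; inward (negative) Ca current raises
    [Ca]. The concentration is clipped at zero."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dCa = -pool.influx_scale * I_Ca_total - (pool.Ca_i - pool.Ca_rest) / pool.tau_decay
    return replace(pool, Ca_i=max(pool.Ca_i + dt * dCa, 0.0))
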