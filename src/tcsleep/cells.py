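"""Single-cell models: two-compartment cortical (PY, IN) and
single-compartment thalamic (TC, RE) neurons.

Cortical cells follow the reduced two-compartment scheme: the dendrite
carries the full capacitive voltage equation

    C_m dV_D/dt = -g_L (V_D - E_L) - g_SD (V_D - V_S) - I_D^int - I^syn

while the axosomatic compartment (tiny area, very large g_Na/g_K) is
quasi-stationary: its voltage solves the algebraic balance

    g_DS (V_D - V_S) = I_S^int(V_S)

each step, found by damped fixed-point iteration (the balance is linear in
V_S for frozen gating; only the instantaneous persistent-Na term makes it
mildly nonlinear).

Thalamic cells are single compartments:  C_m dV/dt = -g_L(V-E_L) - I^int - I^syn
with I^int = I_Na + I_K + I_KL + I_T (+ I_h for TC).

These classes are the slow, readable reference implementation; the network
engine integrates the same equations in a vectorized kernel and is
cross-checked against trajectories produced here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import channels as ch
from .channels import (
    CalciumPool,
    ChannelId,
    ChannelSpec,
    GatingState,
    IhParams,
    IhState,
    channel_current,
    eval_kinetics,
    step_calcium,
    step_gating,
    step_ih,
)

__all__ = [
    "CorticalParams",
    "CorticalCell",
    "ThalamicParams",
    "ThalamicCell",
    "spike_detect",
    "current_clamp",
]

#: axosomatic area (cm^2); dendritic area is rho times this.  Needed to
#: reconcile density conductances with point (uS) synaptic conductances.
AREA_SOMA = 1.0e-6
#: membrane area of a thalamic compartment (cm^2)
AREA_THAL = 2.9e-4
#: cortical membrane capacitance (uF/cm^2); thalamic is 1.0
CM_CORTEX = 0.75
#: axial soma<->dendrite resistance (MOhm); coupling conductance 1/R
R_AXIAL_MOHM = 10.0


def _spec(cid: ChannelId, g: float) -> ChannelSpec:
    base = ch.CHANNELS[cid]
    return ChannelSpec(cid, base.M, base.N, g, base.E_rev, base.units,
                       base.Q_T, base.tau_divisors)


@dataclass
class CorticalParams:
    cell_class: str = "PY"          # "PY" | "IN"
    rho: float = 165.0              # dendrite/soma area ratio (IN: 50)
    C_m: float = CM_CORTEX
    g_L: float = 0.033
    E_L: float = -68.0
    g_na_soma: float = 2000.0
    g_k_soma: float = 200.0
    g_nap_soma: float = 15.0        # 0 for IN
    g_na_dend: float = 1.3
    g_nap_dend: float = 2.5         # 0 for IN
    g_kl: float = 0.0033
    g_hva: float = 0.01
    g_kca: float = 0.4
    g_km: float = 0.014             # IN: 0.03
    r_axial_mohm: float = R_AXIAL_MOHM
    area_soma: float = AREA_SOMA
    ca_influx_scale: float = 0.02     # calibration constant (see methods)
    ca_tau: float = 165.0
    soma_mode: str = "fixed_point"  # "fixed_point" | "ode" (testing fallback)
    C_m_soma: float = 0.75          # only used in "ode" mode

    @classmethod
    def interneuron(cls) -> "CorticalParams":
        return cls(cell_class="IN", rho=50.0, g_nap_soma=0.0, g_nap_dend=0.0,
                   g_km=0.03)

    @property
    def area_dend(self) -> float:
        return self.rho * self.area_soma

    @property
    def g_sd(self) -> float:
        """Dendrite-side coupling conductance density (mS/cm^2)."""
        g_pt_ms = 1e-3 / self.r_axial_mohm   # 1/MOhm = uS -> mS
        return g_pt_ms / self.area_dend

    @property
    def g_ds(self) -> float:
        """Soma-side coupling conductance density (mS/cm^2)."""
        g_pt_ms = 1e-3 / self.r_axial_mohm
        return g_pt_ms / self.area_soma


class CorticalCell:
    """Two-compartment PY or IN cell with explicit-step integration."""

    def __init__(self, params: CorticalParams | None = None, V0: float = -68.0):
        p = params or CorticalParams()
        self.p = p
        self.V_D = V0
        self.V_S = V0
        Ca0 = 2.4e-4
        self.ca = CalciumPool(Ca_i=Ca0, influx_scale=p.ca_influx_scale,
                              tau_decay=p.ca_tau)
        # dendritic channel set
        self.dend = {
            ChannelId.PY_NA_DEND: _spec(ChannelId.PY_NA_DEND, p.g_na_dend),
            ChannelId.PY_NAP: _spec(ChannelId.PY_NAP, p.g_nap_dend),
            ChannelId.PY_KL: _spec(ChannelId.PY_KL, p.g_kl),
            ChannelId.PY_HVA: _spec(ChannelId.PY_HVA, p.g_hva),
            ChannelId.PY_KCA: _spec(ChannelId.PY_KCA, p.g_kca),
            ChannelId.PY_KM: _spec(ChannelId.PY_KM, p.g_km),
        }
        self.soma = {
            ChannelId.PY_NA_SOMA: _spec(ChannelId.PY_NA_SOMA, p.g_na_soma),
            ChannelId.PY_K: _spec(ChannelId.PY_K, p.g_k_soma),
            ChannelId.PY_NAP: _spec(ChannelId.PY_NAP, p.g_nap_soma),
        }
        self.gd = {cid: self._init_gate(cid, V0) for cid in self.dend}
        self.gs = {cid: self._init_gate(cid, V0) for cid in self.soma}

    def _init_gate(self, cid: ChannelId, V: float) -> GatingState:
        m_inf, _, h_inf, _ = eval_kinetics(cid, V, self.ca.Ca_i)
        return GatingState(m=m_inf, h=h_inf)

    # -- current sums (density, uA/cm^2) ------------------------------------
    def _dend_current(self) -> float:
        return sum(
            channel_current(spec, self.gd[cid], self.V_D)
            for cid, spec in self.dend.items()
        )

    def _soma_conductances(self, V_S: float):
        """(total conductance, conductance-weighted reversal) of the soma
        channel set, with the instantaneous Nap gate evaluated at V_S."""
        g_tot = 0.0
        gE = 0.0
        na = self.soma[ChannelId.PY_NA_SOMA]
        g = na.g_max * self.gs[ChannelId.PY_NA_SOMA].m ** 3 * self.gs[
            ChannelId.PY_NA_SOMA].h
        g_tot += g
        gE += g * na.E_rev
        k = self.soma[ChannelId.PY_K]
        g = k.g_max * self.gs[ChannelId.PY_K].h
        g_tot += g
        gE += g * k.E_rev
        nap = self.soma[ChannelId.PY_NAP]
        if nap.g_max:
            m_inf = eval_kinetics(ChannelId.PY_NAP, V_S)[0]
            g = nap.g_max * m_inf
            g_tot += g
            gE += g * nap.E_rev
        return g_tot, gE

    def solve_soma(self, V_D: float, I_inj_soma: float = 0.0,
                   tol: float = 1e-6, max_iter: int = 50) -> float:
        """Damped fixed-point solve of the quasi-stationary soma balance."""
        p = self.p
        i_inj = I_inj_soma * 1e-3 / p.area_soma  # nA -> uA/cm^2
        V = self.V_S
        for _ in range(max_iter):
            g_tot, gE = self._soma_conductances(V)
            V_new = (p.g_ds * V_D + gE + i_inj) / (p.g_ds + g_tot)
            V_next = V + 0.7 * (V_new - V)
            if abs(V_next - V) < tol:
                V = V_next
                break
            V = V_next
        return V

    def step(self, dt: float, I_inj_soma: float = 0.0, I_inj_dend: float = 0.0,
             I_syn_dend: float = 0.0) -> None:
        """Advance one step.  Injected/synaptic currents in nA (inward < 0
        depolarizes for I_syn; I_inj follows the current-clamp convention:
        positive = depolarizing)."""
        p = self.p
        V_D = self.V_D
        # dendritic voltage equation
        I_int = self._dend_current()
        i_inj = I_inj_dend * 1e-3 / p.area_dend
        i_syn = I_syn_dend * 1e-3 / p.area_dend
        dV = (
            -p.g_L * (V_D - p.E_L)
            - p.g_sd * (V_D - self.V_S)
            - I_int - i_syn + i_inj
        ) / p.C_m
        V_D_new = V_D + dt * dV

        # calcium pool fed by the high-threshold Ca current
        I_ca = channel_current(self.dend[ChannelId.PY_HVA],
                               self.gd[ChannelId.PY_HVA], V_D)
        self.ca = step_calcium(self.ca, I_ca, dt)

        # dendritic gating at the pre-step dendritic voltage
        for cid in self.gd:
            kin = eval_kinetics(cid, V_D, self.ca.Ca_i)
            self.gd[cid] = step_gating(self.gd[cid], kin, dt)

        # soma: quasi-stationary solve (or stiff ODE fallback)
        if p.soma_mode == "ode":
            g_tot, gE = self._soma_conductances(self.V_S)
            i_inj_s = I_inj_soma * 1e-3 / p.area_soma
            dVs = (
                -p.g_ds * (self.V_S - V_D_new)
                - (g_tot * self.V_S - gE) + i_inj_s
            ) / p.C_m_soma
            V_S_new = self.V_S + dt * dVs
        else:
            V_S_new = self.solve_soma(V_D_new, I_inj_soma)
        for cid in self.gs:
            kin = eval_kinetics(cid, V_S_new)
            self.gs[cid] = step_gating(self.gs[cid], kin, dt)

        self.V_D = V_D_new
        self.V_S = V_S_new


@dataclass
class ThalamicParams:
    cell_class: str = "TC"          # "TC" | "RE"
    C_m: float = 1.0
    g_L: float = 0.028              # RE: 0.08
    E_L: float = -70.0              # RE: -77
    g_na: float = 90.0              # RE: 100
    g_k: float = 10.0
    g_kl: float = 0.03
    g_t: float = 1.1                # RE: 2.0
    g_h: float = 0.011              # RE: 0 (no I_h)
    area: float = AREA_THAL
    ca_influx_scale: float = 5.18e-5
    ca_tau: float = 5.0
    ih: IhParams = field(default_factory=IhParams)

    @classmethod
    def reticular(cls) -> "ThalamicParams":
        return cls(cell_class="RE", g_L=0.08, E_L=-77.0, g_na=100.0,
                   g_t=2.0, g_h=0.0)


class ThalamicCell:
    """Single-compartment TC or RE cell."""

    def __init__(self, params: ThalamicParams | None = None, V0: float = -70.0):
        p = params or ThalamicParams()
        self.p = p
        self.V = V0
        is_re = p.cell_class == "RE"
        self.na_id = ChannelId.RE_NA if is_re else ChannelId.TC_NA
        self.k_id = ChannelId.RE_K if is_re else ChannelId.TC_K
        self.t_id = ChannelId.RE_T if is_re else ChannelId.TC_T
        self.kl_id = ChannelId.RE_KL if is_re else ChannelId.TC_KL
        self.specs = {
            self.na_id: _spec(self.na_id, p.g_na),
            self.k_id: _spec(self.k_id, p.g_k),
            self.t_id: _spec(self.t_id, p.g_t),
            self.kl_id: _spec(self.kl_id, p.g_kl),
        }
        self.g = {cid: self._init_gate(cid, V0) for cid in self.specs}
        self.ih_state = IhState()
        if p.g_h:
            h_inf = eval_kinetics(ChannelId.TC_H, V0)[0]
            self.ih_state = IhState(O=h_inf)
        self.ca = CalciumPool(influx_scale=p.ca_influx_scale, tau_decay=p.ca_tau)

    def _init_gate(self, cid: ChannelId, V: float) -> GatingState:
        m_inf, _, h_inf, _ = eval_kinetics(cid, V)
        return GatingState(m=m_inf, h=h_inf)

    def ih_current(self) -> float:
        p = self.p
        s = self.ih_state
        return p.g_h * (s.O + p.ih.g_inc * s.OL) * (self.V - ch.E_H)

    def intrinsic_current(self) -> float:
        I = sum(
            channel_current(spec, self.g[cid], self.V)
            for cid, spec in self.specs.items()
        )
        if self.p.g_h:
            I += self.ih_current()
        return I

    def step(self, dt: float, I_inj: float = 0.0, I_syn: float = 0.0) -> None:
        """I_inj, I_syn in nA (I_inj positive = depolarizing)."""
        p = self.p
        V = self.V
        i_inj = I_inj * 1e-3 / p.area
        i_syn = I_syn * 1e-3 / p.area
        dV = (-p.g_L * (V - p.E_L) - self.intrinsic_current() - i_syn + i_inj) / p.C_m
        V_new = V + dt * dV

        I_ca = channel_current(self.specs[self.t_id], self.g[self.t_id], V)
        self.ca = step_calcium(self.ca, I_ca, dt)
        for cid in self.g:
            kin = eval_kinetics(cid, V)
            self.g[cid] = step_gating(self.g[cid], kin, dt)
        if p.g_h:
            self.ih_state = step_ih(self.ih_state, V, self.ca.Ca_i, dt, p.ih)
        self.V = V_new


# ---------------------------------------------------------------------------
# trace utilities
# ---------------------------------------------------------------------------

def spike_detect(
    V_trace: np.ndarray,
    dt: float,
    threshold: float = 0.0,
    refractory: float = 1.0,
) -> np.ndarray:
    """Times (ms) of upward threshold crossings in a uniformly sampled
    voltage trace, de-duplicated with a refractory interval."""
    v = np.asarray(V_trace, dtype=float)
    if v.ndim != 1:
        raise ValueError("V_trace must be 1-D")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = up * dt
    if len(times) == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.asarray(keep)


def current_clamp(
    cell,
    dt: float,
    segments: list[tuple[float, float]],
    record: str = "soma",
) -> tuple[np.ndarray, np.ndarray]:
    """Run a step-current protocol (list of (duration_ms, amplitude_nA))
    and return (t, V).  For cortical cells the current is injected into the
    soma ('soma') or dendrite ('dend'); thalamic cells have one compartment.
    """
    ts, vs = [], []
    t = 0.0
    for dur, amp in segments:
        n = int(round(dur / dt))
        for _ in range(n):
            if isinstance(cell, CorticalCell):
                if record == "dend":
                    cell.step(dt, I_inj_dend=amp)
                    v = cell.V_D
                else:
                    cell.step(dt, I_inj_soma=amp)
                    v = cell.V_S
            else:
                cell.step(dt, I_inj=amp)
                v = cell.V
            t += dt
            ts.append(t)
            vs.append(v)
    return np.asarray(ts), np.asarray(vs)
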