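"""Fixed-step network integration, configuration and recording.

The engine assembles the four-layer network into flat state arrays,
advances them chunk-by-chunk (1 ms of model time per chunk) through the
numba kernel, and runs the online machinery between chunks: the SO
detector, the stimulation protocol controller, the Point-4 population-rate
tracker and the miniature-EPSP drive gate.

Determinism: a single seeded generator drives all randomness (mini-release
times), consumed in a fixed order, so identical (config, seed) pairs give
bit-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import _kernel as K
from . import channels as ch
from .cells import AREA_SOMA, AREA_THAL, CM_CORTEX, R_AXIAL_MOHM, CorticalParams
from .channels import ChannelId, eval_kinetics
from .network import Layer, MiniDrive, NetworkModel, build_network
from .stimulation import (
    CueController,
    EventLog,
    Point4Tracker,
    Protocol,
    ProtocolConfig,
    SensoryNeuron,
    SNSchedule,
    SODetector,
    StimPoint,
)

__all__ = [
    "Preset",
    "SimConfig",
    "Recording",
    "SimulationDiverged",
    "NetworkState",
    "run_simulation",
    "integrate_step",
]

class Preset(str, Enum):
    FAST_SPINDLE = "fast_spindle"   # PY->TC 0.003 uS, PY->RE 0.0015 uS
    SLOW_SPINDLE = "slow_spindle"   # PY->RE 0.0021 uS, PY->TC 0.001 uS


PRESET_CONDUCTANCES = {
    Preset.FAST_SPINDLE: dict(g_py_tc=0.003, g_py_re=0.0015),
    Preset.SLOW_SPINDLE: dict(g_py_tc=0.001, g_py_re=0.0021),
}


class SimulationDiverged(RuntimeError):
    pass


#: Control-regime calibration of quantities the connection table leaves
#: open (effective per-projection scaling of the aggregate conductance,
#: mini-drive strength, calcium influx, thalamic leak/reversal details).
#: See docs/methods.md for the rationale behind each value.
DEFAULT_OVERRIDES: dict = {
    "ca_influx_ctx": 0.03,
    "g_kl_tc": 0.02,
    "e_gabaa_th": -94.0,
    "g_t_tc": 1.3,
}

DEFAULT_G_SCALE: dict = {
    "PY->TC:AMPA": 0.5,
    "PY->RE:AMPA": 0.5,
    "TC->RE:AMPA": 1.5 / 33,
    "RE->TC:GABA_A": 1.5 / 33,
    "RE->TC:GABA_B": 0.45 / 33,
    "RE->RE:GABA_A": 1.0 / 20,
}


def _default_overrides() -> dict:
    return dict(DEFAULT_OVERRIDES)


def _default_g_scale() -> dict:
    return dict(DEFAULT_G_SCALE)


@dataclass
class SimConfig:
    dt: float = 0.025               # ms
    duration: float = 10.0          # s
    seed: int = 0
    preset: Preset = Preset.FAST_SPINDLE
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    sn: SensoryNeuron = field(default_factory=SensoryNeuron)
    mini: MiniDrive = field(default_factory=MiniDrive)
    n: int = 40                     # cells per non-PY layer (PY = 5n)
    radius_scale: str = "target"
    sample_rate: float = 1000.0     # Hz for LFP / voltage traces
    record_ctx: tuple[int, ...] = ()   # cortex indices for V_D traces
    record_th: tuple[int, ...] = ()    # thalamic indices for V traces
    overrides: dict = field(default_factory=_default_overrides)
    g_normalization: str = "per_connection"
    pypy_radius_coarse: bool = True
    g_scale: dict = field(default_factory=_default_g_scale)
    p4_frac: float = 0.5
    p4_min_peak: float = 2.0        # Hz per PY cell, smoothed
    p4_smooth_ms: float = 20.0

    def validate(self) -> None:
        if not (0.0 < self.dt <= 0.1):
            raise ValueError("dt must be in (0, 0.1] ms")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        every = (1e3 / self.sample_rate) / self.dt
        if abs(every - round(every)) > 1e-9 or round(every) < 1:
            raise ValueError("sample interval must be an integer multiple of dt")


@dataclass
class Recording:
    config: SimConfig
    t_ms: np.ndarray                 # sample grid (LFP / traces)
    lfp: np.ndarray                  # summed PY postsynaptic currents (a.u.)
    spikes: pd.DataFrame             # columns t_ms, layer, idx
    events: EventLog
    detections: list                 # SODetection list
    vtraces: dict[str, np.ndarray]

    @property
    def duration_s(self) -> float:
        return self.config.duration

    def spike_times(self, layer: str) -> np.ndarray:
        df = self.spikes
        return df.loc[df["layer"] == layer, "t_ms"].to_numpy()


# ---------------------------------------------------------------------------
# gate tables
# ---------------------------------------------------------------------------

_TABLE_GATES = [
    (K.G_PYNA_M, ChannelId.PY_NA_SOMA, "m"),
    (K.G_PYNA_H, ChannelId.PY_NA_SOMA, "h"),
    (K.G_PYK_N, ChannelId.PY_K, "h"),
    (K.G_PYKM_M, ChannelId.PY_KM, "m"),
    (K.G_HVA_M, ChannelId.PY_HVA, "m"),
    (K.G_HVA_H, ChannelId.PY_HVA, "h"),
    (K.G_NAP_M, ChannelId.PY_NAP, "m"),
    (K.G_TCNA_M, ChannelId.TC_NA, "m"),
    (K.G_TCNA_H, ChannelId.TC_NA, "h"),
    (K.G_TCK_N, ChannelId.TC_K, "h"),
    (K.G_TCT_M, ChannelId.TC_T, "m"),
    (K.G_TCT_H, ChannelId.TC_T, "h"),
    (K.G_RET_M, ChannelId.RE_T, "m"),
    (K.G_RET_H, ChannelId.RE_T, "h"),
]

V_GRID_LO, V_GRID_HI, V_GRID_STEP = -130.0, 60.0, 0.05


def build_tables(dt: float):
    """Dense (m_inf, exp(-dt/tau)) tables on the voltage grid."""
    V = np.arange(V_GRID_LO, V_GRID_HI + V_GRID_STEP / 2, V_GRID_STEP)
    nv = len(V)
    minf = np.zeros((K.N_GATES, nv))
    aexp = np.zeros((K.N_GATES, nv))
    for row, cid, slot in _TABLE_GATES:
        for i, v in enumerate(V):
            m_inf, tau_m, h_inf, tau_h = eval_kinetics(cid, v)
            x_inf, tau = (m_inf, tau_m) if slot == "m" else (h_inf, tau_h)
            minf[row, i] = x_inf
            aexp[row, i] = 0.0 if math.isinf(tau) else math.exp(-dt / tau)
    tch_inf = np.zeros(nv)
    tch_tau = np.zeros(nv)
    for i, v in enumerate(V):
        hinf, taus, _, _ = eval_kinetics(ChannelId.TC_H, v)
        tch_inf[i] = hinf
        tch_tau[i] = taus
    return V, minf, aexp, tch_inf, tch_tau


# ---------------------------------------------------------------------------
# scalar parameter block
# ---------------------------------------------------------------------------

def build_scalars(cfg: SimConfig) -> np.ndarray:
    dt = cfg.dt
    sc = np.zeros(K.N_SCALARS)
    sc[K.S_DT] = dt
    sc[K.S_ENA], sc[K.S_EK], sc[K.S_EH], sc[K.S_ECA] = (
        ch.E_NA, ch.E_K, ch.E_H, ch.E_CA,
    )
    sc[K.S_GL_CTX], sc[K.S_EL_CTX] = 0.033, -68.0
    sc[K.S_GKL_CTX] = 0.0033
    sc[K.S_GNA_D], sc[K.S_GHVA], sc[K.S_GKCA] = 1.3, 0.01, 0.4
    sc[K.S_GNA_S], sc[K.S_GK_S] = 2000.0, 200.0
    sc[K.S_GDS] = 1e-3 / R_AXIAL_MOHM / AREA_SOMA
    sc[K.S_CM_CTX] = CM_CORTEX
    sc[K.S_CA_REST], sc[K.S_CA_TAU_CTX] = 2.4e-4, 165.0
    sc[K.S_QT] = ch.QT
    sc[K.S_GNA_TC], sc[K.S_GK_TC], sc[K.S_GT_TC] = 90.0, 10.0, 1.1
    sc[K.S_GH_TC], sc[K.S_GKL_TC] = 0.011, 0.03
    sc[K.S_GL_TC], sc[K.S_EL_TC] = 0.028, -70.0
    sc[K.S_GNA_RE], sc[K.S_GK_RE], sc[K.S_GT_RE] = 100.0, 10.0, 2.0
    sc[K.S_GKL_RE], sc[K.S_GL_RE], sc[K.S_EL_RE] = 0.03, 0.08, -77.0
    sc[K.S_CM_TH] = 1.0
    sc[K.S_CA_TAU_TH], sc[K.S_CA_INFLUX_TH] = 5.0, 5.18e-5
    p = ch.IhParams()
    sc[K.S_IH_K1], sc[K.S_IH_K2], sc[K.S_IH_K3], sc[K.S_IH_K4] = (
        p.k1, p.k2, p.k3, p.k4,
    )
    sc[K.S_IH_GINC] = p.g_inc
    sc[K.S_SYNFAC_TH] = 1e-3 / AREA_THAL
    sc[K.S_TMAX] = 0.3
    A = 0.5
    for pre, alpha, beta in (
        ("AMPA", 1.1, 0.19), ("NMDA", 1.0, 0.0067), ("GABA", 10.5, 0.166),
    ):
        lam = alpha * A + beta
        sc[getattr(K, f"S_{pre}_AOFF")] = math.exp(-beta * dt)
        sc[getattr(K, f"S_{pre}_AON")] = math.exp(-lam * dt)
        sc[getattr(K, f"S_{pre}_OINF")] = alpha * A / lam
        sc[getattr(K, f"S_{pre}_ALPHA_A")] = alpha * A
        sc[getattr(K, f"S_{pre}_BETA")] = beta
    K1 = cfg.overrides.get("gabab_k1", 0.52)
    K2, K3, K4, Kd = 0.0013, 0.098, 0.033, 100.0
    lam = K1 * A + K2
    sc[K.S_GB_AOFF] = math.exp(-K2 * dt)
    sc[K.S_GB_AON] = math.exp(-lam * dt)
    sc[K.S_GB_RINF] = K1 * A / lam
    sc[K.S_GB_K1A], sc[K.S_GB_K2] = K1 * A, K2
    eK4 = math.exp(-K4 * dt)
    sc[K.S_GB_EK4] = eK4
    sc[K.S_GB_CK3] = K3 / K4 * (1.0 - eK4)
    sc[K.S_GB_KD] = Kd
    sc[K.S_NMDA_SIG], sc[K.S_NMDA_VTH] = 12.5, -25.0
    sc[K.S_GSN] = 0.0    # enabled only when a protocol delivers cues
    sc[K.S_DEP_TAU] = 700.0
    sc[K.S_EGABAA] = -70.0
    sc[K.S_EGABAA_TH] = -70.0

    names = scalar_names()
    special = {"ca_influx_ctx", "gabab_k1"}
    for name, value in cfg.overrides.items():
        if name in special:
            continue
        if name not in names:
            raise KeyError(f"unknown parameter override {name!r}")
        sc[names[name]] = value
    return sc


def scalar_names() -> dict[str, int]:
    """Override-able scalar parameters by name."""
    return {
        "g_l_ctx": K.S_GL_CTX, "e_l_ctx": K.S_EL_CTX, "g_kl_ctx": K.S_GKL_CTX,
        "g_na_dend": K.S_GNA_D, "g_hva": K.S_GHVA, "g_kca": K.S_GKCA,
        "g_na_soma": K.S_GNA_S, "g_k_soma": K.S_GK_S, "g_ds": K.S_GDS,
        "cm_ctx": K.S_CM_CTX, "ca_tau_ctx": K.S_CA_TAU_CTX,
        "g_na_tc": K.S_GNA_TC, "g_k_tc": K.S_GK_TC, "g_t_tc": K.S_GT_TC,
        "g_h_tc": K.S_GH_TC, "g_kl_tc": K.S_GKL_TC, "g_l_tc": K.S_GL_TC,
        "e_l_tc": K.S_EL_TC, "g_na_re": K.S_GNA_RE, "g_t_re": K.S_GT_RE,
        "g_kl_re": K.S_GKL_RE, "g_l_re": K.S_GL_RE, "e_l_re": K.S_EL_RE,
        "ca_influx_th": K.S_CA_INFLUX_TH, "ih_k1": K.S_IH_K1,
        "ih_k2": K.S_IH_K2, "ih_k3": K.S_IH_K3, "ih_k4": K.S_IH_K4,
        "ih_ginc": K.S_IH_GINC, "t_max": K.S_TMAX, "g_sn": K.S_GSN,
        "dep_tau": K.S_DEP_TAU, "e_gabaa": K.S_EGABAA,
        "e_gabaa_th": K.S_EGABAA_TH,
        "ca_rest": K.S_CA_REST, "e_ca": K.S_ECA,
    }


# ---------------------------------------------------------------------------
# network state
# ---------------------------------------------------------------------------

class NetworkState:
    """Flat-array state of the full network plus kernel plumbing."""

    def __init__(self, cfg: SimConfig, net: NetworkModel | None = None):
        cfg.validate()
        self.cfg = cfg
        pre = PRESET_CONDUCTANCES[cfg.preset]
        self.net = net or build_network(
            cfg.n, radius_scale=cfg.radius_scale, mini=cfg.mini,
            g_normalization=cfg.g_normalization,
            pypy_radius_coarse=cfg.pypy_radius_coarse,
            g_scale=cfg.g_scale, **pre
        )
        self.npy = self.net.layer_size(Layer.PY)
        self.nin = self.net.layer_size(Layer.IN)
        self.ntc = self.net.layer_size(Layer.TC)
        self.nre = self.net.layer_size(Layer.RE)
        n_ctx = self.npy + self.nin
        n_th = self.ntc + self.nre

        self.sc = build_scalars(cfg)
        grid, self.minf, self.aexp, self.tch_inf, self.tch_tau = build_tables(cfg.dt)
        self.v0 = grid[0]
        self.inv_dv = 1.0 / V_GRID_STEP

        # per-cell cortical parameters
        py_p = CorticalParams()
        in_p = CorticalParams.interneuron()
        ca_influx = cfg.overrides.get("ca_influx_ctx", py_p.ca_influx_scale)
        self.ctx_param = np.zeros((n_ctx, 8))
        for c in range(n_ctx):
            p = py_p if c < self.npy else in_p
            self.ctx_param[c] = (
                p.g_nap_dend, p.g_km, p.g_sd, 1e-3 / p.area_dend,
                ca_influx, p.g_nap_soma, 1.0 if c < self.npy else 0.0,
                self.net.mini.g_mini * (1.0 if c < self.npy else
                                        in_p.rho / py_p.rho),
            )
        self.ctx_kin = np.zeros((n_ctx, 6))
        for c in range(n_ctx):
            if c < self.npy:
                self.ctx_kin[c] = (
                    self.sc[K.S_AMPA_AOFF], self.sc[K.S_AMPA_AON],
                    self.sc[K.S_AMPA_OINF], 0.07,
                    self.sc[K.S_AMPA_ALPHA_A], self.sc[K.S_AMPA_BETA],
                )
            else:
                self.ctx_kin[c] = (
                    self.sc[K.S_GABA_AOFF], self.sc[K.S_GABA_AON],
                    self.sc[K.S_GABA_OINF], 0.073,
                    self.sc[K.S_GABA_ALPHA_A], self.sc[K.S_GABA_BETA],
                )

        # initial states at rest
        self.ctx_state = np.zeros((n_ctx, 12))
        V0 = -68.0
        self.ctx_state[:, 0] = V0
        self.ctx_state[:, 1] = V0
        for col, cid, slot in (
            (2, ChannelId.PY_NA_DEND, "m"), (3, ChannelId.PY_NA_DEND, "h"),
            (4, ChannelId.PY_KM, "m"), (6, ChannelId.PY_HVA, "m"),
            (7, ChannelId.PY_HVA, "h"), (9, ChannelId.PY_NA_SOMA, "m"),
            (10, ChannelId.PY_NA_SOMA, "h"), (11, ChannelId.PY_K, "h"),
        ):
            kin = eval_kinetics(cid, V0)
            self.ctx_state[:, col] = kin[0] if slot == "m" else kin[2]
        self.ctx_state[:, 5] = 0.0
        self.ctx_state[:, 8] = self.sc[K.S_CA_REST]

        self.th_state = np.zeros((n_th, 10))
        for c in range(n_th):
            is_tc = c < self.ntc
            Vt = -70.0 if is_tc else -81.0
            self.th_state[c, 0] = Vt
            na = ChannelId.TC_NA
            tt = ChannelId.TC_T if is_tc else ChannelId.RE_T
            kin = eval_kinetics(na, Vt)
            self.th_state[c, 1], self.th_state[c, 2] = kin[0], kin[2]
            self.th_state[c, 3] = eval_kinetics(ChannelId.TC_K, Vt)[2]
            kin = eval_kinetics(tt, Vt)
            self.th_state[c, 4], self.th_state[c, 5] = kin[0], kin[2]
            if is_tc:
                self.th_state[c, 6] = eval_kinetics(ChannelId.TC_H, Vt)[0]
            self.th_state[c, 9] = self.sc[K.S_CA_REST]

        self.ctx_syn = np.zeros((n_ctx, 7))
        self.ctx_syn[:, 2] = 1.0                 # D
        self.ctx_syn[:, 3] = -np.inf             # pulse_end
        self.ctx_syn[:, 4] = -1e9                # last spike
        self.ctx_syn[:, 6] = -np.inf
        self.th_syn = np.zeros((n_th, 4))
        self.th_syn[:, 3] = -np.inf
        self.sn_state = np.array([0.0, -np.inf])

        # wiring arrays
        def w(src, tgt, rec):
            wd = self.net.wiring[(src, tgt, rec)]
            return (wd.lo.astype(np.int64), wd.hi.astype(np.int64),
                    wd.g_per_conn.astype(np.float64))

        from .synapses import Receptor as R
        self.pypy_lo, self.pypy_hi, self.gw_pypy_a = w(Layer.PY, Layer.PY, R.AMPA)
        _, _, self.gw_pypy_n = w(Layer.PY, Layer.PY, R.NMDA)
        self.inpy_lo, self.inpy_hi, self.gw_inpy = w(Layer.IN, Layer.PY, R.GABA_A)
        self.tcpy_lo, self.tcpy_hi, self.gw_tcpy = w(Layer.TC, Layer.PY, R.AMPA)
        self.pyin_lo, self.pyin_hi, self.gw_pyin_a = w(Layer.PY, Layer.IN, R.AMPA)
        _, _, self.gw_pyin_n = w(Layer.PY, Layer.IN, R.NMDA)
        self.tcin_lo, self.tcin_hi, self.gw_tcin = w(Layer.TC, Layer.IN, R.AMPA)
        self.pytc_lo, self.pytc_hi, self.gw_pytc = w(Layer.PY, Layer.TC, R.AMPA)
        self.retc_lo, self.retc_hi, self.gw_retc_a = w(Layer.RE, Layer.TC, R.GABA_A)
        _, _, self.gw_retc_b = w(Layer.RE, Layer.TC, R.GABA_B)
        self.tcre_lo, self.tcre_hi, self.gw_tcre = w(Layer.TC, Layer.RE, R.AMPA)
        self.pyre_lo, self.pyre_hi, self.gw_pyre = w(Layer.PY, Layer.RE, R.AMPA)
        self.rere_lo, self.rere_hi, self.gw_rere = w(Layer.RE, Layer.RE, R.GABA_A)

        self.pf_py_ad = np.zeros(self.npy + 1)
        self.pf_py_a = np.zeros(self.npy + 1)
        self.pf_py_n = np.zeros(self.npy + 1)
        self.pf_in = np.zeros(self.nin + 1)
        self.pf_tc = np.zeros(self.ntc + 1)
        self.pf_re = np.zeros(self.nre + 1)
        self.pf_regb = np.zeros(self.nre + 1)

        self._spike_cap = 65536
        self._spk_t = np.zeros(self._spike_cap)
        self._spk_layer = np.zeros(self._spike_cap, dtype=np.int64)
        self._spk_idx = np.zeros(self._spike_cap, dtype=np.int64)

        self.t = 0.0
        self.step_count = 0

    def advance(self, nsteps: int, mini_cells, mini_steps, sn_steps,
                lfp_out, rec0, rec_every, vrec_ctx, vrec_th, vrec_out):
        n_spk = K.run_chunk(
            nsteps, self.t, self.step_count,
            self.npy, self.nin, self.ntc, self.nre,
            self.sc,
            self.ctx_state, self.ctx_param, self.ctx_syn, self.ctx_kin,
            self.th_state, self.th_syn,
            self.minf, self.aexp, self.tch_inf, self.tch_tau,
            self.v0, self.inv_dv,
            self.pypy_lo, self.pypy_hi, self.gw_pypy_a, self.gw_pypy_n,
            self.inpy_lo, self.inpy_hi, self.gw_inpy,
            self.tcpy_lo, self.tcpy_hi, self.gw_tcpy,
            self.pyin_lo, self.pyin_hi, self.gw_pyin_a, self.gw_pyin_n,
            self.tcin_lo, self.tcin_hi, self.gw_tcin,
            self.pytc_lo, self.pytc_hi, self.gw_pytc,
            self.retc_lo, self.retc_hi, self.gw_retc_a, self.gw_retc_b,
            self.tcre_lo, self.tcre_hi, self.gw_tcre,
            self.pyre_lo, self.pyre_hi, self.gw_pyre,
            self.rere_lo, self.rere_hi, self.gw_rere,
            self.pf_py_ad, self.pf_py_a, self.pf_py_n, self.pf_in,
            self.pf_tc, self.pf_re, self.pf_regb,
            mini_cells, mini_steps, sn_steps, self.sn_state,
            self._spk_t, self._spk_layer, self._spk_idx,
            rec_every, lfp_out, rec0, vrec_ctx, vrec_th, vrec_out,
        )
        self.t += nsteps * self.cfg.dt
        self.step_count += nsteps
        return (self._spk_t[:n_spk].copy(), self._spk_layer[:n_spk].copy(),
                self._spk_idx[:n_spk].copy())

    def check_finite(self) -> None:
        for name, arr, vcol in (("cortex", self.ctx_state, 0),
                                ("thalamus", self.th_state, 0)):
            v = arr[:, vcol]
            bad = ~np.isfinite(v) | (np.abs(v) > 200.0)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise SimulationDiverged(
                    f"voltage divergence in {name} cell {i} at t={self.t:.2f} ms"
                )


def integrate_step(state: NetworkState, nsteps: int = 1):
    """Advance the network by ``nsteps`` raw dt-steps with no events
    scheduled (plumbing for tests and for external drivers)."""
    empty_i = np.zeros(0, dtype=np.int64)
    lfp = np.zeros(max(1, nsteps))
    vr = np.zeros((0, max(1, nsteps)))
    return state.advance(nsteps, empty_i, empty_i, empty_i, lfp, 0,
                         10 ** 9, empty_i, empty_i, vr)


# ---------------------------------------------------------------------------
# full simulation with protocol machinery
# ---------------------------------------------------------------------------

def run_simulation(config: SimConfig) -> Recording:
    config.validate()
    state = NetworkState(config)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    dt = cfg.dt
    chunk_ms = 1.0
    steps_per_chunk = int(round(chunk_ms / dt))
    rec_every = int(round((1e3 / cfg.sample_rate) / dt))
    n_chunks = int(round(cfg.duration * 1e3 / chunk_ms))
    n_samples = (n_chunks * steps_per_chunk) // rec_every

    lfp_out = np.zeros(n_samples)
    vrec_ctx = np.asarray(cfg.record_ctx, dtype=np.int64)
    vrec_th = np.asarray(cfg.record_th, dtype=np.int64)
    vrec_out = np.zeros((len(vrec_ctx) + len(vrec_th), max(1, n_samples)))

    detector = SODetector()
    controller = CueController(cfg.protocol)
    p4 = Point4Tracker(frac=cfg.p4_frac, min_peak=cfg.p4_min_peak)
    sched = SNSchedule(cfg.sn)
    log = EventLog()
    detections = []

    stim_on = cfg.protocol.protocol is not Protocol.CONTROL
    if stim_on:
        state.sc[K.S_GSN] = cfg.overrides.get("g_sn", cfg.sn.g_sn_tc)

    mini = state.net.mini
    n_mini_targets = state.npy + state.nin
    rate = mini.rate
    gate_open = mini.enabled and rate > 0
    next_mini = np.full(n_mini_targets, np.inf)
    if gate_open:
        next_mini = rng.exponential(1e3 / rate, n_mini_targets)
    last_py_spike = -np.inf
    so_active = False          # between detection and termination
    gate_reopen_t = -np.inf
    pause_logged_until = -np.inf

    # population-rate smoothing for Point 4
    alpha_s = 1.0 - math.exp(-chunk_ms / cfg.p4_smooth_ms)
    rate_smooth = 0.0
    pending_p4 = None

    spk_t_all, spk_l_all, spk_i_all = [], [], []
    empty = np.zeros(0, dtype=np.int64)

    for ci in range(n_chunks):
        t0 = ci * chunk_ms
        t1 = t0 + chunk_ms

        # scheduled minis in this chunk
        if gate_open:
            cells = []
            steps = []
            due = np.flatnonzero(next_mini < t1)
            for c in due:
                tn = next_mini[c]
                while tn < t1:
                    if tn >= t0:
                        cells.append(c)
                        steps.append(min(int((tn - t0) / dt), steps_per_chunk - 1))
                    tn += rng.exponential(1e3 / rate)
                next_mini[c] = tn
            if cells:
                order = np.argsort(np.asarray(steps), kind="stable")
                mini_cells = np.asarray(cells, dtype=np.int64)[order]
                mini_steps = np.asarray(steps, dtype=np.int64)[order]
            else:
                mini_cells = mini_steps = empty
        else:
            mini_cells = mini_steps = empty
            if t0 >= gate_reopen_t and gate_reopen_t > -np.inf:
                gate_open = mini.enabled and rate > 0
                if gate_open:
                    next_mini = t1 + rng.exponential(1e3 / rate, n_mini_targets)
                gate_reopen_t = -np.inf

        sn_times = sched.spikes_between(t0, t1)
        sn_steps = (
            np.clip(((sn_times - t0) / dt).astype(np.int64), 0,
                    steps_per_chunk - 1)
            if len(sn_times) else empty
        )

        spk_t, spk_l, spk_i = state.advance(
            steps_per_chunk, mini_cells, mini_steps, sn_steps,
            lfp_out, ci, rec_every, vrec_ctx, vrec_th, vrec_out,
        )
        if ci % 200 == 199:
            state.check_finite()
        if len(spk_t):
            spk_t_all.append(spk_t)
            spk_l_all.append(spk_l)
            spk_i_all.append(spk_i)

        py_spikes = spk_t[spk_l == 0]
        if len(py_spikes):
            last_py_spike = py_spikes[-1]

        # SO termination -> re-arm the mini drive
        if so_active and t1 - last_py_spike >= mini.termination_silence_ms:
            so_active = False
            log.add(t1, "SO_END")
            gate_reopen_t = t1 + mini.rearm_delay_ms
            gate_open = False

        # population rate (Hz per PY cell), smoothed
        inst = len(py_spikes) / state.npy * 1e3
        rate_smooth += alpha_s * (inst - rate_smooth)
        if pending_p4 is not None:
            t_cue = p4.update(t1, rate_smooth)
            if t_cue is not None:
                sched.add_cue(t_cue)
                log.add(t_cue, "CUE", cfg.protocol.protocol.value, 4,
                        pending_p4.so_detection_t)
                pending_p4 = None

        # detector + protocol
        for det in detector.update(py_spikes, t1):
            detections.append(det)
            log.add(det.t, "SO_DETECT", cfg.protocol.protocol.value,
                    int(cfg.protocol.point), det.down_duration_ms)
            log.add(det.t, "SO_START")
            so_active = True
            gate_open = False
            if pending_p4 is not None:
                pending_p4 = None   # Up-state ended without a P4 crossing
            ev = controller.on_detection(det.t, det.down_duration_ms)
            if controller.pauses and controller.pauses[-1][1] > pause_logged_until:
                ps, pe = controller.pauses[-1]
                log.add(ps, "PAUSE_START", cfg.protocol.protocol.value,
                        int(cfg.protocol.point))
                log.add(pe, "PAUSE_END", cfg.protocol.protocol.value,
                        int(cfg.protocol.point))
                pause_logged_until = pe
            if ev is not None and stim_on:
                if cfg.protocol.point is StimPoint.P4:
                    pending_p4 = ev
                    p4.arm()
                    rate_smooth = 0.0
                else:
                    sched.add_cue(ev.t_cue)
                    log.add(ev.t_cue, "CUE", cfg.protocol.protocol.value,
                            int(cfg.protocol.point), det.t)

    state.check_finite()

    if spk_t_all:
        spikes = pd.DataFrame({
            "t_ms": np.concatenate(spk_t_all),
            "layer": pd.Categorical.from_codes(
                np.concatenate(spk_l_all), categories=["PY", "IN", "TC", "RE"]
            ),
            "idx": np.concatenate(spk_i_all),
        })
    else:
        spikes = pd.DataFrame({
            "t_ms": np.zeros(0), "layer": pd.Categorical([], categories=[
                "PY", "IN", "TC", "RE"]), "idx": np.zeros(0, dtype=int),
        })

    t_ms = (np.arange(n_samples) + 1) * (rec_every * dt)
    vtraces = {}
    for q, c in enumerate(vrec_ctx):
        vtraces[f"ctx{c}"] = vrec_out[q, :n_samples]
    for q, c in enumerate(vrec_th):
        vtraces[f"th{c}"] = vrec_out[len(vrec_ctx) + q, :n_samples]

    return Recording(
        config=cfg, t_ms=t_ms, lfp=lfp_out, spikes=spikes,
        events=log, detections=detections, vtraces=vtraces,
    )
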