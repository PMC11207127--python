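"""Intrinsic-current kinetics: landmark values, singularity guards,
reversal-potential zeros and integrator oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tcsleep.channels import (
    CHANNELS,
    CalciumPool,
    ChannelId,
    ChannelSpec,
    GatingState,
    IhParams,
    IhState,
    QT,
    channel_current,
    eval_kinetics,
    step_calcium,
    step_gating,
    step_ih,
)
from tcsleep import channels as chmod


# ---------------------------------------------------------------------------
# steady states and rates at landmark voltages
# ---------------------------------------------------------------------------

def test_py_k_rate_limit_at_pole():
    # alpha = 0.02*(V-25)/(1-exp(-(V-25)/9)) has its removable singularity
    # at V = 25 with limit 0.02*9 = 0.18; beta's limit is 0.002*9 = 0.018
    a, b = 0.18, 0.018
    m_inf, tau_m, n_inf, tau_n = eval_kinetics(ChannelId.PY_K, 25.0)
    assert n_inf == pytest.approx(a / (a + b), rel=1e-9)
    assert tau_n == pytest.approx((1.0 / (a + b)) / QT, rel=1e-9)


@pytest.mark.parametrize("cid, V, expected", [
    (ChannelId.RE_T, -52.0, 0.5),     # sigmoid midpoint of m_inf
    (ChannelId.TC_H, -75.0, 0.5),     # midpoint of the open-fraction sigmoid
])
def test_sigmoid_midpoints(cid, V, expected):
    m_inf = eval_kinetics(cid, V)[0]
    assert m_inf == pytest.approx(expected, abs=1e-12)


def test_kca_steady_state_at_calcium_level():
    # alpha = 0.01*[Ca], beta = 0.02 -> m_inf = 0.0002/0.0202 at 0.02 mM
    m_inf = eval_kinetics(ChannelId.PY_KCA, -60.0, Ca_i=0.02)[0]
    assert m_inf == pytest.approx(0.0002 / 0.0202, rel=1e-9)


@pytest.mark.parametrize("cid, pole", [
    (ChannelId.PY_NA_SOMA, -25.0),
    (ChannelId.PY_NA_SOMA, -40.0),
    (ChannelId.PY_NA_SOMA, 85.0),
    (ChannelId.PY_K, 25.0),
    (ChannelId.PY_KM, -30.0),
    (ChannelId.PY_HVA, -27.0),
    (ChannelId.TC_NA, -37.0),
    (ChannelId.TC_NA, -10.0),
    (ChannelId.TC_K, -35.0),
])
def test_continuity_across_singularity_guards(cid, pole):
    """Every guarded rate is continuous through its pole."""
    eps = 1e-6
    lo = np.array(eval_kinetics(cid, pole - eps))
    hi = np.array(eval_kinetics(cid, pole + eps))
    at = np.array(eval_kinetics(cid, pole))
    finite = np.isfinite(at)
    assert np.allclose(lo[finite], at[finite], rtol=1e-5, atol=1e-6)
    assert np.allclose(hi[finite], at[finite], rtol=1e-5, atol=1e-6)


def test_steady_states_bounded_and_taus_positive():
    V = np.linspace(-120, 60, 181)
    for cid in ChannelId:
        for v in V:
            m_inf, tau_m, h_inf, tau_h = eval_kinetics(cid, v, Ca_i=1e-4)
            assert 0.0 <= m_inf <= 1.0
            assert 0.0 <= h_inf <= 1.0
            assert tau_m > 0 and tau_h > 0


def test_unknown_channel_rejected():
    with pytest.raises((KeyError, ValueError)):
        eval_kinetics("no_such_channel", -60.0)


# ---------------------------------------------------------------------------
# channel_current
# ---------------------------------------------------------------------------

def test_zero_current_at_reversal_for_every_channel():
    for cid, spec in CHANNELS.items():
        g = GatingState(m=0.5, h=0.5)
        assert channel_current(spec, g, spec.E_rev) == pytest.approx(0.0)


def test_leak_type_current_value():
    spec = CHANNELS[ChannelId.PY_KL]        # g = 0.0033 mS/cm^2, E = -95
    I = channel_current(spec, GatingState(), -65.0)
    assert I == pytest.approx(0.0033 * 30.0, rel=1e-12)   # outward, positive


def test_closed_activation_gate_gives_zero():
    spec = CHANNELS[ChannelId.TC_T]
    assert channel_current(spec, GatingState(m=0.0, h=1.0), -20.0) == 0.0


def test_outward_sign_convention():
    # K-type current above its reversal must be positive (outward)
    spec = CHANNELS[ChannelId.PY_KCA]
    assert channel_current(spec, GatingState(m=0.3, h=1.0), -60.0) > 0


# ---------------------------------------------------------------------------
# gating updates
# ---------------------------------------------------------------------------

def test_step_gating_fixed_point_and_closed_form():
    kin = (1.0, 1.0, 0.5, 2.0)
    g = GatingState(m=1.0, h=0.5)
    g2 = step_gating(g, kin, dt=0.5)
    assert g2.m == pytest.approx(1.0) and g2.h == pytest.approx(0.5)
    # x=0, x_inf=1, tau=dt -> 1 - 1/e
    g3 = step_gating(GatingState(m=0.0, h=0.0), (1.0, 0.7, 1.0, 0.7), dt=0.7)
    assert g3.m == pytest.approx(1 - math.exp(-1), rel=1e-12)
    # dt >> tau -> x_inf
    g4 = step_gating(GatingState(m=0.2, h=0.9), (0.8, 0.1, 0.3, 0.1), dt=1e4)
    assert g4.m == pytest.approx(0.8) and g4.h == pytest.approx(0.3)


def test_step_gating_rejects_bad_inputs():
    with pytest.raises(ValueError):
        step_gating(GatingState(), (0.5, 1.0, 1.0, 1.0), dt=0.0)
    with pytest.raises(ValueError):
        step_gating(GatingState(), (0.5, -1.0, 1.0, 1.0), dt=0.1)


def test_exponential_update_matches_substepped_oracle(rng):
    """Driving a gate along a random voltage trajectory, the dt update must
    agree with the same exact update applied at dt/100."""
    cid = ChannelId.TC_NA
    dt = 0.1
    V_path = -70.0 + np.cumsum(rng.normal(0, 2.0, 200))
    g_coarse = GatingState(m=0.1, h=0.9)
    g_fine = GatingState(m=0.1, h=0.9)
    for V in V_path:
        kin = eval_kinetics(cid, float(V))
        g_coarse = step_gating(g_coarse, kin, dt)
        for _ in range(100):
            g_fine = step_gating(g_fine, kin, dt / 100)
    assert g_coarse.m == pytest.approx(g_fine.m, abs=1e-9)
    assert g_coarse.h == pytest.approx(g_fine.h, abs=1e-9)


def test_gating_stays_in_unit_interval_on_random_trajectories(rng):
    for cid in (ChannelId.PY_NA_SOMA, ChannelId.RE_T, ChannelId.PY_HVA):
        g = GatingState(m=rng.random(), h=rng.random())
        for _ in range(500):
            V = rng.uniform(-120, 60)
            g = step_gating(g, eval_kinetics(cid, V), dt=0.25)
            assert 0.0 <= g.m <= 1.0 and 0.0 <= g.h <= 1.0


# ---------------------------------------------------------------------------
# I_h calcium-regulated scheme
# ---------------------------------------------------------------------------

def test_ih_voltage_branch_equilibrates_to_sigmoid():
    s = IhState(O=0.0, P1=0.0, OL=0.0)
    for _ in range(20000):
        s = step_ih(s, -75.0, 0.0, dt=1.0)
    assert s.O == pytest.approx(0.5, abs=1e-3)
    assert s.OL == pytest.approx(0.0, abs=1e-9)


def test_ih_k3_zero_freezes_locked_fraction():
    p = IhParams(k3=0.0)
    s = IhState(O=0.4, P1=0.5, OL=0.2)
    for _ in range(100):
        s = step_ih(s, -80.0, 1e-3, dt=0.1, params=p)
    # OL only decays via k4; with k3 = 0 nothing flows in
    assert s.OL <= 0.2 + 1e-12


def test_ih_scheme_conserves_fractions_and_matches_reference(rng):
    p = IhParams()
    s = IhState(O=0.3, P1=0.1, OL=0.1)
    V, Ca = -80.0, 2e-3
    # reference: stiff ODE solve of the same mass-action system
    def rhs(t, y):
        O, P1, OL = y
        h_inf, tau_s, _, _ = eval_kinetics(ChannelId.TC_H, V)
        a, b = h_inf / tau_s, (1 - h_inf) / tau_s
        r = p.k1 * Ca ** 4
        return [a * (1 - O - OL) - b * O - p.k3 * P1 * O + p.k4 * OL,
                r * (1 - P1) - p.k2 * P1,
                p.k3 * P1 * O - p.k4 * OL]
    sol = solve_ivp(rhs, (0, 50.0), [s.O, s.P1, s.OL], rtol=1e-10, atol=1e-12)
    t = 0.0
    while t < 50.0 - 1e-9:
        s = step_ih(s, V, Ca, dt=0.025, params=p)
        t += 0.025
        assert 0 <= s.O <= 1 and 0 <= s.OL <= 1 and 0 <= s.P1 <= 1
        assert abs(s.C + s.O + s.OL - 1.0) < 1e-12
    assert s.O == pytest.approx(sol.y[0, -1], abs=2e-4)
    assert s.P1 == pytest.approx(sol.y[1, -1], abs=2e-4)
    assert s.OL == pytest.approx(sol.y[2, -1], abs=2e-4)


# ---------------------------------------------------------------------------
# calcium pool
# ---------------------------------------------------------------------------

def test_calcium_rest_is_fixed_point():
    pool = CalciumPool()
    out = step_calcium(pool, 0.0, dt=0.5)
    assert out.Ca_i == pytest.approx(pool.Ca_rest)


def test_calcium_decays_monotonically_to_rest():
    pool = CalciumPool(Ca_i=0.05)
    prev = pool.Ca_i
    for _ in range(200):
        pool = step_calcium(pool, 0.0, dt=1.0)
        assert pool.Ca_i <= prev + 1e-15
        prev = pool.Ca_i
    assert pool.Ca_i == pytest.approx(pool.Ca_rest, rel=1e-6)


def test_calcium_steady_state_under_constant_influx():
    pool = CalciumPool()
    I = -2.0       # inward Ca current
    for _ in range(200000):
        pool = step_calcium(pool, I, dt=0.05)
    expected = pool.Ca_rest + pool.influx_scale * abs(I) * pool.tau_decay
    assert pool.Ca_i == pytest.approx(expected, rel=1e-3)


def test_channel_spec_invariants():
    with pytest.raises(ValueError):
        ChannelSpec(ChannelId.LEAK, M=0, N=2, g_max=1.0, E_rev=0.0)
    with pytest.raises(ValueError):
        ChannelSpec(ChannelId.LEAK, M=0, N=0, g_max=-1.0, E_rev=0.0)
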