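import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navgate.constants import thermal_voltage_mV
from navgate.gating_model import (GatingScheme, Protocol, SolutionPair, State,
                                  Transition, ghk_current, propagate,
                                  steady_state)

from conftest import SOL_NA, three_state_scheme, two_state_scheme

VT = thermal_voltage_mV()


# ---------------------------------------------------------------------------
# SolutionPair
# ---------------------------------------------------------------------------

def test_solution_pair_rejects_negative_concentration():
    with pytest.raises(ValueError):
        SolutionPair(na_out=-1.0, k_out=0.0, na_in=12.0, k_in=0.0)


def test_solution_pair_rejects_bad_temperature():
    with pytest.raises(ValueError):
        SolutionPair(na_out=1.0, k_out=0.0, na_in=1.0, k_in=0.0,
                     temperature=0.0)


# ---------------------------------------------------------------------------
# ghk_current
# ---------------------------------------------------------------------------

def test_ghk_symmetric_bionic_zero_at_0mV():
    sol = SolutionPair(na_out=120.0, k_out=0.0, na_in=0.0, k_in=120.0)
    assert ghk_current(1.0, 1.0, 0.0, sol) == pytest.approx(0.0, abs=1e-12)


def _bisect_reversal(p_na, p_k, sol, lo=-150.0, hi=150.0):
    # independent oracle: plain bisection on the flux sum
    f_lo = ghk_current(p_na, p_k, lo, sol)
    f_hi = ghk_current(p_na, p_k, hi, sol)
    assert f_lo * f_hi < 0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f_mid = ghk_current(p_na, p_k, mid, sol)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def test_ghk_reversal_equal_permeabilities_symmetric():
    sol = SolutionPair(na_out=120.0, k_out=0.0, na_in=0.0, k_in=120.0)
    assert _bisect_reversal(1.0, 1.0, sol) == pytest.approx(0.0, abs=1e-6)


def test_ghk_reversal_ratio_4p35_is_18mV():
    # bisection oracle cross-checks the closed-form reversal relation
    sol = SolutionPair(na_out=57.5, k_out=0.0, na_in=0.0, k_in=120.0)
    v_rev = _bisect_reversal(4.35, 1.0, sol)
    assert v_rev == pytest.approx(18.0, abs=0.5)


def test_ghk_invalid_inputs():
    with pytest.raises(ValueError):
        ghk_current(1.0, 1.0, float("nan"), SOL_NA)
    with pytest.raises(ValueError):
        ghk_current(-0.5, 1.0, 10.0, SOL_NA)


def test_ghk_continuous_at_zero():
    sol = SolutionPair(na_out=57.5, k_out=2.0, na_in=12.0, k_in=120.0)
    limit = ghk_current(1.0, 0.4, 0.0, sol)
    left = ghk_current(1.0, 0.4, -1e-12, sol)
    right = ghk_current(1.0, 0.4, 1e-12, sol)
    # scale of the individual ion fluxes (the net current nearly cancels)
    scale = abs(ghk_current(1.0, 0.0, 0.0, sol))
    assert abs(left - limit) / scale < 1e-9
    assert abs(right - limit) / scale < 1e-9


def test_ghk_nernst_limit_sodium_only():
    sol = SolutionPair(na_out=57.5, k_out=0.0, na_in=12.0, k_in=0.0)
    nernst = VT * np.log(57.5 / 12.0)
    v_rev = _bisect_reversal(1.0, 0.0, sol)
    assert v_rev == pytest.approx(nernst, abs=0.1)


@settings(max_examples=50, deadline=None)
@given(v=st.floats(min_value=-200, max_value=200),
       p_k=st.floats(min_value=0.0, max_value=10.0))
def test_ghk_finite_everywhere(v, p_k):
    sol = SolutionPair(na_out=57.5, k_out=1.0, na_in=12.0, k_in=120.0)
    assert np.isfinite(ghk_current(1.0, p_k, v, sol))


# ---------------------------------------------------------------------------
# scheme validation
# ---------------------------------------------------------------------------

def test_scheme_requires_explicit_reverse():
    states = [State("A"), State("B")]
    with pytest.raises(ValueError, match="reverse"):
        GatingScheme("bad", states, [Transition("A", "B", 1.0)])


def test_scheme_reverse_with_zero_rate_is_allowed():
    states = [State("A"), State("B")]
    transitions = [Transition("A", "B", 1.0, 0.5, 1.0),
                   Transition("B", "A", 0.0, -0.5, -1.0)]
    GatingScheme("absorbing-by-parameter", states, transitions)


def test_scheme_rejects_disconnected_graph():
    states = [State("A"), State("B"), State("C"), State("D")]
    transitions = [Transition("A", "B", 1.0), Transition("B", "A", 1.0),
                   Transition("C", "D", 1.0), Transition("D", "C", 1.0)]
    with pytest.raises(ValueError, match="not connected"):
        GatingScheme("split", states, transitions)


def test_scheme_rejects_inconsistent_gating_charge():
    states = [State("A"), State("B")]
    transitions = [Transition("A", "B", 1.0, 0.0, 1.0),
                   Transition("B", "A", 1.0, 0.0, 1.0)]
    with pytest.raises(ValueError, match="q_gating"):
        GatingScheme("bad-q", states, transitions)


def test_scheme_json_round_trip(tmp_path):
    scheme = three_state_scheme()
    path = tmp_path / "scheme.json"
    scheme.to_json(path)
    loaded = GatingScheme.from_json(path)
    assert loaded.to_dict() == scheme.to_dict()


# ---------------------------------------------------------------------------
# steady_state
# ---------------------------------------------------------------------------

def test_steady_state_symmetric_two_state():
    scheme = two_state_scheme(k_co=0.7, k_oc=0.7, z_co=0.0, z_oc=0.0)
    p = steady_state(scheme, 0.0)
    assert p == pytest.approx([0.5, 0.5], abs=1e-12)


def test_steady_state_matches_long_propagation():
    scheme = three_state_scheme()
    v = -20.0
    p_inf = steady_state(scheme, v)
    a = scheme.rate_matrix(v)
    taus = 1.0 / np.abs([x for x in np.linalg.eigvals(a) if abs(x) > 1e-12])
    t_long = 50.0 * taus.max()
    proto = Protocol(v, ((v, t_long),), sample_interval_ms=t_long / 100)
    sweep = propagate(scheme, proto, SOL_NA, init=np.array([1.0, 0.0, 0.0]),
                      keep_occupancy=True)
    assert sweep.occupancy[-1] == pytest.approx(p_inf, abs=1e-6)


def test_steady_state_reducible_chain_error():
    states = [State("A"), State("B")]
    transitions = [Transition("A", "B", 1.0, 0.0, 0.0),
                   Transition("B", "A", 0.0, 0.0, 0.0)]
    scheme = GatingScheme("oneway", states, transitions)
    with pytest.raises(ValueError, match="reducible"):
        steady_state(scheme, 0.0)


def test_wt_fixture_closed_at_hyperpolarized():
    from navgate.synthetic_data import get_fixture
    scheme = get_fixture("WT").build_scheme()
    p = steady_state(scheme, -120.0)
    conducting = sum(p[i] for i, s in enumerate(scheme.states)
                     if s.p_na > 0 or s.p_k > 0)
    assert conducting < 0.01


# ---------------------------------------------------------------------------
# propagate
# ---------------------------------------------------------------------------

def test_propagate_stationary_at_equilibrium():
    scheme = three_state_scheme()
    proto = Protocol(-40.0, ((-40.0, 5.0),), 0.01)
    sweep = propagate(scheme, proto, SOL_NA, keep_occupancy=True)
    assert np.allclose(sweep.occupancy, sweep.occupancy[0], atol=1e-9)
    assert np.allclose(sweep.i_gating, 0.0, atol=1e-9)
    assert np.allclose(sweep.i_ionic, sweep.i_ionic[0], atol=1e-9)


def test_propagate_two_state_closed_form():
    scheme = two_state_scheme(k_co=1.2, k_oc=0.05, z_co=0.8, z_oc=-1.2)
    proto = Protocol(-120.0, ((0.0, 8.0),), 0.01)
    sweep = propagate(scheme, proto, SOL_NA, keep_occupancy=True)
    vt = VT
    k_co = 1.2 * np.exp(0.8 * 0.0 / vt)
    k_oc = 0.05 * np.exp(-1.2 * 0.0 / vt)
    p0 = steady_state(scheme, -120.0)[1]
    p_inf = k_co / (k_co + k_oc)
    tau = 1.0 / (k_co + k_oc)
    expected = p_inf + (p0 - p_inf) * np.exp(-sweep.t_ms / tau)
    assert np.allclose(sweep.occupancy[:, 1], expected, atol=1e-6)


def test_propagate_occupancy_conserved():
    scheme = three_state_scheme()
    proto = Protocol(-120.0, ((-120.0, 1.0), (20.0, 5.0), (-120.0, 5.0)), 0.01)
    sweep = propagate(scheme, proto, SOL_NA, keep_occupancy=True)
    sums = sweep.occupancy.sum(axis=1)
    assert np.abs(sums - 1.0).max() < 1e-9


def test_propagate_rejects_unnormalized_init():
    scheme = two_state_scheme()
    proto = Protocol(-100.0, ((-100.0, 1.0),), 0.01)
    with pytest.raises(ValueError, match="sum to 1"):
        propagate(scheme, proto, SOL_NA, init=np.array([0.7, 0.7]))


def test_propagate_rate_overflow_names_transition():
    scheme = two_state_scheme(z_co=15.0, z_oc=-15.0)
    proto = Protocol(-100.0, ((150.0, 1.0),), 0.01)
    with pytest.raises(OverflowError, match="C->O"):
        propagate(scheme, proto, SOL_NA, init=np.array([1.0, 0.0]))


def test_wt_step_current_decays_to_small_fraction():
    # transient ionic current at +60 mV decays to <= 3% of its peak
    from navgate.synthetic_data import get_fixture
    fx = get_fixture("WT")
    scheme = fx.build_scheme()
    proto = Protocol(-130.0, ((-130.0, 2.0), (60.0, 30.0)), 0.01)
    sweep = propagate(scheme, proto, SOL_NA, p_abs=fx.p_abs)
    t, i = sweep.t_ms, sweep.i_ionic
    peak = np.abs(i[(t >= 2.0) & (t <= 31.9)]).max()
    late = np.abs(i[(t >= 29.0) & (t <= 31.9)]).mean()
    assert late <= 0.03 * peak


def test_gating_charge_conservation():
    """On-charge equals returned off-charge after full recovery (0.1%)."""
    scheme = three_state_scheme()
    proto = Protocol(-120.0, ((-120.0, 2.0), (20.0, 20.0), (-120.0, 60.0)),
                     0.005)
    sweep = propagate(scheme, proto, SOL_NA)
    t, ig = sweep.t_ms, sweep.i_gating
    on_mask = (t >= 2.0) & (t < 22.0)        # boundary sample is off-epoch
    on = np.trapezoid(ig[on_mask], t[on_mask])
    off = np.trapezoid(ig[t >= 22.0], t[t >= 22.0])
    assert abs(on + off) < 1e-3 * abs(on)


# ---------------------------------------------------------------------------
# stochastic oracle
# ---------------------------------------------------------------------------

def _population_gillespie(scheme, v_mV, counts0, t_grid, rng):
    """Event-driven stochastic simulation of the whole channel population."""
    vt = VT
    trans = [(scheme.state_index(tr.from_state), scheme.state_index(tr.to_state),
              tr.rate(v_mV, vt)) for tr in scheme.transitions]
    counts = np.array(counts0, dtype=np.int64)
    t = 0.0
    out = np.empty((len(t_grid), len(counts)))
    gi = 0
    while gi < len(t_grid):
        prop = np.array([counts[i] * k for i, _, k in trans])
        total = prop.sum()
        if total == 0:
            while gi < len(t_grid):
                out[gi] = counts
                gi += 1
            break
        dt = rng.exponential(1.0 / total)
        while gi < len(t_grid) and t + dt > t_grid[gi]:
            out[gi] = counts
            gi += 1
        t += dt
        which = rng.choice(len(trans), p=prop / total)
        i, j, _ = trans[which]
        counts[i] -= 1
        counts[j] += 1
    return out


def test_propagate_matches_gillespie_three_state():
    scheme = three_state_scheme()
    n = 100_000
    v = -10.0
    rng = np.random.default_rng(42)
    t_grid = np.linspace(0.2, 4.0, 12)
    mc = _population_gillespie(scheme, v, [n, 0, 0], t_grid, rng) / n

    proto = Protocol(v, ((v, 4.2),), 0.01)
    sweep = propagate(scheme, proto, SOL_NA, init=np.array([1.0, 0.0, 0.0]),
                      keep_occupancy=True)
    for k, tg in enumerate(t_grid):
        idx = np.argmin(np.abs(sweep.t_ms - tg))
        exact = sweep.occupancy[idx]
        se = np.sqrt(np.clip(exact * (1 - exact), 1e-12, None) / n)
        assert np.all(np.abs(mc[k] - exact) <= 3 * se + 1e-9), (
            f"t={tg}: MC {mc[k]} vs exact {exact}")
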