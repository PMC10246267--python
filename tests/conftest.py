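import numpy as np
import pytest

from navgate import protocols as protocol_families
from navgate.gating_model import (GatingScheme, SolutionPair, State,
                                  Transition)
from navgate.synthetic_data import (PN_GATING, PN_IONIC, generate_recording,
                                    get_fixture)

SOL_NA = SolutionPair(na_out=57.5, k_out=0.0, na_in=12.0, k_in=0.0)
SOL_BIONIC = SolutionPair(na_out=57.5, k_out=0.0, na_in=0.0, k_in=120.0)
SOL_SYM_NA = SolutionPair(na_out=120.0, k_out=0.0, na_in=120.0, k_in=0.0)
SOL_K = SolutionPair(na_out=0.0, k_out=120.0, na_in=0.0, k_in=120.0)


@pytest.fixture(scope="session")
def sol_na():
    return SOL_NA


@pytest.fixture(scope="session")
def sol_bionic():
    return SOL_BIONIC


@pytest.fixture(scope="session")
def sol_sym_na():
    return SOL_SYM_NA


def two_state_scheme(k_co=1.0, k_oc=1.0, z_co=1.0, z_oc=-1.0, q=2.0,
                     p_na=1.0, p_k=0.0, n_channels=1e9):
    states = [State("C", 0.0, 0.0), State("O", p_na, p_k)]
    transitions = [Transition("C", "O", k_co, z_co, q),
                   Transition("O", "C", k_oc, z_oc, -q)]
    return GatingScheme("two-state", states, transitions, n_channels)


def three_state_scheme():
    """C <-> O <-> I reversible chain with mixed voltage dependence."""
    states = [State("C", 0.0, 0.0), State("O", 1.0, 0.1), State("I", 0.0, 0.0)]
    transitions = [
        Transition("C", "O", 0.8, 0.9, 1.5),
        Transition("O", "C", 0.3, -0.6, -1.5),
        Transition("O", "I", 0.5, 0.2, 0.5),
        Transition("I", "O", 0.2, -0.3, -0.5),
    ]
    return GatingScheme("three-state", states, transitions, 1e9)


# -- cached, deterministic simulated families (shared across test modules) --

_cache = {}


def _cached(key, builder):
    if key not in _cache:
        _cache[key] = builder()
    return _cache[key]


@pytest.fixture(scope="session")
def wt_iv_sym():
    return _cached("wt_iv_sym", lambda: generate_recording(
        get_fixture("WT"), protocol_families.iv_family(), SOL_SYM_NA,
        pn=PN_IONIC))


@pytest.fixture(scope="session")
def diiiaa_iv_sym():
    return _cached("diiiaa_iv_sym", lambda: generate_recording(
        get_fixture("DIIIAA"), protocol_families.iv_family(), SOL_SYM_NA,
        pn=PN_IONIC))


@pytest.fixture(scope="session")
def diiiaa_iv_bionic():
    return _cached("diiiaa_iv_bionic", lambda: generate_recording(
        get_fixture("DIIIAA"), protocol_families.iv_family(), SOL_BIONIC,
        pn=PN_IONIC))


@pytest.fixture(scope="session")
def wt_immobilization():
    return _cached("wt_immobilization", lambda: generate_recording(
        get_fixture("WT"), protocol_families.immobilization_family(), SOL_NA,
        pn=PN_GATING, ttx=True))


@pytest.fixture(scope="session")
def diiiaa_immobilization():
    return _cached("diiiaa_immobilization", lambda: generate_recording(
        get_fixture("DIIIAA"), protocol_families.immobilization_family(),
        SOL_NA, pn=PN_GATING, ttx=True))


@pytest.fixture(scope="session")
def diiiaa_tails():
    return _cached("diiiaa_tails", lambda: generate_recording(
        get_fixture("DIIIAA"), protocol_families.tail_duration_family(),
        SOL_NA, pn=PN_IONIC))


@pytest.fixture(scope="session")
def wt_tails():
    return _cached("wt_tails", lambda: generate_recording(
        get_fixture("WT"), protocol_families.tail_duration_family(), SOL_NA,
        pn=PN_IONIC))


@pytest.fixture(scope="session")
def wt_hinf():
    return _cached("wt_hinf", lambda: generate_recording(
        get_fixture("WT"), protocol_families.h_infinity_family(), SOL_NA,
        pn=PN_IONIC))


@pytest.fixture(scope="session")
def step_sweep_wt():
    """WT 30 ms step to +60 mV in 57.5/12 Na (P/-4 subtracted, no noise)."""
    def build():
        proto = protocol_families.step_protocol(
            -130.0, [(-130.0, 2.0), (60.0, 30.0), (-130.0, 8.0)])
        return generate_recording(get_fixture("WT"), proto, SOL_NA,
                                  pn=PN_IONIC)
    return _cached("step_sweep_wt", build).sweeps[0]


@pytest.fixture(scope="session")
def step_sweep_diiiaa():
    def build():
        proto = protocol_families.step_protocol(
            -130.0, [(-130.0, 2.0), (60.0, 30.0), (-130.0, 8.0)])
        return generate_recording(get_fixture("DIIIAA"), proto, SOL_NA,
                                  pn=PN_IONIC)
    return _cached("step_sweep_diiiaa", build).sweeps[0]
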