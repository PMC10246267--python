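"""Synthetic cut-open-oocyte recordings for every reference construct.

The gating scheme behind every fixture has eight states laid out as four
rows of a closed<->open pair:

    C  -- O          (DIV sensor down)
    C3 -- O3         (DIV sensor up)
    C5 -- O5         (IFM motif bound)
    CI -- OI         (S6 gate shut; OI is the "leaky" inactivated state)

Horizontal transitions aggregate DI-DIII activation into a single step and
carry ~40% of the gating charge; the DIV step carries the remaining ~60%,
which is what makes charge immobilization come out near 60% once channels
dwell below the IFM-bound row.  The IFM-binding and gate transitions carry
no charge.  Fixtures with the gate-closure rate set to zero (IQM variants)
drop the bottom row entirely so the chain stays irreducible.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import signal

from .constants import thermal_voltage_mV
from .gating_model import (GatingScheme, Protocol, SolutionPair, State, Sweep,
                           TraceSet, Transition, propagate)

STATE_ROWS = [("C", "O"), ("C3", "O3"), ("C5", "O5"), ("CI", "OI")]
OPEN_STATES = ("O", "O3", "O5")


# ---------------------------------------------------------------------------
# noise / subtraction configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Band-limited Gaussian current noise (4-pole Bessel low-pass)."""

    rms: float                    # uA
    bandwidth_kHz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("noise rms must be >= 0")

    def sample(self, n: int, dt_ms: float, stream: int = 0) -> np.ndarray:
        if self.rms == 0.0:
            return np.zeros(n)
        rng = np.random.default_rng([self.seed, stream])
        white = rng.standard_normal(n)
        fs_kHz = 1.0 / dt_ms
        nyquist = fs_kHz / 2.0
        if self.bandwidth_kHz < nyquist:
            b, a = signal.bessel(4, self.bandwidth_kHz / nyquist)
            white = signal.lfilter(b, a, white)
        std = white.std()
        if std > 0:
            white = white * (self.rms / std)
        return white


@dataclass(frozen=True)
class PNSpec:
    """P/N leak subtraction: N scaled pulses from a subtraction holding.

    ``sign=-1`` is the P/-4 protocol used for ionic recordings (default
    subtraction holding -130 mV); ``sign=+1`` with ``v_sub=+20`` matches the
    gating-current configuration.
    """

    n: int = 4
    sign: int = -1
    v_sub_mV: float = -130.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("P/N requires n >= 1")
        if self.sign not in (-1, 1):
            raise ValueError("P/N sign must be +1 or -1")


PN_IONIC = PNSpec(n=4, sign=-1, v_sub_mV=-130.0)
PN_GATING = PNSpec(n=4, sign=+1, v_sub_mV=20.0)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A named construct: kinetic parameters plus its tuning targets."""

    name: str
    params: dict
    targets: dict = field(default_factory=dict)

    @property
    def p_abs(self) -> float:
        return self.params["p_abs"]

    @property
    def cap_nF(self) -> float:
        return self.params["cap_nF"]

    @property
    def clamp_tau_ms(self) -> float:
        return self.params["clamp_tau_ms"]

    def build_scheme(self, ttx: bool = False) -> GatingScheme:
        scheme = build_scheme(self.params, name=self.name)
        if ttx:
            scheme = scheme.scaled(0.0)
        return scheme


def _shifted(k0f, zf, k0b, zb, shift_mV, vt):
    """Shift a transition pair's voltage dependence right by ``shift_mV``."""
    return (k0f * math.exp(-zf * shift_mV / vt),
            k0b * math.exp(-zb * shift_mV / vt))


def build_scheme(params: dict, name: str = "scheme") -> GatingScheme:
    vt = thermal_voltage_mV()
    act, div = params["act"], params["div"]
    ifm, gate = params["ifm"], params["gate"]
    act67 = params["act67"]
    has_gate_row = gate["kc"] > 0.0

    rows = STATE_ROWS if has_gate_row else STATE_ROWS[:3]
    coupling = params["coupling"]
    p_k_open = coupling / params["open_pnak"]
    leak_pna = params["leak_pna"] * coupling
    leak_pk = (params["leak_pna"] / params["inact_pnak"] * coupling
               if params["leak_pna"] > 0 else 0.0)

    states = []
    for closed, open_ in rows:
        states.append(State(closed, 0.0, 0.0))
        if open_ == "OI":
            states.append(State(open_, leak_pna, leak_pk))
        else:
            states.append(State(open_, coupling, p_k_open))

    transitions = []

    def add_pair(a, b, k0f, zf, k0b, zb, q):
        transitions.append(Transition(a, b, k0f, zf, q))
        transitions.append(Transition(b, a, k0b, zb, -q))

    # horizontal activation steps; the intermediate rows (DIV-up, IFM-bound)
    # are slowed without changing their equilibrium -- they are off-pathway
    # and would otherwise trickle recovering channels through open states
    a_f, a_b = _shifted(act["k0f"], act["zf"], act["k0b"], act["zb"],
                        params["act_shift_mV"], vt)
    a_scale = act.get("scale", 1.0)
    for closed, open_ in rows[:3]:
        add_pair(closed, open_, a_f * a_scale, act["zf"],
                 a_b * a_scale, act["zb"], act["q"])
    if has_gate_row:
        g_f, g_b = _shifted(act["k0f"], act["zf"], act["k0b"], act["zb"],
                            act67["shift_mV"], vt)
        add_pair("CI", "OI", g_f * act67["scale"], act["zf"],
                 g_b * act67["scale"], act["zb"], act["q"])

    # DIV sensor step
    d_f, d_b = _shifted(div["k0f"], div["zf"], div["k0b"], div["zb"],
                        params["div_shift_mV"], vt)
    add_pair("C", "C3", d_f, div["zf"], d_b, div["zb"], div["q"])
    add_pair("O", "O3", d_f, div["zf"], d_b, div["zb"], div["q"])

    # IFM binding (voltage independent, no charge)
    add_pair("C3", "C5", ifm["kon"], 0.0, ifm["koff"], 0.0, 0.0)
    add_pair("O3", "O5", ifm["kon"], 0.0, ifm["koff"], 0.0, 0.0)

    # gate closure: weakly voltage dependent so recovery at hyperpolarized
    # potentials is not equilibrium-blocked; carries a small charge
    if has_gate_row:
        zg = gate.get("z", 0.0)
        qg = gate.get("q", 0.0)
        add_pair("C5", "CI", gate["kc"], zg, gate["ko"], -zg, qg)
        # the open-column gate is slower (same equilibrium): recovery routes
        # through closed states, keeping wild-type tail kinetics fast
        os_ = gate.get("open_scale", 1.0)
        add_pair("O5", "OI", gate["kc"] * os_, zg, gate["ko"] * os_, -zg, qg)

    return GatingScheme(name, states, transitions,
                        n_channels=params["n_channels"])


def _load_config() -> dict:
    text = resources.files("navgate").joinpath("schemes/fixtures.json").read_text()
    return json.loads(text)


def fixture_catalog() -> list:
    """All reference fixtures with their machine-readable tuning targets."""
    cfg = _load_config()
    out = []
    for name, entry in cfg["fixtures"].items():
        params = copy.deepcopy(cfg["base"])
        for key, value in entry.get("overrides", {}).items():
            if isinstance(value, dict) and isinstance(params.get(key), dict):
                params[key] = {**params[key], **value}
            else:
                params[key] = value
        out.append(Fixture(name=name, params=params,
                           targets=dict(entry.get("targets", {}))))
    return out


def get_fixture(name: str) -> Fixture:
    for fx in fixture_catalog():
        if fx.name == name:
            return fx
    raise KeyError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def capacitive_current(protocol: Protocol, cap_nF: float,
                       tau_ms: float) -> np.ndarray:
    """Single-exponential clamp transient for every voltage step (uA)."""
    t, _ = protocol.voltage_trace()
    out = np.zeros_like(t)
    if cap_nF == 0.0:
        return out
    prev_v = protocol.holding_mV
    t_step = 0.0
    for v, dur in protocol.epochs:
        dv = v - prev_v
        if dv != 0.0:
            mask = t >= t_step - 1e-12
            out[mask] += (cap_nF * dv / tau_ms) * 1e-3 * np.exp(
                -(t[mask] - t_step) / tau_ms)
        prev_v = v
        t_step += dur
    return out


def _subtraction_protocol(protocol: Protocol, pn: PNSpec) -> Protocol:
    epochs = []
    for v, dur in protocol.epochs:
        dv = (v - protocol.holding_mV) / pn.n * pn.sign
        v_sub = pn.v_sub_mV + dv
        if not (-200.0 <= v_sub <= 120.0):
            raise ValueError(
                f"P/N subtraction epoch at {v_sub:.1f} mV exceeds protocol bounds")
        epochs.append((v_sub, dur))
    return Protocol(pn.v_sub_mV, tuple(epochs), protocol.sample_interval_ms)


def _simulate_sweep(scheme: GatingScheme, protocol: Protocol, sol: SolutionPair,
                    fixture: Fixture, pn: PNSpec | None) -> Sweep:
    main = propagate(scheme, protocol, sol, p_abs=fixture.p_abs)
    i_cap = capacitive_current(protocol, fixture.cap_nF, fixture.clamp_tau_ms)
    i_ionic, i_gating = main.i_ionic, main.i_gating

    if pn is not None:
        sub_proto = _subtraction_protocol(protocol, pn)
        sub = propagate(scheme, sub_proto, sol, p_abs=fixture.p_abs)
        sub_cap = capacitive_current(sub_proto, fixture.cap_nF,
                                     fixture.clamp_tau_ms)
        scale = pn.sign * pn.n
        i_ionic = i_ionic - scale * (sub.i_ionic - sub.i_ionic[0])
        i_gating = i_gating - scale * (sub.i_gating - sub.i_gating[0])
        i_cap = i_cap - scale * sub_cap

    return Sweep(t_ms=main.t_ms, v_mV=main.v_mV, i_ionic=i_ionic,
                 i_gating=i_gating, i_cap=i_cap, meta=dict(main.meta))


def generate_recording(fixture: Fixture, protocols, sol: SolutionPair,
                       noise: NoiseModel | None = None,
                       pn: PNSpec | None = None, ttx: bool = False,
                       sweep_key: str = "sweep_value") -> TraceSet:
    """Simulate a family of sweeps for one fixture.

    ``protocols`` is either a single :class:`Protocol` or a list of
    ``(sweep_value, Protocol)`` pairs as produced by
    :mod:`navgate.protocols`.  With ``pn`` given, N scaled subtraction sweeps
    are simulated and subtracted, which removes the linear capacitive
    transient exactly and leaves the nonlinear gating charge.  ``ttx`` zeroes
    the ionic conductance (gating-current configuration).
    """
    if isinstance(protocols, Protocol):
        protocols = [(None, protocols)]
    scheme = fixture.build_scheme(ttx=ttx)
    sweeps = []
    for idx, (value, proto) in enumerate(protocols):
        sweep = _simulate_sweep(scheme, proto, sol, fixture, pn)
        if noise is not None:
            sweep.noise = noise.sample(len(sweep.t_ms), proto.sample_interval_ms,
                                       stream=idx)
        sweep.meta.update({
            sweep_key: value,
            "fixture": fixture.name,
            "epoch_starts_ms": proto.epoch_starts_ms(),
            "ttx": ttx,
            "pn": None if pn is None else {"n": pn.n, "sign": pn.sign,
                                           "v_sub_mV": pn.v_sub_mV},
        })
        sweeps.append(sweep)
    meta = {
        "fixture": fixture.name,
        "ttx": ttx,
        "noise": None if noise is None else {
            "rms": noise.rms, "bandwidth_kHz": noise.bandwidth_kHz,
            "seed": noise.seed},
    }
    return TraceSet(sweeps=sweeps, solution=sol, meta=meta)
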