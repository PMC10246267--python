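"""Markov gating scheme, GHK ionic currents and voltage-clamp propagation.

A :class:`GatingScheme` is a labelled-state Markov chain with
voltage-dependent rates ``k(V) = k0 * exp(z_eff * F * V / (R * T))`` and a
signed gating charge ``q_gating`` per directed transition (the reverse
transition carries ``-q_gating``).  States carry relative Na+/K+
permeabilities; conducting occupancy is converted to ionic current with the
GHK flux equation.  Propagation under a piecewise-constant voltage protocol
is exact: one matrix exponential per epoch per sample interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm, null_space
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .constants import E0, FARADAY, T_DEFAULT, thermal_voltage_mV

SCHEMA_VERSION = 1

#: largest allowed |z_eff * V / (RT/F)| before a rate is declared overflowed
MAX_RATE_EXPONENT = 50.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolutionPair:
    """Extra/intracellular Na+ and K+ concentrations (mM) and temperature (K).

    All-zero concentrations are permitted and represent impermeant-cation
    (NMG) solutions used for gating-current recordings.
    """

    na_out: float
    k_out: float
    na_in: float
    k_in: float
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        for name in ("na_out", "k_out", "na_in", "k_in"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"concentration {name}={value} must be finite and >= 0")
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def vt_mV(self) -> float:
        return thermal_voltage_mV(self.temperature)

    def to_dict(self) -> dict:
        return {
            "na_out": self.na_out, "k_out": self.k_out,
            "na_in": self.na_in, "k_in": self.k_in,
            "temperature": self.temperature,
        }


@dataclass(frozen=True)
class State:
    name: str
    p_na: float = 0.0
    p_k: float = 0.0

    def __post_init__(self) -> None:
        if self.p_na < 0 or self.p_k < 0:
            raise ValueError(f"state {self.name}: permeabilities must be >= 0")


@dataclass(frozen=True)
class Transition:
    """Directed transition with rate law k0*exp(z_eff*V/vt).

    ``q_gating`` is the signed charge (e0 per channel) counted in the gating
    current when the transition fires; a listed reverse transition must carry
    the opposite sign.
    """

    from_state: str
    to_state: str
    k0: float
    z_eff: float = 0.0
    q_gating: float = 0.0

    def __post_init__(self) -> None:
        if self.k0 < 0 or not math.isfinite(self.k0):
            raise ValueError(
                f"transition {self.from_state}->{self.to_state}: k0 must be finite and >= 0")

    def rate(self, v_mV: float, vt_mV: float) -> float:
        exponent = self.z_eff * v_mV / vt_mV
        if abs(exponent) > MAX_RATE_EXPONENT:
            raise OverflowError(
                f"rate overflow on transition {self.from_state}->{self.to_state}: "
                f"z_eff*V/vt = {exponent:.1f} exceeds {MAX_RATE_EXPONENT}")
        return self.k0 * math.exp(exponent)


class GatingScheme:
    """Labelled-state Markov model of channel gating."""

    def __init__(self, name: str, states: list[State], transitions: list[Transition],
                 n_channels: float = 1e9):
        self.name = name
        self.states = list(states)
        self.transitions = list(transitions)
        self.n_channels = float(n_channels)
        self._index = {s.name: i for i, s in enumerate(self.states)}
        self._validate()

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "GatingScheme":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported scheme schema_version {version}")
        states = [State(s["name"], s.get("p_na", 0.0), s.get("p_k", 0.0))
                  for s in d["states"]]
        transitions = [
            Transition(t["from"], t["to"], t["k0"], t.get("z_eff", 0.0),
                       t.get("q_gating", 0.0))
            for t in d["transitions"]
        ]
        return cls(d.get("name", "scheme"), states, transitions,
                   d.get("n_channels", 1e9))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "n_channels": self.n_channels,
            "states": [{"name": s.name, "p_na": s.p_na, "p_k": s.p_k}
                       for s in self.states],
            "transitions": [
                {"from": t.from_state, "to": t.to_state, "k0": t.k0,
                 "z_eff": t.z_eff, "q_gating": t.q_gating}
                for t in self.transitions
            ],
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "GatingScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if len(self.states) != len(self._index):
            raise ValueError("duplicate state names")
        pair_index = {}
        for t in self.transitions:
            if t.from_state not in self._index or t.to_state not in self._index:
                raise ValueError(f"transition references unknown state: {t}")
            if t.from_state == t.to_state:
                raise ValueError(f"self-transition not allowed: {t.from_state}")
            key = (t.from_state, t.to_state)
            if key in pair_index:
                raise ValueError(f"duplicate transition {key}")
            pair_index[key] = t
        for (a, b), t in pair_index.items():
            rev = pair_index.get((b, a))
            if rev is None:
                raise ValueError(
                    f"transition {a}->{b} has no explicit reverse; absorbing "
                    "transitions must be listed with k0=0")
            if abs(rev.q_gating + t.q_gating) > 1e-12:
                raise ValueError(
                    f"q_gating of {b}->{a} must be the negative of {a}->{b}")
        self._check_connected()

    def _check_connected(self) -> None:
        n = len(self.states)
        rows, cols = [], []
        for t in self.transitions:
            if t.k0 > 0:
                rows.append(self._index[t.from_state])
                cols.append(self._index[t.to_state])
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=True, connection="weak")
        if n_comp != 1:
            raise ValueError(f"state graph is not connected ({n_comp} components)")

    # -- numerics --------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self._index[name]

    def rate_matrix(self, v_mV: float, temperature: float = T_DEFAULT) -> np.ndarray:
        """Generator matrix A with dP/dt = A @ P (rates in 1/ms)."""
        vt = thermal_voltage_mV(temperature)
        n = self.n_states
        a = np.zeros((n, n))
        for t in self.transitions:
            i, j = self._index[t.from_state], self._index[t.to_state]
            k = t.rate(v_mV, vt)
            a[j, i] += k
            a[i, i] -= k
        return a

    def permeability_matrix(self) -> np.ndarray:
        """(n_states, 2) array of per-state (p_na, p_k)."""
        return np.array([[s.p_na, s.p_k] for s in self.states])

    def scaled(self, conductance_scale: float = 1.0, name: str | None = None) -> "GatingScheme":
        """Copy with all state permeabilities multiplied by a factor.

        Used both for TTX block (scale 0) and for VSD-pore uncoupling
        phenotypes modelled as a reduced open probability.
        """
        states = [State(s.name, s.p_na * conductance_scale, s.p_k * conductance_scale)
                  for s in self.states]
        return GatingScheme(name or self.name, states, self.transitions, self.n_channels)


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant voltage-clamp protocol.

    ``epochs`` are (voltage_mV, duration_ms) pairs executed in order from the
    holding potential; sampling is uniform at ``sample_interval_ms``.
    """

    holding_mV: float
    epochs: tuple
    sample_interval_ms: float = 0.01

    def __post_init__(self) -> None:
        if self.sample_interval_ms <= 0:
            raise ValueError("sample interval must be > 0")
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        for v, dur in self.epochs:
            if dur <= 0:
                raise ValueError(f"epoch duration must be > 0 (got {dur})")
            if not math.isfinite(v):
                raise ValueError("epoch voltage must be finite")

    @property
    def total_ms(self) -> float:
        return sum(d for _, d in self.epochs)

    def epoch_samples(self) -> list[int]:
        """Number of samples per epoch (durations snapped to the grid)."""
        counts = []
        for _, dur in self.epochs:
            n = int(round(dur / self.sample_interval_ms))
            counts.append(max(n, 1))
        return counts

    def epoch_starts_ms(self) -> list[float]:
        starts, t = [], 0.0
        for _, dur in self.epochs:
            starts.append(t)
            t += dur
        return starts

    def voltage_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, v) arrays; sample j in an epoch carries that epoch's voltage."""
        counts = self.epoch_samples()
        n_total = sum(counts) + 1
        t = np.arange(n_total) * self.sample_interval_ms
        v = np.empty(n_total)
        j = 0
        for (volt, _), n in zip(self.epochs, counts):
            v[j:j + n] = volt
            j += n
        v[-1] = self.epochs[-1][0]
        return t, v

    def to_dict(self) -> dict:
        return {"holding_mV": self.holding_mV,
                "epochs": [[v, d] for v, d in self.epochs],
                "sample_interval_ms": self.sample_interval_ms}

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(d["holding_mV"], tuple((e[0], e[1]) for e in d["epochs"]),
                   d.get("sample_interval_ms", 0.01))


@dataclass
class Sweep:
    """One voltage-clamp sweep with its current components (uA)."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    i_ionic: np.ndarray
    i_gating: np.ndarray
    i_cap: np.ndarray = None
    noise: np.ndarray = None
    occupancy: np.ndarray = None          # (n_samples, n_states), optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.i_cap is None:
            self.i_cap = np.zeros_like(self.t_ms)
        if self.noise is None:
            self.noise = np.zeros_like(self.t_ms)
        n = len(self.t_ms)
        for name in ("v_mV", "i_ionic", "i_gating", "i_cap", "noise"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"sweep vector {name} length mismatch")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("time vector must be strictly increasing")

    @property
    def i_total(self) -> np.ndarray:
        return self.i_ionic + self.i_gating + self.i_cap + self.noise


@dataclass
class TraceSet:
    """A family of sweeps plus recording metadata."""

    sweeps: list
    solution: SolutionPair
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sweeps)

    def sweep_values(self, key: str = "sweep_value") -> np.ndarray:
        return np.array([s.meta.get(key) for s in self.sweeps], dtype=float)


# ---------------------------------------------------------------------------
# GHK flux
# ---------------------------------------------------------------------------

def _ghk_single(p: float, z: int, c_in: float, c_out: float,
                v_mV: float, vt_mV: float, p_abs: float) -> float:
    """I = p * p_abs * z * F * (c_in - c_out*exp(-u)) * u / (1 - exp(-u)).

    u = z*V/vt.  Branches keep every intermediate exponent <= 0 so the
    expression is stable (and continuous to better than 1e-9 at V = 0).
    """
    if p == 0.0 or (c_in == 0.0 and c_out == 0.0):
        return 0.0
    u = z * v_mV / vt_mV
    if abs(u) < 1e-10:
        conc = c_in - c_out + (c_in + c_out) * u / 2.0
        return p * p_abs * z * FARADAY * conc
    if u > 0:
        core = (c_in - c_out * math.exp(-u)) * u / (-math.expm1(-u))
    else:
        # multiplied through by exp(u) to avoid overflow at large negative u
        core = (c_in * math.exp(u) - c_out) * u / math.expm1(u)
    return p * p_abs * z * FARADAY * core


def ghk_current(p_na: float, p_k: float, v_mV: float, sol: SolutionPair,
                p_abs: float = 1.0) -> float:
    """Net GHK current (outward positive) for one channel-equivalent.

    ``p_na``/``p_k`` are dimensionless relative permeabilities (open-state
    Na+ permeability is 1 by convention); ``p_abs`` is the lumped absolute
    permeability scale that fixes the current unit (uA).  Concentrations are
    mM, voltage mV.
    """
    if not math.isfinite(v_mV):
        raise ValueError(f"voltage must be finite, got {v_mV}")
    if p_na < 0 or p_k < 0:
        raise ValueError("permeabilities must be >= 0")
    vt = sol.vt_mV
    i_na = _ghk_single(p_na, 1, sol.na_in, sol.na_out, v_mV, vt, p_abs)
    i_k = _ghk_single(p_k, 1, sol.k_in, sol.k_out, v_mV, vt, p_abs)
    return i_na + i_k


def ghk_current_states(perm: np.ndarray, v_mV: float, sol: SolutionPair,
                       p_abs: float) -> np.ndarray:
    """Per-state GHK currents for an (n_states, 2) permeability matrix."""
    return np.array([
        ghk_current(p_na, p_k, v_mV, sol, p_abs) for p_na, p_k in perm
    ])


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def steady_state(scheme: GatingScheme, v_mV: float,
                 temperature: float = T_DEFAULT) -> np.ndarray:
    """Stationary occupancy at a fixed voltage (null space of the generator)."""
    _check_irreducible(scheme, v_mV, temperature)
    a = scheme.rate_matrix(v_mV, temperature)
    ns = null_space(a, rcond=1e-12)
    if ns.shape[1] == 0:
        raise RuntimeError("no stationary distribution found")
    p = ns[:, 0]
    p = p * np.sign(p.sum())
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _check_irreducible(scheme: GatingScheme, v_mV: float, temperature: float) -> None:
    vt = thermal_voltage_mV(temperature)
    n = scheme.n_states
    rows, cols = [], []
    for t in scheme.transitions:
        if t.rate(v_mV, vt) > 0:
            rows.append(scheme.state_index(t.from_state))
            cols.append(scheme.state_index(t.to_state))
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        groups = [[scheme.states[i].name for i in np.where(labels == c)[0]]
                  for c in range(n_comp)]
        raise ValueError(
            f"chain reducible at {v_mV} mV; strongly connected components: {groups}")


def _initial_occupancy(scheme: GatingScheme, protocol: Protocol,
                       init, temperature: float) -> np.ndarray:
    if isinstance(init, str):
        if init != "equilibrium-at-holding":
            raise ValueError(f"unknown init mode {init!r}")
        return steady_state(scheme, protocol.holding_mV, temperature)
    p0 = np.asarray(init, dtype=float)
    if p0.shape != (scheme.n_states,):
        raise ValueError("init occupancy has wrong length")
    if abs(p0.sum() - 1.0) > 1e-8 or np.any(p0 < -1e-12):
        raise ValueError("init occupancy must be nonnegative and sum to 1")
    return p0


def propagate(scheme: GatingScheme, protocol: Protocol, sol: SolutionPair,
              init="equilibrium-at-holding", p_abs: float = 1.0,
              keep_occupancy: bool = False) -> Sweep:
    """Integrate the master equation under a voltage-clamp protocol.

    Exact per-epoch propagation: within each constant-voltage epoch the
    occupancy is advanced by the matrix exponential of the generator over one
    sample interval.  Returns a :class:`Sweep` with ionic and gating current
    components (no capacitive transient, no noise).
    """
    temperature = sol.temperature
    p = _initial_occupancy(scheme, protocol, init, temperature)
    t, v = protocol.voltage_trace()
    counts = protocol.epoch_samples()
    n_samples = len(t)
    occ = np.empty((n_samples, scheme.n_states))
    dt = protocol.sample_interval_ms

    occ[0] = p
    j = 1
    for (volt, _), n in zip(protocol.epochs, counts):
        a = scheme.rate_matrix(volt, temperature)
        m = expm(a * dt)
        for _ in range(n):
            p = m @ p
            occ[j] = p
            j += 1

    # renormalize roundoff drift (kept well below the 1e-9 contract)
    occ /= occ.sum(axis=1, keepdims=True)

    vt = thermal_voltage_mV(temperature)
    perm = scheme.permeability_matrix()

    # per-epoch state currents; sample voltages are piecewise constant
    i_ionic = np.empty(n_samples)
    i_gating = np.empty(n_samples)
    unique_v = {}
    for volt in v:
        if volt not in unique_v:
            unique_v[volt] = (
                ghk_current_states(perm, volt, sol, p_abs) * scheme.n_channels,
                _gating_flux_operator(scheme, volt, vt),
            )
    for idx in range(n_samples):
        state_i, gate_op = unique_v[v[idx]]
        i_ionic[idx] = occ[idx] @ state_i
        i_gating[idx] = gate_op @ occ[idx]

    sweep = Sweep(
        t_ms=t, v_mV=v, i_ionic=i_ionic, i_gating=i_gating,
        occupancy=occ if keep_occupancy else None,
        meta={"protocol": protocol.to_dict(), "scheme": scheme.name,
              "p_abs": p_abs},
    )
    return sweep


def _gating_flux_operator(scheme: GatingScheme, v_mV: float, vt_mV: float) -> np.ndarray:
    """Row vector g with I_gating(uA) = g @ occupancy.

    I_g = n_channels * e0 * sum_d q_d * k_d(V) * P(from_d), with the
    convention that the reverse transition carries -q; 1/ms flux to uA gives
    a factor 1e9.
    """
    g = np.zeros(scheme.n_states)
    for tr in scheme.transitions:
        if tr.q_gating == 0.0:
            continue
        k = tr.rate(v_mV, vt_mV)
        g[scheme.state_index(tr.from_state)] += tr.q_gating * k
    return g * scheme.n_channels * E0 * 1e9
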