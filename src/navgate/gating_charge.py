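"""Off-gating decomposition, charge immobilization and Q-V curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boltzmann import BoltzmannCurve, fit_rising
from .gating_model import Sweep, TraceSet
from .trace_analysis import (DEFAULT_BLANK_MS, ExpDecomposition,
                             fit_exponentials, fit_exponentials_xy)


@dataclass
class ImmobilizationCurve:
    """Immobilized-charge fraction vs conditioning duration."""

    durations_ms: np.ndarray
    fraction: np.ndarray
    onset_tau_ms: float
    asymptote: float
    decompositions: list = field(default_factory=list)


def _off_window(sweep: Sweep, blank_ms: float):
    starts = sweep.meta.get("epoch_starts_ms")
    if starts is None or len(starts) < 3:
        raise ValueError("sweep lacks an off epoch (epoch_starts_ms metadata)")
    return (starts[2] + blank_ms, float(sweep.t_ms[-1]))


GATING_BLANK_MS = 0.04    # P/N cancels the clamp transient, so fits can
                          # start early enough to catch the fast component


def decompose_off_gating(sweep: Sweep, off_window: tuple | None = None,
                         blank_ms: float = GATING_BLANK_MS,
                         n="auto") -> ExpDecomposition:
    """Exponential decomposition of the off-gating current (zero offset).

    Fits the return-to-holding gating current with one or two exponential
    decays; the second component is only kept when it passes the F-test, so
    a genuinely single-exponential off current reports a single component.
    """
    if off_window is None:
        off_window = _off_window(sweep, blank_ms)
    return fit_exponentials(sweep, n, off_window, fix_i_ss=0.0)


def immobilized_fraction(d: ExpDecomposition, total_charge="components") -> float:
    """Fraction of off-gating charge in the slow component.

    ``total_charge`` is either the measured total off charge (same units as
    |A|*tau) or the string "components" to use the sum of fitted components.
    """
    if len(d.components) == 1:
        q_slow = 0.0
    else:
        a_slow, tau_slow = d.components[-1]
        q_slow = abs(a_slow) * tau_slow
    if total_charge == "components":
        q_total = sum(abs(a) * tau for a, tau in d.components)
    else:
        q_total = float(total_charge)
    if q_total <= 0:
        raise ValueError(f"total off-gating charge must be > 0, got {q_total}")
    return q_slow / q_total


def integrate_off_charge(sweep: Sweep, off_window: tuple | None = None,
                         blank_ms: float = 0.0) -> float:
    """|integral| of the off-gating current over the off window (uA*ms)."""
    if off_window is None:
        off_window = _off_window(sweep, blank_ms)
    t, y = sweep.t_ms, sweep.i_total
    mask = (t >= off_window[0]) & (t <= off_window[1])
    return abs(float(np.trapezoid(y[mask], t[mask])))


def immobilization_course(ts: TraceSet, mode: str = "integral",
                          blank_ms: float = GATING_BLANK_MS) -> ImmobilizationCurve:
    """Immobilized fraction vs conditioning duration with an onset fit.

    ``mode`` selects the total-charge denominator: "integral" (default, the
    off-current integral) or "components" (sum of fitted A*tau terms).
    """
    if len(ts) < 4:
        raise ValueError("need >= 4 conditioning durations")
    durations, fractions, decomps = [], [], []
    for sweep in ts.sweeps:
        d = decompose_off_gating(sweep, blank_ms=blank_ms)
        if mode == "integral":
            total = integrate_off_charge(sweep)
        elif mode == "components":
            total = "components"
        else:
            raise ValueError(f"unknown total-charge mode {mode!r}")
        durations.append(sweep.meta.get("sweep_value"))
        fractions.append(immobilized_fraction(d, total))
        decomps.append(d)
    durations = np.asarray(durations, dtype=float)
    order = np.argsort(durations)
    durations = durations[order]
    fractions = np.asarray(fractions)[order]

    # single-exponential association: f(t) = asymptote*(1 - exp(-t/tau)) + f0
    assoc = fit_exponentials_xy(durations, fractions, 1,
                                min_points_per_component=4)
    onset_tau = assoc.taus[0]
    asymptote = assoc.i_ss
    return ImmobilizationCurve(durations_ms=durations, fraction=fractions,
                               onset_tau_ms=float(onset_tau),
                               asymptote=float(asymptote),
                               decompositions=[decomps[i] for i in order])


def on_gating_charge(sweep: Sweep, pulse_epoch: int = 1,
                     stop_fraction: float = 0.01) -> float:
    """Integrated on-gating charge for one sweep (uA*ms, signed).

    Integration starts at the pulse epoch and stops once |I_g| stays below
    ``stop_fraction`` of its peak (or at the epoch end).  The pre-pulse
    baseline is subtracted to reject DC offsets.
    """
    starts = sweep.meta.get("epoch_starts_ms")
    if starts is None or len(starts) <= pulse_epoch:
        raise ValueError("sweep lacks pulse epoch metadata")
    t, y = sweep.t_ms, sweep.i_total
    t0 = starts[pulse_epoch]
    t1 = starts[pulse_epoch + 1] if len(starts) > pulse_epoch + 1 else t[-1]
    t1 -= float(np.median(np.diff(t))) / 2      # drop the boundary sample
    base_mask = (t >= max(t[0], t0 - 1.0)) & (t < t0)
    baseline = float(y[base_mask].mean()) if np.any(base_mask) else 0.0
    mask = (t >= t0) & (t <= t1)
    seg_t, seg_y = t[mask], y[mask] - baseline
    peak = np.abs(seg_y).max()
    if peak == 0:
        return 0.0
    below = np.abs(seg_y) < stop_fraction * peak
    stop = len(seg_y)
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= 20:               # sustained sub-threshold tail
            stop = i + 1
            break
    return float(np.trapezoid(seg_y[:stop], seg_t[:stop]))


def qv_curve(ts: TraceSet, pulse_epoch: int = 1,
             stop_fraction: float = 0.01) -> BoltzmannCurve:
    """Normalized on-gating charge vs voltage with a two-state fit."""
    if len(ts) < 6:
        raise ValueError("need >= 6 voltages for a Q-V curve")
    v = ts.sweep_values()
    q = np.array([on_gating_charge(s, pulse_epoch, stop_fraction)
                  for s in ts.sweeps])
    q_max = np.abs(q).max()
    if q_max == 0:
        raise ValueError("no gating charge detected in family")
    q_norm = q / q.max()
    curve = fit_rising(v, q_norm, temperature=ts.solution.temperature)
    curve.warnings = [w for w in curve.warnings]
    return curve
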