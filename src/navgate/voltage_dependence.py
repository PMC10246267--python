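"""Availability (h-infinity), I-V and G-V relations with Boltzmann fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boltzmann import BoltzmannCurve, fit_falling, fit_rising
from .gating_model import TraceSet
from .trace_analysis import peak_and_steady


@dataclass
class IVData:
    """Peak and steady-state I-V relations with reversal potentials."""

    v_mV: np.ndarray
    i_peak: np.ndarray
    i_steady: np.ndarray
    v_rev_peak: float
    v_rev_steady: float
    se: dict = field(default_factory=dict)


def _pulse_window(sweep, pulse_epoch: int = 1):
    starts = sweep.meta.get("epoch_starts_ms")
    if starts is None or len(starts) <= pulse_epoch:
        raise ValueError("sweep lacks pulse epoch metadata")
    t0 = starts[pulse_epoch]
    t1 = (starts[pulse_epoch + 1] if len(starts) > pulse_epoch + 1
          else float(sweep.t_ms[-1]))
    # keep the epoch-boundary sample (already at the next voltage) out
    dt = float(np.median(np.diff(sweep.t_ms)))
    return t0, t1 - dt / 2


def h_infinity(ts: TraceSet, test_epoch: int = 2, blank_ms: float = 0.15,
               noise_tol: float = 0.05) -> BoltzmannCurve:
    """Steady-state availability curve from a conditioning-voltage family.

    Plots the normalized test-pulse peak current against conditioning
    voltage and fits the falling two-state form (Base + (1-Base)/(1+exp)).
    Non-monotone peaks beyond ``noise_tol`` set a warning flag; the fit is
    still returned.
    """
    v_cond, peaks = [], []
    for sweep in ts.sweeps:
        starts = sweep.meta.get("epoch_starts_ms")
        if starts is None or len(starts) <= test_epoch:
            raise ValueError("sweep lacks test epoch metadata")
        t0 = starts[test_epoch]
        t1 = (starts[test_epoch + 1] if len(starts) > test_epoch + 1
              else float(sweep.t_ms[-1]))
        t1 -= float(np.median(np.diff(sweep.t_ms))) / 2
        # baseline from the initial holding epoch: the conditioning epoch can
        # carry steady current for non-inactivating constructs
        i_peak, _, _ = peak_and_steady(
            sweep, (t0 + blank_ms, t1),
            baseline_window=(float(sweep.t_ms[0]), starts[1] - 0.001))
        v_cond.append(sweep.meta.get("sweep_value"))
        peaks.append(abs(i_peak))
    v_cond = np.asarray(v_cond, dtype=float)
    peaks = np.asarray(peaks)
    order = np.argsort(v_cond)
    v_cond, peaks = v_cond[order], peaks[order]
    y = peaks / peaks.max()

    curve = fit_falling(v_cond, y, temperature=ts.solution.temperature)
    rises = np.diff(y) > noise_tol
    if np.any(rises):
        curve.warnings.append("availability curve non-monotone beyond noise")
    return curve


def linear_reversal(v: np.ndarray, i: np.ndarray, n_fit: int = 4):
    """Reversal potential from a linear fit of points bracketing zero current.

    Returns (v_rev, se).  Raises if the I-V points never change sign.
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    sign_change = np.nonzero(np.diff(np.sign(i)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("reversal not bracketed by the I-V family")
    k = sign_change[-1]
    lo = max(0, k - (n_fit // 2 - 1))
    hi = min(len(v), lo + n_fit)
    lo = max(0, hi - n_fit)
    vv, ii = v[lo:hi], i[lo:hi]
    if len(vv) > 2:
        coeffs, cov = np.polyfit(vv, ii, 1, cov=True)
    else:
        coeffs = np.polyfit(vv, ii, 1)
        cov = np.zeros((2, 2))
    slope, intercept = coeffs
    if slope == 0:
        raise ValueError("degenerate linear fit (zero slope)")
    v_rev = -intercept / slope
    # first-order error propagation on -b/a
    var = (cov[1, 1] / slope**2 + cov[0, 0] * intercept**2 / slope**4
           - 2 * cov[0, 1] * intercept / slope**3)
    se = float(np.sqrt(max(var, 0.0)))
    return float(v_rev), se


def iv_curves(ts: TraceSet, pulse_epoch: int = 1, blank_ms: float = 0.15) -> IVData:
    """Peak and steady-state I-V curves with interpolated reversal potentials."""
    if len(ts) < 6:
        raise ValueError("need >= 6 voltages for an I-V family")
    v, ip, iss = [], [], []
    for sweep in ts.sweeps:
        t0, t1 = _pulse_window(sweep, pulse_epoch)
        i_peak, i_steady, _ = peak_and_steady(
            sweep, (t0 + blank_ms, t1),
            baseline_window=(max(float(sweep.t_ms[0]), t0 - 1.0), t0 - 0.001))
        v.append(sweep.meta.get("sweep_value"))
        ip.append(i_peak)
        iss.append(i_steady)
    v = np.asarray(v, dtype=float)
    ip, iss = np.asarray(ip), np.asarray(iss)
    v_rev_p, se_p = linear_reversal(v, ip)
    v_rev_s, se_s = linear_reversal(v, iss)
    return IVData(v_mV=v, i_peak=ip, i_steady=iss, v_rev_peak=v_rev_p,
                  v_rev_steady=v_rev_s,
                  se={"v_rev_peak": se_p, "v_rev_steady": se_s})


def gv_curve(v: np.ndarray, i: np.ndarray, v_rev: float,
             temperature: float = 284.65, exclusion_mV: float = 2.0,
             min_points: int = 5) -> BoltzmannCurve:
    """Conductance-voltage curve from currents and a reversal potential.

    G = I / (V - V_rev) (ohmic driving force, as in the printed analysis),
    normalized to the maximum across the family and fitted with the rising
    two-state form.  Points within ``exclusion_mV`` of V_rev are dropped.
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    mask = np.abs(v - v_rev) >= exclusion_mV
    if mask.sum() < min_points:
        raise ValueError(
            f"fewer than {min_points} points remain after excluding "
            f"|V - V_rev| < {exclusion_mV} mV")
    v, i = v[mask], i[mask]
    g = i / (v - v_rev)
    g_max = g.max()
    if g_max <= 0:
        raise ValueError("non-positive maximal conductance")
    return fit_rising(v, g / g_max, temperature=temperature)
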