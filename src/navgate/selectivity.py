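"""Time-resolved Na+/K+ selectivity from instantaneous I-V families.

Pipeline: sample tail currents shortly after the tail step (instantaneous
I-V), fit each I-V linearly to locate the reversal potential, convert
reversal potentials to permeability ratios with the bionic GHK reversal
relation, and fit the time course of the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import thermal_voltage_mV
from .gating_model import SolutionPair, TraceSet
from .trace_analysis import DEFAULT_BLANK_MS, fit_exponentials_xy
from .voltage_dependence import linear_reversal

DEFAULT_LATENCY_MS = 0.2


@dataclass
class PermeabilityTimeCourse:
    """P_Na/P_K vs depolarization time with an exponential fit."""

    times_ms: np.ndarray
    v_rev_mV: np.ndarray
    p_ratio: np.ndarray
    p_ratio_inf: float
    fit_components: list            # [(amplitude, tau_ms)]
    tau_perm_fast_ms: float
    constant_flag: bool = False
    meta: dict = field(default_factory=dict)


def instantaneous_iv(ts: TraceSet, latency_ms: float = DEFAULT_LATENCY_MS,
                     blank_ms: float = DEFAULT_BLANK_MS, tail_epoch: int = 2):
    """(v_tail, i) points sampled ``latency_ms`` after the tail step.

    The family varies the tail voltage at a fixed depolarization duration;
    the sampling latency must clear the capacitive blank.
    """
    if latency_ms < blank_ms:
        raise ValueError(
            f"sampling latency {latency_ms} ms lies inside the {blank_ms} ms "
            "capacitive blank")
    v_tail, i_inst = [], []
    for sweep in ts.sweeps:
        starts = sweep.meta.get("epoch_starts_ms")
        if starts is None or len(starts) <= tail_epoch:
            raise ValueError("sweep lacks tail epoch metadata")
        t_sample = starts[tail_epoch] + latency_ms
        if t_sample > sweep.t_ms[-1]:
            raise ValueError("sampling latency beyond sweep end")
        idx = int(np.argmin(np.abs(sweep.t_ms - t_sample)))
        base_mask = sweep.t_ms < starts[1]
        baseline = float(sweep.i_total[base_mask].mean()) if np.any(base_mask) else 0.0
        v_tail.append(sweep.meta.get("sweep_value"))
        i_inst.append(float(sweep.i_total[idx]) - baseline)
    return np.asarray(v_tail, dtype=float), np.asarray(i_inst)


def reversal_vs_time(families: dict, latency_ms: float = DEFAULT_LATENCY_MS,
                     blank_ms: float = DEFAULT_BLANK_MS):
    """(times, v_rev, se) from instantaneous I-V families keyed by time.

    ``families`` maps depolarization duration (ms) to a tail-voltage
    :class:`TraceSet`.
    """
    if len(families) < 3:
        raise ValueError("need >= 3 depolarization time points")
    times = sorted(families)
    v_revs, ses = [], []
    for t_dep in times:
        v, i = instantaneous_iv(families[t_dep], latency_ms, blank_ms)
        v_rev, se = linear_reversal(v, i)
        v_revs.append(v_rev)
        ses.append(se)
    return (np.asarray(times, dtype=float), np.asarray(v_revs),
            np.asarray(ses))


def permeability_ratio(v_rev_mV: float, sol: SolutionPair) -> float:
    """Invert the bionic GHK reversal relation for P_Na/P_K.

    Requires a bionic solution pair (Na+ outside only, K+ inside only);
    other compositions need the full GHK zero-current root instead.
    """
    if sol.k_out != 0.0 or sol.na_in != 0.0:
        raise ValueError(
            "permeability_ratio requires bionic solutions (k_out = na_in = 0); "
            "use the full-GHK zero-current mode for mixed solutions")
    if sol.na_out <= 0 or sol.k_in <= 0:
        raise ValueError("bionic inversion needs na_out > 0 and k_in > 0")
    vt = sol.vt_mV
    return (sol.k_in / sol.na_out) * math.exp(v_rev_mV / vt)


def reversal_from_ratio(p_ratio: float, sol: SolutionPair) -> float:
    """Forward bionic GHK reversal: V_rev = vt * ln(p * [Na]o / [K]i)."""
    if p_ratio <= 0:
        raise ValueError("permeability ratio must be > 0")
    vt = sol.vt_mV
    return vt * math.log(p_ratio * sol.na_out / sol.k_in)


def permeability_time_course(times_ms, v_rev_mV, sol: SolutionPair,
                             inactivation_taus=None,
                             rel_const_tol: float = 1e-3) -> PermeabilityTimeCourse:
    """P_Na/P_K(t) with a two-component exponential fit of its decay.

    Returns the fast permeability time constant; when ``inactivation_taus``
    (a sample of inactivation time constants) is supplied, a Welch t-test
    against the fast tau is included in ``meta``.
    """
    times = np.asarray(times_ms, dtype=float)
    v_rev = np.asarray(v_rev_mV, dtype=float)
    if len(times) < 4:
        raise ValueError("need >= 4 time points")
    p = np.array([permeability_ratio(v, sol) for v in v_rev])

    spread = p.max() - p.min()
    if spread <= rel_const_tol * abs(p.mean()):
        return PermeabilityTimeCourse(
            times_ms=times, v_rev_mV=v_rev, p_ratio=p,
            p_ratio_inf=float(p.mean()), fit_components=[],
            tau_perm_fast_ms=math.nan, constant_flag=True,
            meta={"tau_comparison": "undefined (constant series)"})

    n_comp = 2 if len(times) >= 6 else 1
    try:
        fit = fit_exponentials_xy(times, p, n_comp,
                                  min_points_per_component=3)
    except ValueError:
        fit = fit_exponentials_xy(times, p, 1, min_points_per_component=4)
    decaying = [(a, tau) for a, tau in fit.components if a > 0]
    tau_fast = min((tau for _, tau in decaying), default=fit.taus[0])

    meta = {}
    if inactivation_taus is not None:
        taus = np.asarray(inactivation_taus, dtype=float)
        t_stat, p_val = stats.ttest_1samp(taus, tau_fast)
        meta["tau_comparison"] = {"t": float(t_stat), "p": float(p_val),
                                  "tau_perm_fast": float(tau_fast),
                                  "tau_fi_mean": float(taus.mean())}
    return PermeabilityTimeCourse(
        times_ms=times, v_rev_mV=v_rev, p_ratio=p,
        p_ratio_inf=float(fit.i_ss), fit_components=fit.components,
        tau_perm_fast_ms=float(tau_fast), constant_flag=False, meta=meta)


def welch_tau_comparison(taus_a, taus_b):
    """Welch's t-test between two samples of time constants."""
    t_stat, p_val = stats.ttest_ind(np.asarray(taus_a, dtype=float),
                                    np.asarray(taus_b, dtype=float),
                                    equal_var=False)
    return float(t_stat), float(p_val)
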