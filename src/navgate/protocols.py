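"""Built-in voltage-clamp protocol families.

Every builder returns a list of ``(sweep_value, Protocol)`` pairs; the sweep
value is the quantity varied across the family (test voltage, conditioning
voltage, depolarization duration, tail voltage ...).  All protocols start
with a short epoch at the holding potential so downstream analysis has a
pre-pulse baseline.
"""

from __future__ import annotations

import numpy as np

from .gating_model import Protocol

DEFAULT_DT_MS = 0.01
HOLDING_MV = -130.0


def step_protocol(holding: float, epochs, dt: float = DEFAULT_DT_MS) -> Protocol:
    return Protocol(holding_mV=holding, epochs=tuple(epochs), sample_interval_ms=dt)


def iv_family(v_min: float = -80.0, v_max: float = 60.0, v_step: float = 10.0,
              holding: float = HOLDING_MV, baseline_ms: float = 2.0,
              pulse_ms: float = 30.0, post_ms: float = 8.0,
              dt: float = DEFAULT_DT_MS):
    """Voltage family for peak/steady I-V and G-V curves."""
    out = []
    for v in np.arange(v_min, v_max + v_step / 2, v_step):
        v = float(v)
        proto = step_protocol(holding, [(holding, baseline_ms), (v, pulse_ms),
                                        (holding, post_ms)], dt)
        out.append((v, proto))
    return out


def h_infinity_family(v_min: float = -130.0, v_max: float = -10.0,
                      v_step: float = 10.0, conditioning_ms: float = 80.0,
                      test_mV: float = -10.0, test_ms: float = 12.0,
                      holding: float = HOLDING_MV, baseline_ms: float = 2.0,
                      dt: float = DEFAULT_DT_MS):
    """Conditioning-voltage family for the steady-state availability curve."""
    out = []
    for v in np.arange(v_min, v_max + v_step / 2, v_step):
        v = float(v)
        proto = step_protocol(
            holding,
            [(holding, baseline_ms), (v, conditioning_ms), (test_mV, test_ms),
             (holding, 5.0)], dt)
        out.append((v, proto))
    return out


def immobilization_family(durations_ms=(0.5, 1.0, 2.0, 3.5, 5.0, 8.0, 12.0,
                                        17.0, 23.0),
                          pulse_mV: float = 20.0, holding: float = HOLDING_MV,
                          baseline_ms: float = 1.0, off_ms: float = 15.0,
                          dt: float = DEFAULT_DT_MS):
    """Conditioning-duration family for off-gating charge immobilization."""
    out = []
    for dur in durations_ms:
        proto = step_protocol(
            holding, [(holding, baseline_ms), (pulse_mV, dur), (holding, off_ms)],
            dt)
        out.append((float(dur), proto))
    return out


def qv_family(v_min: float = -110.0, v_max: float = 40.0, v_step: float = 10.0,
              pulse_ms: float = 25.0, holding: float = HOLDING_MV,
              baseline_ms: float = 1.0, post_ms: float = 12.0,
              dt: float = DEFAULT_DT_MS):
    """Voltage family for Q-V curves (gating-current integration)."""
    out = []
    for v in np.arange(v_min, v_max + v_step / 2, v_step):
        v = float(v)
        proto = step_protocol(holding, [(holding, baseline_ms), (v, pulse_ms),
                                        (holding, post_ms)], dt)
        out.append((v, proto))
    return out


def instantaneous_iv_family(depol_times_ms=(0.6, 1.0, 2.0, 3.5, 5.0, 10.0, 20.0),
                            tail_voltages=tuple(range(-20, 61, 10)),
                            depol_mV: float = 60.0, tail_ms: float = 4.0,
                            holding: float = HOLDING_MV, baseline_ms: float = 1.0,
                            dt: float = DEFAULT_DT_MS):
    """Two-level family: for each depolarization time, a tail-voltage sweep.

    Returns ``{t_depol: [(v_tail, Protocol), ...]}``.
    """
    families = {}
    for t_dep in depol_times_ms:
        sweeps = []
        for v_tail in tail_voltages:
            v_tail = float(v_tail)
            proto = step_protocol(
                holding,
                [(holding, baseline_ms), (depol_mV, t_dep), (v_tail, tail_ms),
                 (holding, 3.0)], dt)
            sweeps.append((v_tail, proto))
        families[float(t_dep)] = sweeps
    return families


def tail_duration_family(durations_ms=(0.3, 0.5, 0.8, 1.2, 1.8, 2.6, 4.0, 6.0,
                                       9.0, 14.0, 20.0),
                         depol_mV: float = 60.0, tail_mV: float = -80.0,
                         tail_ms: float = 10.0, holding: float = HOLDING_MV,
                         baseline_ms: float = 1.0, dt: float = DEFAULT_DT_MS):
    """Variable-duration depolarization followed by a fixed tail step."""
    out = []
    for dur in durations_ms:
        proto = step_protocol(
            holding,
            [(holding, baseline_ms), (depol_mV, dur), (tail_mV, tail_ms)], dt)
        out.append((float(dur), proto))
    return out


BUILTIN_FAMILIES = {
    "iv_family": iv_family,
    "h_infinity": h_infinity_family,
    "immobilization_family": immobilization_family,
    "qv_family": qv_family,
    "instantaneous_iv": instantaneous_iv_family,
    "tail_duration_family": tail_duration_family,
}
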