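"""Two-state Boltzmann fits shared by the Q-V, G-V and availability curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import T_DEFAULT, thermal_voltage_mV


@dataclass
class BoltzmannCurve:
    """Normalized sigmoid data and its two-state fit.

    ``direction`` is "rising" for G-V/Q-V style curves (y -> 1 with
    depolarization) and "falling" for availability curves (y -> Base).
    ``z_app`` is reported positive for both.
    """

    x_mV: np.ndarray
    y: np.ndarray
    v_half: float
    z_app: float
    baseline: float = 0.0
    se: dict = field(default_factory=dict)
    direction: str = "rising"
    warnings: list = field(default_factory=list)

    def predict(self, v: np.ndarray, temperature: float = T_DEFAULT) -> np.ndarray:
        vt = thermal_voltage_mV(temperature)
        if self.direction == "rising":
            return 1.0 / (1.0 + np.exp(-self.z_app * (v - self.v_half) / vt))
        return self.baseline + (1.0 - self.baseline) / (
            1.0 + np.exp(self.z_app * (v - self.v_half) / vt))


def fit_rising(v: np.ndarray, y: np.ndarray,
               temperature: float = T_DEFAULT) -> BoltzmannCurve:
    """Fit y = 1 / (1 + exp(-z (V - V1/2) / vt))."""
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    vt = thermal_voltage_mV(temperature)

    def model(vv, v_half, z):
        return 1.0 / (1.0 + np.exp(-z * (vv - v_half) / vt))

    v0 = float(v[np.argmin(np.abs(y - 0.5))])
    popt, pcov = optimize.curve_fit(model, v, y, p0=[v0, 2.0],
                                    bounds=([-200, 0.05], [200, 20]),
                                    maxfev=20000)
    se = _se(pcov, ["v_half", "z_app"])
    return BoltzmannCurve(x_mV=v, y=y, v_half=float(popt[0]),
                          z_app=float(popt[1]), baseline=0.0, se=se,
                          direction="rising")


def fit_falling(v: np.ndarray, y: np.ndarray, temperature: float = T_DEFAULT,
                fit_base: bool = True) -> BoltzmannCurve:
    """Fit y = Base + (1 - Base) / (1 + exp(z (V - V1/2) / vt)).

    This is the availability form: y -> 1 at hyperpolarized voltages and
    y -> Base with depolarization, with z reported positive.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    vt = thermal_voltage_mV(temperature)

    def model(vv, v_half, z, base):
        return base + (1.0 - base) / (1.0 + np.exp(z * (vv - v_half) / vt))

    v0 = float(v[np.argmin(np.abs(y - 0.5 * (y.max() + y.min())))])
    base0 = float(max(min(y.min(), 0.99), 0.0))
    if fit_base:
        popt, pcov = optimize.curve_fit(
            model, v, y, p0=[v0, 3.0, base0],
            bounds=([-200, 0.05, -0.2], [200, 20, 1.05]), maxfev=20000)
        v_half, z, base = popt
        se = _se(pcov, ["v_half", "z_app", "baseline"])
    else:
        popt, pcov = optimize.curve_fit(
            lambda vv, v_half, z: model(vv, v_half, z, 0.0), v, y,
            p0=[v0, 3.0], bounds=([-200, 0.05], [200, 20]), maxfev=20000)
        v_half, z, base = popt[0], popt[1], 0.0
        se = _se(pcov, ["v_half", "z_app"])
    return BoltzmannCurve(x_mV=v, y=y, v_half=float(v_half), z_app=float(z),
                          baseline=float(base), se=se, direction="falling")


def _se(pcov, names):
    diag = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return {name: float(s) for name, s in zip(names, diag)}
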