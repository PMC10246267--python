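"""Peak/steady-state extraction and exponential kinetics fitting.

Exponential fits use variable projection: amplitudes and offset are solved
linearly for any trial set of time constants, and only the (log) time
constants are optimized, from multiple starting points.  This keeps 1- and
2-exponential fits robust without hand-tuned initial amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .gating_model import Sweep, TraceSet

DEFAULT_BLANK_MS = 0.15   # fit dead time after a voltage step (clamp settling)


@dataclass
class ExpDecomposition:
    """1- or 2-exponential decay fit: I(t) = sum A_i exp(-t/tau_i) + i_ss."""

    components: list                  # [(A_uA, tau_ms)], ordered fast -> slow
    i_ss: float
    window: tuple
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError("1 or 2 exponential components required")
        for _, tau in self.components:
            if tau <= 0:
                raise ValueError("time constants must be > 0")
        self.components = sorted(self.components, key=lambda c: c[1])

    @property
    def taus(self) -> list:
        return [tau for _, tau in self.components]

    @property
    def amplitudes(self) -> list:
        return [a for a, _ in self.components]

    def predict(self, t: np.ndarray) -> np.ndarray:
        y = np.full_like(t, self.i_ss, dtype=float)
        for a, tau in self.components:
            y = y + a * np.exp(-t / tau)
        return y


@dataclass
class TailCourse:
    """Weighted tail time constant vs depolarization duration."""

    durations_ms: np.ndarray
    tau_w_ms: np.ndarray
    association_y0: float
    association_components: list      # [(amplitude, tau_ms)]
    tau_fast_assoc_ms: float
    decompositions: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def _design_rss(log_taus, t, y, fit_offset, tau_bounds=None):
    taus = np.exp(log_taus)
    if tau_bounds is not None and (np.any(taus < tau_bounds[0])
                                   or np.any(taus > tau_bounds[1])):
        return np.inf, np.full(len(taus) + int(fit_offset), np.nan), taus
    cols = [np.exp(-t / tau) for tau in taus]
    if fit_offset:
        cols.append(np.ones_like(t))
    design = np.column_stack(cols)
    coeffs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    return float(resid @ resid), coeffs, taus


def _tau_starts(n: int, span: float, dt: float):
    lo = max(2 * dt, span / 300.0)
    grid = np.geomspace(lo, span, 6)
    if n == 1:
        return [[tau] for tau in grid]
    starts = []
    for i in range(len(grid)):
        for j in range(i + 1, len(grid)):
            starts.append([grid[i], grid[j]])
    return starts


def fit_exponentials_xy(t: np.ndarray, y: np.ndarray, n: int,
                        fix_i_ss: float | None = None,
                        window: tuple | None = None,
                        min_points_per_component: int = 10) -> ExpDecomposition:
    """Fit ``y(t)`` with ``n`` exponential decays (t relative to window start)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
        t = t - window[0]
    if len(t) == 0:
        raise ValueError("empty fit window")
    if len(t) < min_points_per_component * n:
        raise ValueError(
            f"need >= {min_points_per_component * n} points for an "
            f"{n}-exponential fit, got {len(t)}")
    fit_offset = fix_i_ss is None
    y_fit = y if fit_offset else y - fix_i_ss
    span = float(t[-1] - t[0]) or 1.0
    dt = float(np.median(np.diff(t)))

    # keep time constants resolvable by the data: no faster than half a
    # sample, no slower than a few window spans
    tau_bounds = (dt / 2, 5.0 * span)
    best = None
    diagnostics = []
    for start in _tau_starts(n, span, dt):
        x0 = np.log(start)
        try:
            res = optimize.minimize(
                lambda lt: _design_rss(lt, t, y_fit, fit_offset, tau_bounds)[0],
                x0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000})
        except (ValueError, FloatingPointError) as exc:   # pragma: no cover
            diagnostics.append(str(exc))
            continue
        rss, coeffs, taus = _design_rss(res.x, t, y_fit, fit_offset, tau_bounds)
        if not np.isfinite(rss):
            continue
        if not np.all(np.isfinite(coeffs)):
            continue
        if best is None or rss < best[0]:
            best = (rss, coeffs, taus)
    if best is None:
        raise RuntimeError(f"exponential fit failed to converge; diagnostics: "
                           f"{diagnostics}")
    rss, coeffs, taus = best
    i_ss = fix_i_ss if fix_i_ss is not None else float(coeffs[-1])
    amps = coeffs[:n]
    components = [(float(a), float(tau)) for a, tau in zip(amps, taus)]
    win = window if window is not None else (float(t[0]), float(t[-1]))
    return ExpDecomposition(components=components, i_ss=i_ss, window=win,
                            rss=rss, n_points=len(t))


def f_test_p(rss1: float, rss2: float, n_points: int, extra_params: int = 2,
             params2: int = 5) -> float:
    """p-value that the richer model (rss2) is a real improvement."""
    dof2 = n_points - params2
    if rss2 <= 0 or dof2 <= 0:
        return 0.0
    f_stat = ((rss1 - rss2) / extra_params) / (rss2 / dof2)
    if f_stat <= 0:
        return 1.0
    return float(stats.f.sf(f_stat, extra_params, dof2))


def fit_exponentials(sweep: Sweep, n, window: tuple,
                     fix_i_ss: float | None = None,
                     f_threshold: float = 0.01) -> ExpDecomposition:
    """Fit a sweep's total current in ``window`` with 1 or 2 exponentials.

    ``n`` may be 1, 2 or ``"auto"``.  Requesting 2 components does not force
    them: the richer model is refused unless it improves the fit at the
    configured F-test threshold, so a genuinely single-exponential trace
    always comes back with one component.
    """
    t, y = sweep.t_ms, sweep.i_total
    if n == 1:
        return fit_exponentials_xy(t, y, 1, fix_i_ss, window)
    if n not in (2, "auto"):
        raise ValueError(f"n must be 1, 2 or 'auto', got {n!r}")
    d1 = fit_exponentials_xy(t, y, 1, fix_i_ss, window)
    try:
        d2 = fit_exponentials_xy(t, y, 2, fix_i_ss, window)
    except (ValueError, RuntimeError):
        return d1
    offset_params = 0 if fix_i_ss is not None else 1
    p = f_test_p(d1.rss, d2.rss, d1.n_points,
                 params2=4 + offset_params)
    return d2 if p < f_threshold else d1


def weighted_tau(d: ExpDecomposition) -> float:
    """Amplitude-weighted mean time constant (|A| weights)."""
    weights = [abs(a) for a, _ in d.components]
    total = sum(weights)
    if total == 0:
        raise ValueError("all amplitudes are zero; weighted tau undefined")
    return sum(w * tau for w, (_, tau) in zip(weights, d.components)) / total


# ---------------------------------------------------------------------------
# peak / steady-state measures
# ---------------------------------------------------------------------------

def peak_and_steady(sweep: Sweep, peak_window: tuple,
                    steady_window: tuple | None = None,
                    baseline_window: tuple | None = None):
    """(i_peak, i_ss, ratio) for one sweep, baseline subtracted.

    The peak is the signed extremum of |I| in ``peak_window``; the steady
    level is the mean over ``steady_window`` (default: last 10% of the peak
    window).  The baseline defaults to the mean over the 1 ms preceding the
    peak window.
    """
    t, y = sweep.t_ms, sweep.i_total
    t0, t1 = peak_window
    if steady_window is None:
        steady_window = (t1 - 0.1 * (t1 - t0), t1)
    if baseline_window is None:
        baseline_window = (max(t[0], t0 - 1.0), t0)

    def _mask(win):
        m = (t >= win[0]) & (t <= win[1])
        if not np.any(m):
            raise ValueError(f"empty window {win}")
        return m

    base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    baseline = float(y[base_mask].mean()) if np.any(base_mask) else 0.0
    yc = y - baseline

    pm = _mask(peak_window)
    idx = np.argmax(np.abs(yc[pm]))
    i_peak = float(yc[pm][idx])
    i_ss = float(yc[_mask(steady_window)].mean())
    if i_peak == 0.0:
        raise ValueError("zero peak current; ratio undefined")
    return i_peak, i_ss, i_ss / i_peak


# ---------------------------------------------------------------------------
# variable-duration tail analysis
# ---------------------------------------------------------------------------

def _tail_weighted_tau(d: ExpDecomposition, sweep: Sweep, window: tuple) -> float:
    """Weighted tau over sign-consistent tail components.

    Components whose amplitude opposes the tail's polarity (e.g. the slowly
    redeveloping standing window current after recovery) are not part of the
    deactivating tail and are excluded from the weighting.
    """
    t, y = sweep.t_ms, sweep.i_total
    mask = (t >= window[0]) & (t <= window[1])
    resid = y[mask] - d.i_ss
    polarity = np.sign(resid[np.argmax(np.abs(resid))])
    kept = [(a, tau) for a, tau in d.components if np.sign(a) == polarity]
    if not kept:
        kept = d.components
    weights = [abs(a) for a, _ in kept]
    return sum(w * tau for w, (_, tau) in zip(weights, kept)) / sum(weights)


def _tail_window(sweep: Sweep, blank_ms: float):
    starts = sweep.meta.get("epoch_starts_ms")
    if starts is None or len(starts) < 3:
        raise ValueError("sweep lacks a tail epoch (epoch_starts_ms metadata)")
    tail_start = starts[2]
    t_end = float(sweep.t_ms[-1])
    if len(starts) > 3:
        t_end = starts[3] - float(np.median(np.diff(sweep.t_ms))) / 2
    return (tail_start + blank_ms, t_end)


def tail_time_course(ts: TraceSet, blank_ms: float = DEFAULT_BLANK_MS,
                     f_threshold: float = 0.01) -> TailCourse:
    """Weighted tail-current time constant vs depolarization duration.

    Each sweep must hold a variable-duration depolarization followed by a
    fixed tail step (epoch 2).  The tau_w(t_depol) course is fitted with a
    two-component exponential association; the fast association time
    constant is returned for comparison with the inactivation time constant.
    """
    if len(ts) < 4:
        raise ValueError("need >= 4 depolarization durations")
    durations, tau_ws, decomps = [], [], []
    for sweep in ts.sweeps:
        window = _tail_window(sweep, blank_ms)
        # pin the offset to the settled late-tail level; otherwise a slow
        # pseudo-component can absorb the baseline and corrupt tau_w
        t, y = sweep.t_ms, sweep.i_total
        late = (t >= window[1] - 0.1 * (window[1] - window[0])) & (t <= window[1])
        d = fit_exponentials(sweep, "auto", window, f_threshold=f_threshold,
                             fix_i_ss=float(y[late].mean()))
        durations.append(sweep.meta.get("sweep_value"))
        tau_ws.append(_tail_weighted_tau(d, sweep, window))
        decomps.append(d)
    durations = np.asarray(durations, dtype=float)
    order = np.argsort(durations)
    durations, tau_ws = durations[order], np.asarray(tau_ws)[order]

    # association y(t) = y0 + sum a_i (1 - exp(-t/tau_i)) refit as decays
    n_assoc = 2 if len(durations) >= 8 else 1
    assoc = fit_exponentials_xy(durations, tau_ws, n_assoc,
                                min_points_per_component=4)
    y0 = assoc.i_ss + sum(a for a, _ in assoc.components)
    components = [(-a, tau) for a, tau in assoc.components]
    rising = [(a, tau) for a, tau in components if a > 1e-12]
    if rising:
        tau_fast = min(tau for _, tau in rising)
    else:
        tau_fast = math.nan
    return TailCourse(durations_ms=durations, tau_w_ms=tau_ws,
                      association_y0=float(y0),
                      association_components=components,
                      tau_fast_assoc_ms=float(tau_fast),
                      decompositions=[decomps[i] for i in order])
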