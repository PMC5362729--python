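"""Intrinsic excitability: spike detection, FI-curve model, passive measures.

The firing-rate vs injected-current (FI) relation is parameterized by a
piecewise model: linear from F0 at zero current up to F0 + F1 at the
breakpoint I_break, then a saturating exponential of dynamic range F2
and current constant I_rate,

    F(I <= I_break) = F0 + I·F1/I_break
    F(I >  I_break) = F2·(1 − exp(−(I − I_break)/I_rate)) + (F0 + F1),

so the maximal rate is F0 + F1 + F2 and the rate reaches 63% (1 − 1/e)
of F2 above the breakpoint at I = I_break + I_rate.  Fitting is by
constrained least squares (SLSQP with non-negativity bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from lspsmap.trace import Trace, InsufficientDataError, DegenerateFitError

__all__ = [
    "FIFit",
    "IntrinsicProfile",
    "InvalidSpikeError",
    "eval_fi",
    "fit_fi",
    "max_rate",
    "detect_spikes",
    "input_resistance",
    "membrane_tau",
    "adaptation_ratio",
    "ap_half_width",
    "classify_discharge",
]


class InvalidSpikeError(ValueError):
    """Raised when a waveform does not qualify as an action potential."""


@dataclass
class FIFit:
    """Parameters of the piecewise FI model.

    F0: rate at zero current (sp/s); F1: rate increment at the breakpoint;
    F2: supra-breakpoint dynamic range; I_break: breakpoint current (pA);
    I_rate: exponential current constant (pA).
    """

    F0: float
    F1: float
    F2: float
    I_break: float
    I_rate: float

    def __post_init__(self):
        for name in ("F0", "F1", "F2", "I_break", "I_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.I_rate == 0:
            raise ValueError("I_rate must be positive")


@dataclass
class IntrinsicProfile:
    """Summary of one cell's intrinsic measures."""

    V_rest: float  # mV
    R_in: float  # MΩ
    tau_m: float  # ms
    adaptation_ratio: float | None
    ap_half_width: float  # ms
    max_rate: float  # sp/s
    discharge_class: str | None


# ---------------------------------------------------------------------------
# FI model

def eval_fi(fit: FIFit, I):
    """Firing rate (sp/s) at injected current(s) I (pA), per the FI model."""
    I = np.asarray(I, dtype=float)
    slope = fit.F1 / fit.I_break if fit.I_break > 0 else 0.0
    lower = fit.F0 + I * slope
    expo = np.clip(-(I - fit.I_break) / fit.I_rate, None, 50.0)
    upper = fit.F2 * (1.0 - np.exp(expo)) + fit.F0 + fit.F1
    out = np.where(I <= fit.I_break, lower, upper)
    return float(out) if out.ndim == 0 else out


def max_rate(fit: FIFit) -> float:
    """Saturating firing rate F0 + F1 + F2 (sp/s)."""
    return fit.F0 + fit.F1 + fit.F2


def fit_fi(points, tol: float = 1e-8) -> FIFit:
    """Constrained least-squares fit of the FI model.

    ``points`` is a pair (currents pA, rates sp/s) or an iterable of
    (I, rate) tuples; needs >= 5 points spanning sub- and suprathreshold
    currents.  SLSQP with all parameters bounded >= 0.  Because the SSE
    surface is multimodal in the breakpoint, the optimizer is started
    from a deterministic grid of candidate breakpoints (the observed
    currents up to 60% of the range, plus the smallest firing current),
    each with data-informed initial values, and the best solution kept.
    """
    I, F = _as_points(points)
    if I.size < 5:
        raise InsufficientDataError("need at least 5 FI points")
    if np.all(F <= 0):
        raise DegenerateFitError(
            "all rates are zero; FI model is unconstrained",
            fit=FIFit(0.0, 0.0, 0.0, float(I.max()), max(float(I.max()), 1.0)),
        )

    def residuals(p):
        f = FIFit.__new__(FIFit)
        f.F0, f.F1, f.F2, f.I_break, f.I_rate = p
        return float(np.sum((eval_fi(f, I) - F) ** 2))

    firing = I[F > 0]
    i_break0 = float(firing.min()) if firing.size else float(I.max())
    i_max = float(I.max())
    bounds = [(0, None), (0, None), (0, None), (0, i_max), (1e-3, None)]
    # the SSE surface is multimodal in the breakpoint; start SLSQP from a
    # deterministic grid of candidate breakpoints with data-informed
    # initial values for the remaining parameters, and keep the best
    starts = {round(i_break0, 6)}
    starts.update(round(float(v), 6) for v in I
                  if 0 < v <= 0.6 * i_max)
    best = None
    for ib in sorted(starts):
        below = I <= ib + 1e-9
        if below.sum() >= 2:
            slope, f0_init = np.polyfit(I[below], F[below], 1)
            f0_init = max(f0_init, 0.0)
            f1_init = max(slope, 0.0) * ib
        else:
            f0_init = max(float(F[np.argmin(np.abs(I))]), 0.0)
            f1_init = 1.0
        f2_init = max(float(F.max()) - f0_init - f1_init, 1.0)
        x0 = [f0_init, f1_init, f2_init, ib, max((i_max - ib) / 3.0, 1.0)]
        res = optimize.minimize(residuals, x0, method="SLSQP", bounds=bounds,
                                options={"ftol": tol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    p = best.x
    return FIFit(F0=float(p[0]), F1=float(p[1]), F2=float(p[2]),
                 I_break=float(p[3]), I_rate=float(p[4]))


def _as_points(points):
    if isinstance(points, tuple) and len(points) == 2:
        I, F = points
    else:
        arr = np.asarray(list(points), dtype=float)
        I, F = arr[:, 0], arr[:, 1]
    I = np.asarray(I, dtype=float)
    F = np.asarray(F, dtype=float)
    if I.shape != F.shape or not (np.all(np.isfinite(I)) and np.all(np.isfinite(F))):
        raise ValueError("currents and rates must be finite and congruent")
    order = np.argsort(I)
    return I[order], F[order]


# ---------------------------------------------------------------------------
# spike-train measures

def detect_spikes(voltage: Trace, dvdt_threshold: float = 20.0,
                  refractory_ms: float = 2.0, peak_window_ms: float = 5.0):
    """Action-potential times (ms) by upward dV/dt threshold crossing.

    A crossing counts only if the voltage exceeds 0 mV within
    ``peak_window_ms`` after it; crossings within ``refractory_ms`` of the
    previous spike are ignored.  ``dvdt_threshold`` is in V/s.
    """
    v = voltage.samples
    dt_ms = voltage.sample_interval * 1e3
    dvdt = np.diff(v) / dt_ms  # mV/ms == V/s
    crossing = np.flatnonzero((dvdt[1:] >= dvdt_threshold) & (dvdt[:-1] < dvdt_threshold)) + 1
    times = []
    last = -np.inf
    win = max(1, int(round(peak_window_ms / dt_ms)))
    for i in crossing:
        t = voltage.t0_ms + i * dt_ms
        if t - last < refractory_ms:
            continue
        if v[i:i + win].max() <= 0.0:
            continue
        times.append(t)
        last = t
    return np.asarray(times)


def input_resistance(iv_points, v_rest=None) -> float:
    """Slope of the IV curve between rest and 20 mV below rest, in MΩ.

    ``iv_points`` is an iterable of (I pA, steady-state V mV).  ``v_rest``
    defaults to the voltage at the smallest |I| (the resting point).
    """
    pts = np.asarray(list(iv_points), dtype=float).reshape(-1, 2)
    if v_rest is None:
        v_rest = pts[np.argmin(np.abs(pts[:, 0])), 1]
    sel = (pts[:, 1] >= v_rest - 20.0) & (pts[:, 1] <= v_rest + 1e-9)
    if sel.sum() < 2:
        raise InsufficientDataError(
            "need >= 2 IV points with V between rest and 20 mV below rest")
    slope = np.polyfit(pts[sel, 0], pts[sel, 1], 1)[0]  # mV/pA = GΩ
    return float(slope * 1000.0)


def membrane_tau(traces, v_rest: float, fit_ms: float = 100.0,
                 settle_range=(3.0, 20.0)) -> float:
    """Mean membrane time constant (ms) from hyperpolarizing step responses.

    Each trace is a voltage response starting at the step onset.  Only
    responses settling 3–20 mV below rest qualify; each is fitted with a
    single exponential over its first ``fit_ms`` ms and the mean τ is
    returned.
    """
    taus = []
    for tr in traces:
        v = tr.samples
        n_tail = max(1, v.size // 10)
        settle = v_rest - float(np.mean(v[-n_tail:]))
        if not settle_range[0] <= settle <= settle_range[1]:
            continue
        dt_ms = tr.sample_interval * 1e3
        n = min(v.size, int(round(fit_ms / dt_ms)))
        t = np.arange(n) * dt_ms
        y = v[:n]

        def model(t, v_ss, dv, tau):
            return v_ss + dv * np.exp(-t / tau)

        p0 = (y[-1], y[0] - y[-1], 15.0)
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=5000)
        taus.append(abs(popt[2]))
    if not taus:
        raise InsufficientDataError("no step settled 3-20 mV below rest")
    return float(np.mean(taus))


def adaptation_ratio(spike_times, step_duration: float,
                     max_mean_rate: float = 50.0):
    """Mean of the last two interspike intervals over the first interval.

    ``spike_times`` in ms, ``step_duration`` in s.  Returns None (not
    applicable) for trains with fewer than 4 spikes or mean rate at or
    above ``max_mean_rate`` Hz.  1 means no adaptation; > 1 a slowing.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size < 4:
        return None
    if st.size / step_duration >= max_mean_rate:
        return None
    isis = np.diff(st)
    return float(np.mean(isis[-2:]) / isis[0])


def ap_half_width(voltage: Trace, spike_time: float,
                  dvdt_threshold: float = 20.0,
                  search_ms: float = 5.0) -> float:
    """Action-potential width (ms) at half-height.

    Half-height is midway between the spike threshold voltage (at the
    upward dV/dt crossing nearest ``spike_time``) and the peak; the two
    half-height crossings are located by linear interpolation.
    """
    v = voltage.samples
    dt_ms = voltage.sample_interval * 1e3
    i_spike = int(round((spike_time - voltage.t0_ms) / dt_ms))
    i_spike = int(np.clip(i_spike, 1, v.size - 2))
    win = max(2, int(round(search_ms / dt_ms)))
    seg = v[i_spike:min(i_spike + win, v.size)]
    i_peak = i_spike + int(np.argmax(seg))
    v_peak = v[i_peak]
    if v_peak <= 0.0:
        raise InvalidSpikeError("peak does not exceed 0 mV")
    # threshold voltage: dV/dt crossing at/before the nominal spike time
    dvdt = np.diff(v) / dt_ms
    below = np.flatnonzero(dvdt[:i_peak] < dvdt_threshold)
    i_thr = below[-1] + 1 if below.size else i_spike
    v_thr = v[i_thr]
    v_half = 0.5 * (v_thr + v_peak)
    i_up = _cross_time(v, i_peak, v_half, direction=-1)
    i_down = _cross_time(v, i_peak, v_half, direction=+1)
    return float((i_down - i_up) * dt_ms)


def _cross_time(v, i_peak, level, direction):
    """Fractional index where v crosses `level`, walking from the peak."""
    i = i_peak
    while 0 < i < v.size - 1 and v[i] > level:
        i += direction
    a, b = (i, i - direction) if direction < 0 else (i - direction, i)
    if v[b] == v[a]:
        return float(i)
    frac = (level - v[a]) / (v[b] - v[a])
    return a + frac * (b - a)


def classify_discharge(spike_times, step_duration: float,
                       half_width: float | None = None,
                       cohort_median_half_width: float | None = None):
    """Rule-based discharge-pattern label for one suprathreshold step.

    Returns one of "fast-spiking", "adapting", "stuttering",
    "delayed-onset", or None when no spikes are present.  Rules (an
    adaptation of published interneuron classification schemes, in
    priority order): first-spike latency beyond 50% of the step →
    delayed-onset; ISI coefficient of variation > 1 with silent gaps
    (an ISI over 5× the median) → stuttering; adaptation ratio >= 1.3 →
    adapting; otherwise fast-spiking (half-width below 1.5× the cohort
    median, when supplied, is required).
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size == 0:
        return None
    step_ms = step_duration * 1e3
    if st[0] > 0.5 * step_ms:
        return "delayed-onset"
    if st.size >= 3:
        isis = np.diff(st)
        cv = isis.std() / isis.mean() if isis.mean() > 0 else 0.0
        if cv > 1.0 and isis.max() > 5.0 * np.median(isis):
            return "stuttering"
    ratio = adaptation_ratio(st, step_duration, max_mean_rate=math.inf)
    if ratio is not None and ratio >= 1.3:
        return "adapting"
    if (half_width is not None and cohort_median_half_width is not None
            and half_width >= 1.5 * cohort_median_half_width):
        return "adapting"
    return "fast-spiking"
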