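"""Predictive duty-cycle temperature controller.

The controlled parameter is the sonication duty cycle ``delta``.  Every
dwell interval the controller estimates the asymptotic temperature
elevation ``T_inf`` that the current duty cycle would eventually reach
(mono-exponential extrapolation from a sliding observation window) and
applies the multiplicative master update

    delta_{n+1} = clamp(min(delta_n * T_target / T_inf, 1), delta_range)

which has its fixed point exactly where the projected asymptote matches
the prescribed elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ControllerConfig",
    "AsymptoteEstimate",
    "PulsePattern",
    "estimate_asymptote",
    "update_duty_cycle",
    "pulse_schedule",
    "energy_delivered",
    "DutyCycleController",
    "FirstOrderPlant",
    "run_on_plant",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Controller settings (defaults follow the hyperthermia protocol)."""

    target_elevation_c: float = 6.0
    delta0: float = 0.3                     # geometric mean of the range limits
    delta_min: float = 0.1
    delta_max: float = 0.9
    dwell_time_s: float = 64.0
    observation_window_s: float = 32.0
    activation_threshold_c: float = 1.5
    pulse_period_s: float = 0.5
    thermometry_interval_s: float = 1.6
    acoustic_power_w: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_min < self.delta_max <= 1.0:
            raise ValueError("require 0 < delta_min < delta_max <= 1")
        if not self.delta_min <= self.delta0 <= self.delta_max:
            raise ValueError("delta0 must lie inside the effective range")
        if self.observation_window_s > self.dwell_time_s:
            raise ValueError("observation window cannot exceed the dwell time")


@dataclass
class AsymptoteEstimate:
    """Result of the mono-exponential projection."""

    t_inf_c: float
    tau_s: float | None          # None for a flat (plateau) window
    flagged: bool = False        # fit degenerate / at parameter bounds
    unphysical: bool = False     # cooling window projecting upward
    method: str = "exponential"


def _moving_average(x: np.ndarray, width: int = 3) -> np.ndarray:
    if width <= 1 or x.size < width:
        return x.astype(float)
    kernel = np.ones(width) / width
    sm = np.convolve(x, kernel, mode="same")
    # fix edge bias of the 'same' convolution
    for i in range(width // 2):
        sm[i] = x[: i + width // 2 + 1].mean()
        sm[-(i + 1)] = x[-(i + width // 2 + 1):].mean()
    return sm


def estimate_asymptote(times_s, temps_c, *, anchor: tuple[float, float] | None = None,
                       tau_bounds_s: tuple[float, float] = (5.0, 1500.0),
                       t_inf_bounds_c: tuple[float, float] = (-10.0, 40.0),
                       plateau_slope_c_s: float = 0.004,
                       smooth_width: int = 3) -> AsymptoteEstimate:
    """Project the asymptote of a mono-exponential temperature rise.

    Parameters
    ----------
    times_s, temps_c:
        Observation window samples (>= 10 required).
    anchor:
        Optional known past state ``(t_a, T_a)`` through which the
        exponential is constrained to pass -- in closed loop, the state
        at the previous duty-cycle update.  With an anchor the fit has
        two free parameters (``T_inf``, ``tau``); without it, three.
    plateau_slope_c_s:
        Below this absolute mean slope the window is treated as a
        plateau and ``T_inf`` is simply the window mean.

    Notes
    -----
    The detailed estimator of the original control loop is not public;
    this realization (smoothed window + bounded-``tau`` exponential
    least squares) is one faithful reading of "average slope of the
    curve used to estimate the asymptotic value" and is isolated behind
    this function so alternatives can be swapped.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(temps_c, dtype=float)
    if t.size < 10:
        raise ValueError("observation window needs >= 10 samples")
    y_sm = _moving_average(y, smooth_width)
    slope, _ = np.polyfit(t, y_sm, 1)

    if abs(slope) <= plateau_slope_c_s:
        return AsymptoteEstimate(float(np.mean(y)), None, method="plateau")

    lo, hi = tau_bounds_s
    blo, bhi = t_inf_bounds_c
    tau0 = float(np.clip(3.0 * (t[-1] - t[0]), lo, hi))
    tinf0 = float(np.clip(y_sm[-1] + slope * tau0, blo + 1e-6, bhi - 1e-6))

    try:
        if anchor is not None:
            ta, ya = anchor

            def model(tt, t_inf, tau):
                return t_inf + (ya - t_inf) * np.exp(-(tt - ta) / tau)

            popt, _ = curve_fit(model, t, y, p0=[tinf0, tau0],
                                bounds=([blo, lo], [bhi, hi]), maxfev=2000)
            t_inf, tau = popt
        else:
            def model(tt, t_inf, tau, y0):
                return t_inf + (y0 - t_inf) * np.exp(-(tt - t[0]) / tau)

            popt, _ = curve_fit(model, t, y, p0=[tinf0, tau0, y_sm[0]],
                                bounds=([blo, lo, blo], [bhi, hi, bhi]),
                                maxfev=2000)
            t_inf, tau = popt[0], popt[1]
    except RuntimeError:
        # fall back to a straight slope projection over one time constant
        return AsymptoteEstimate(tinf0, tau0, flagged=True, method="slope")

    if tau >= hi * 0.99:
        # runaway tau degenerates into a linear extrapolation over many
        # time constants; project conservatively over two windows instead
        fallback_tau = 2.0 * (t[-1] - t[0])
        t_inf = float(y_sm[-1] + slope * fallback_tau)
        return AsymptoteEstimate(t_inf, fallback_tau, flagged=True,
                                 method="slope")
    unphysical = bool(slope < 0 and t_inf > np.max(y_sm))
    return AsymptoteEstimate(float(t_inf), float(tau),
                             flagged=bool(tau <= lo * 1.01 or unphysical),
                             unphysical=unphysical)


def update_duty_cycle(delta_n: float, t_inf_c: float,
                      cfg: ControllerConfig) -> tuple[float, bool]:
    """Master update.  Returns ``(delta_{n+1}, held)``.

    A non-positive asymptote estimate holds the current duty cycle and
    flags the update.
    """
    if t_inf_c <= 0.0:
        return delta_n, True
    raw = min(delta_n * cfg.target_elevation_c / t_inf_c, 1.0)
    return float(np.clip(raw, cfg.delta_min, cfg.delta_max)), False


@dataclass(frozen=True)
class PulsePattern:
    """On/off pattern of one pulse period."""

    duty: float
    period_s: float

    @property
    def on_s(self) -> float:
        return self.duty * self.period_s

    @property
    def off_s(self) -> float:
        return (1.0 - self.duty) * self.period_s

    def average_power_w(self, acoustic_power_w: float) -> float:
        return self.duty * acoustic_power_w

    def sample(self, resolution_s: float) -> np.ndarray:
        """Boolean emission pattern over one period."""
        n = max(1, int(round(self.period_s / resolution_s)))
        tt = (np.arange(n) + 0.5) * (self.period_s / n)
        return tt <= self.on_s


def pulse_schedule(delta: float, pulse_period_s: float = 0.5) -> PulsePattern:
    """Each period: ON for ``period * delta``, OFF for the rest."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("duty cycle must be in [0, 1]")
    return PulsePattern(duty=float(delta), period_s=float(pulse_period_s))


def energy_delivered(delta: float, acoustic_power_w: float,
                     interval_s: float) -> float:
    """Energy per thermometry frame, ``E = delta * P * dt`` (J)."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("duty cycle must be in [0, 1]")
    if acoustic_power_w < 0:
        raise ValueError("acoustic power must be >= 0")
    return float(delta * acoustic_power_w * interval_s)


class DutyCycleController:
    """Stateful closed-loop wrapper around the estimator and the update.

    Feed one ROI temperature sample per thermometry frame through
    :meth:`observe`; read the duty cycle to apply from ``delta``.  The
    controller stays at ``delta0`` until the elevation crosses the
    activation threshold; the first update happens one dwell time after
    activation and the observation window restarts at every update (the
    transient right after a duty-cycle change would otherwise
    contaminate the projection).
    """

    def __init__(self, cfg: ControllerConfig):
        self.cfg = cfg
        self.delta = cfg.delta0
        self.activated = False
        self.t_activated: float | None = None
        self._t_next_update: float | None = None
        self._window: list[tuple[float, float]] = []
        self._anchor: tuple[float, float] | None = None
        self.history: list[dict] = []
        self.cumulative_energy_j = 0.0

    def _smoothed_current(self) -> float:
        tail = [v for _, v in self._window[-3:]]
        return float(np.mean(tail)) if tail else 0.0

    def observe(self, t_s: float, temp_c: float) -> float:
        """Ingest one sample, maybe update delta; returns delta to apply."""
        self.cumulative_energy_j += energy_delivered(
            self.delta, self.cfg.acoustic_power_w, self.cfg.thermometry_interval_s)
        self._window.append((float(t_s), float(temp_c)))

        if not self.activated:
            if temp_c >= self.cfg.activation_threshold_c:
                self.activated = True
                self.t_activated = float(t_s)
                self._t_next_update = t_s + self.cfg.dwell_time_s
                self._anchor = (float(t_s), self._smoothed_current())
                self._window = [(float(t_s), float(temp_c))]
            return self.delta

        if t_s + 1e-9 >= self._t_next_update:
            self._update(t_s)
        return self.delta

    def _update(self, t_s: float) -> None:
        t0 = t_s - self.cfg.observation_window_s
        win = [(tt, vv) for tt, vv in self._window if tt >= t0 - 1e-9]
        if len(win) < 10:
            return
        tw = np.array([w[0] for w in win])
        vw = np.array([w[1] for w in win])
        est = estimate_asymptote(tw, vw, anchor=self._anchor)
        if est.unphysical:
            new_delta, held = self.delta, True
        else:
            new_delta, held = update_duty_cycle(self.delta, est.t_inf_c, self.cfg)
        self.history.append({
            "t_s": float(t_s), "delta": float(new_delta),
            "t_inf_c": float(est.t_inf_c),
            "tau_s": est.tau_s, "held": held, "flagged": est.flagged,
        })
        self.delta = new_delta
        self._anchor = (float(t_s), self._smoothed_current())
        self._window = []
        self._t_next_update = t_s + self.cfg.dwell_time_s


class FirstOrderPlant:
    """Analytic test plant: ``dT/dt = (K * delta - T) / tau``."""

    def __init__(self, gain_c: float, tau_s: float, temp_c: float = 0.0):
        self.gain_c = gain_c
        self.tau_s = tau_s
        self.temp_c = temp_c

    def advance(self, delta: float, dt_s: float) -> float:
        t_inf = self.gain_c * delta
        self.temp_c = t_inf + (self.temp_c - t_inf) * np.exp(-dt_s / self.tau_s)
        return self.temp_c


def run_on_plant(plant: FirstOrderPlant, cfg: ControllerConfig,
                 duration_s: float, *, noise_std_c: float = 0.0,
                 rng: np.random.Generator | None = None) -> "pd.DataFrame":
    """Closed loop against an analytic plant (controller unit-test mode)."""
    import pandas as pd

    rng = rng or np.random.default_rng(0)
    ctl = DutyCycleController(cfg)
    dt = cfg.thermometry_interval_s
    rows = []
    t = 0.0
    while t < duration_s:
        temp = plant.advance(ctl.delta, dt)
        t += dt
        measured = temp + (rng.normal(0.0, noise_std_c) if noise_std_c else 0.0)
        delta = ctl.observe(t, measured)
        rows.append({"t_s": t, "T_c": temp, "T_meas_c": measured, "delta": delta,
                     "E_j": ctl.cumulative_energy_j})
    return pd.DataFrame(rows)
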