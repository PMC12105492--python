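"""Kinetic feature extraction for propagating stress-signal waves.

The field's working definitions, applied throughout this module:

* **baseline fluctuation** — spread of the pre-stimulus signal; here the
  standard deviation of the linearly detrended pre-stimulus window (a
  robust scaled-MAD alternative is available), floored at a tiny ε so a
  perfectly flat baseline still yields a usable threshold.
* **take-off point** — first time after the stimulus at which the signal
  departs from the baseline mean by at least k× (default 5×) the baseline
  fluctuation, sustained for a short hold to reject single-sample spikes.
* **delay** — take-off time minus stimulus time.
* **amplitude** — largest |signal − baseline mean| in the post-stimulus
  analysis window.  Membrane-potential traces deflect negative on
  depolarisation; the magnitude is used so amplitudes are always positive.
* **rise time** — time from take-off to the first crossing of 63.2%
  (1 − 1/e) of the amplitude, with sub-sample linear interpolation.
* **propagation velocity** — sensor separation divided by the difference
  of the two take-off times.

Amplitude and velocity decay exponentially with travel distance, and rise
time shortens with amplitude down to a kinetic floor; the fits for both
regularities live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateInputError,
    DomainError,
    FitConvergenceError,
    InfiniteVelocityError,
    NoWaveDetected,
    SignWarning,
)

__all__ = [
    "Trace",
    "BaselineStats",
    "WaveFeatures",
    "DecayFit",
    "RiseTimeFit",
    "baseline_fluctuation",
    "detect_takeoff",
    "wave_features",
    "pair_velocity",
    "fit_exponential_decay",
    "fit_risetime_floor",
]

#: Fluctuation floor (trace units) so flat baselines keep a finite threshold.
FLUCTUATION_EPS = 1e-12


@dataclass
class Trace:
    """One sensor channel: times (s, strictly increasing), values, stem
    position (cm, signed: positive = downstream of the stimulus) and a kind
    label (``h2o2 | vp | cation | flow``)."""

    times: np.ndarray
    values: np.ndarray
    position: float | None = None
    kind: str = ""
    channel: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise DomainError("times and values must be 1D arrays of equal length")
        if self.times.size < 2:
            raise DomainError(f"a trace needs >= 2 samples, got {self.times.size}")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("values must all be finite")

    @property
    def dt_median(self) -> float:
        return float(np.median(np.diff(self.times)))

    def window(self, t0: float, t1: float) -> np.ndarray:
        return (self.times >= t0) & (self.times <= t1)


@dataclass
class BaselineStats:
    """Pre-stimulus baseline summary: the window it came from, the mean
    level, and the fluctuation (detrended spread, floored at ε)."""

    window: tuple[float, float]
    mean: float
    fluctuation: float

    def __post_init__(self) -> None:
        if self.fluctuation < FLUCTUATION_EPS:
            self.fluctuation = FLUCTUATION_EPS


@dataclass
class WaveFeatures:
    """Per-trace kinetic summary (see module docstring for definitions)."""

    takeoff_time: float
    delay: float
    amplitude: float
    rise_time: float
    position: float | None = None
    kind: str = ""

    def to_dict(self) -> dict:
        return {
            "takeoff_time_s": self.takeoff_time,
            "delay_s": self.delay,
            "amplitude": self.amplitude,
            "rise_time_s": self.rise_time,
            "position_cm": self.position,
            "kind": self.kind,
        }


@dataclass
class DecayFit:
    """Exponential distance decay y = y0 · exp(−x / decay_constant).

    ``decaying`` is False when the series does not decay (flat → infinite
    constant; increasing → negative constant, flagged, kept for diagnosis).
    """

    y0: float
    decay_constant: float
    rms: float
    decaying: bool = True

    def to_dict(self) -> dict:
        return {
            "y0": self.y0,
            "decay_constant_cm": self.decay_constant,
            "rms": self.rms,
            "decaying": self.decaying,
        }


@dataclass
class RiseTimeFit:
    """Rise time vs amplitude: rise = floor + prefactor · exp(−A / scale).

    ``floor`` is the extrapolated kinetic limit — the shortest rise time
    the generating process can produce at large amplitude.
    """

    floor: float
    scale: float
    prefactor: float
    rms: float = 0.0

    def to_dict(self) -> dict:
        return {
            "floor_s": self.floor,
            "scale": self.scale,
            "prefactor_s": self.prefactor,
            "rms": self.rms,
        }


def baseline_fluctuation(
    trace: Trace,
    window: tuple[float, float],
    method: str = "std",
    detrend: bool = True,
    eps: float = FLUCTUATION_EPS,
) -> BaselineStats:
    """Estimate the baseline level and fluctuation in a pre-stimulus window.

    ``method='std'`` uses the standard deviation of the (optionally
    linearly detrended) window; ``method='mad'`` uses the scaled median
    absolute deviation (1.4826·MAD), robust to outliers.  The mean is taken
    on the raw (un-detrended) values.

    Raises :class:`DegenerateInputError` for windows with < 10 samples.
    """
    t0, t1 = window
    mask = trace.window(t0, t1)
    if mask.sum() < 10:
        raise DegenerateInputError(
            f"baseline window [{t0}, {t1}] holds {int(mask.sum())} samples; need >= 10"
        )
    tw = trace.times[mask]
    vw = trace.values[mask]
    resid = vw - np.polyval(np.polyfit(tw, vw, 1), tw) if detrend else vw - vw.mean()
    if method == "std":
        fluct = float(np.std(resid))
    elif method == "mad":
        fluct = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    else:
        raise DomainError(f"unknown fluctuation method {method!r}")
    return BaselineStats(window=(float(t0), float(t1)), mean=float(np.mean(vw)),
                         fluctuation=max(fluct, eps))


def _hold_span(trace: Trace, hold: float | None) -> float:
    # default persistence: 3 consecutive samples (2 sampling intervals)
    return 2.0 * trace.dt_median if hold is None else float(hold)


def detect_takeoff(
    trace: Trace,
    baseline: BaselineStats,
    stimulus_time: float,
    k: float = 5.0,
    hold: float | None = None,
) -> float | None:
    """Find the take-off point: earliest sample at or after the stimulus
    where |value − baseline mean| ≥ k·fluctuation holds continuously for
    ``hold`` seconds (default: 3 consecutive samples).

    Returns the sample time of the first sustained crossing, or ``None``
    when no wave is detected.  Take-off is reported sample-aligned — the
    criterion is a level crossing of the recorded samples, so an
    instantaneous step registers at the sample where it lands.
    """
    times, values = trace.times, trace.values
    if not (times[0] <= stimulus_time <= times[-1]):
        raise DomainError(
            f"stimulus_time {stimulus_time} outside trace span [{times[0]}, {times[-1]}]"
        )
    hold_s = _hold_span(trace, hold)
    above = np.abs(values - baseline.mean) >= k * baseline.fluctuation
    candidates = np.nonzero(above & (times >= stimulus_time))[0]
    for j in candidates:
        span = (times >= times[j]) & (times <= times[j] + hold_s)
        if np.all(above[span]):
            return float(times[j])
    return None


def _interp_crossing(times: np.ndarray, mags: np.ndarray, level: float,
                     start_idx: int) -> float:
    """First time |signal| reaches ``level`` at or after ``start_idx``,
    linearly interpolated between samples."""
    for j in range(start_idx, mags.size):
        if mags[j] >= level:
            if j == start_idx or mags[j - 1] >= level:
                return float(times[j])
            f = (level - mags[j - 1]) / (mags[j] - mags[j - 1])
            return float(times[j - 1] + f * (times[j] - times[j - 1]))
    return float(times[-1])


def wave_features(
    trace: Trace,
    stimulus_time: float,
    baseline_window: tuple[float, float] | None = None,
    k: float = 5.0,
    hold: float | None = None,
    analysis_window: float = 300.0,
    method: str = "std",
    min_fluctuation: float = FLUCTUATION_EPS,
) -> WaveFeatures:
    """Extract the full kinetic summary of one trace.

    ``baseline_window`` defaults to everything before the stimulus.
    ``analysis_window`` (s) bounds the post-stimulus span searched for the
    peak, excluding late drift.  ``min_fluctuation`` floors the baseline
    fluctuation — useful for noiseless model output, where the 5× criterion
    would otherwise trigger on numerically tiny leakage.

    Raises :class:`NoWaveDetected` when no sustained 5×-baseline crossing
    exists.
    """
    if baseline_window is None:
        baseline_window = (float(trace.times[0]), float(stimulus_time))
    base = baseline_fluctuation(trace, baseline_window, method=method,
                                eps=min_fluctuation)
    takeoff = detect_takeoff(trace, base, stimulus_time, k=k, hold=hold)
    if takeoff is None:
        raise NoWaveDetected(
            f"no {k}x-baseline crossing after t={stimulus_time} "
            f"(fluctuation={base.fluctuation:g})"
        )
    mags = np.abs(trace.values - base.mean)
    post = trace.window(stimulus_time, stimulus_time + analysis_window)
    amplitude = float(np.max(mags[post]))
    level = 0.632 * amplitude
    start_idx = int(np.searchsorted(trace.times, takeoff))
    t632 = _interp_crossing(trace.times, mags, level, start_idx)
    return WaveFeatures(
        takeoff_time=takeoff,
        delay=float(takeoff - stimulus_time),
        amplitude=amplitude,
        rise_time=max(0.0, t632 - takeoff),
        position=trace.position,
        kind=trace.kind,
    )


def pair_velocity(f_near: WaveFeatures, f_far: WaveFeatures) -> float:
    """Propagation velocity from a sensor pair: |Δposition| / Δtake-off.

    ``f_near`` is the sensor closer to the stimulus, which the wave should
    reach first.  Equal take-off times raise
    :class:`InfiniteVelocityError`; reversed ordering warns and returns a
    negative velocity so the caller can see the sign anomaly.
    """
    if f_near.position is None or f_far.position is None:
        raise DomainError("both features need a position to compute a velocity")
    dx = abs(f_far.position - f_near.position)
    if dx == 0:
        raise DomainError("sensor positions coincide; velocity undefined")
    dt = f_far.takeoff_time - f_near.takeoff_time
    if dt == 0:
        raise InfiniteVelocityError(
            "identical take-off times at both sensors; velocity is unbounded"
        )
    if dt < 0:
        warnings.warn(
            "far sensor took off before the near sensor; returning a negative "
            "velocity", SignWarning, stacklevel=2,
        )
    return dx / dt


def fit_exponential_decay(xs, ys) -> DecayFit:
    """Fit y = y0 · exp(−x/λ) to positive values over distance.

    A log-linear least-squares fit provides the starting point (and is
    exact on noiseless exponential data); a nonlinear refinement pass on
    the original scale follows.  Flat series are flagged non-decaying with
    an infinite constant; increasing series yield a negative constant,
    flagged.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size or xs.size < 3:
        raise DomainError("need >= 3 (x, y) points")
    if np.any(ys <= 0):
        raise DomainError("all y values must be > 0 for an exponential-decay fit")
    slope, logy0 = np.polyfit(xs, np.log(ys), 1)
    if abs(slope) < 1e-12:
        return DecayFit(y0=float(np.exp(logy0)), decay_constant=np.inf,
                        rms=float(np.std(ys)), decaying=False)
    lam = -1.0 / slope
    y0 = float(np.exp(logy0))
    if lam < 0:
        resid = ys - y0 * np.exp(-xs / lam)
        return DecayFit(y0=y0, decay_constant=float(lam),
                        rms=float(np.sqrt(np.mean(resid ** 2))), decaying=False)

    def resid_fn(p):
        return p[0] * np.exp(-xs / p[1]) - ys

    sol = least_squares(resid_fn, x0=[y0, lam], bounds=([0, 1e-9], [np.inf, np.inf]))
    y0_f, lam_f = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return DecayFit(y0=float(y0_f), decay_constant=float(lam_f), rms=rms)


def fit_risetime_floor(amplitudes, rise_times) -> RiseTimeFit:
    """Fit rise = floor + prefactor · exp(−A/scale) with floor bounded ≥ 0.

    The floor is the extrapolated minimum rise time at large amplitude.
    Near-constant rise times short-circuit to floor = mean, prefactor = 0
    (the scale is then unidentifiable and reported as inf).

    Raises :class:`FitConvergenceError` with residual diagnostics when the
    bounded nonlinear fit fails.
    """
    A = np.asarray(amplitudes, dtype=float)
    rt = np.asarray(rise_times, dtype=float)
    if A.size != rt.size or A.size < 4:
        raise DomainError("need >= 4 (amplitude, rise_time) points")
    if np.any(rt <= 0):
        raise DomainError("rise times must be > 0")
    if np.ptp(rt) < 1e-12 * max(1.0, float(np.max(rt))):
        return RiseTimeFit(floor=float(np.mean(rt)), scale=np.inf, prefactor=0.0)

    # initial guesses: floor slightly under the smallest rise time, then a
    # log-linear fit of the remainder gives prefactor and scale
    floor0 = max(0.0, float(np.min(rt)) * 0.9)
    excess = np.clip(rt - floor0, 1e-9 * float(np.max(rt)), None)
    s, b = np.polyfit(A, np.log(excess), 1)
    scale0 = -1.0 / s if s < -1e-12 else float(np.ptp(A)) or 1.0
    pref0 = float(np.exp(b))

    def resid_fn(p):
        floor, pref, scale = p
        return floor + pref * np.exp(-A / scale) - rt

    sol = least_squares(
        resid_fn,
        x0=[floor0, pref0, max(scale0, 1e-6)],
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitConvergenceError(
            f"rise-time floor fit did not converge: {sol.message}; "
            f"residuals={sol.fun!r}"
        )
    floor, pref, scale = sol.x
    return RiseTimeFit(floor=float(floor), scale=float(scale),
                       prefactor=float(pref),
                       rms=float(np.sqrt(np.mean(sol.fun ** 2))))


def features_table(features: Sequence[WaveFeatures]):
    """Tabular summary: one row per trace (position, delay, amplitude,
    rise_time) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position_cm": [f.position for f in features],
            "kind": [f.kind for f in features],
            "takeoff_time_s": [f.takeoff_time for f in features],
            "delay_s": [f.delay for f in features],
            "amplitude": [f.amplitude for f in features],
            "rise_time_s": [f.rise_time for f in features],
        }
    )
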