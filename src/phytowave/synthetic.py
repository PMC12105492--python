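"""Phenomenological generators for fOECT/VP-style recordings.

Real recordings from stem-implanted fibre sensors are not redistributable,
so every pipeline stage is exercised on synthetic tables that reproduce the
statistical structure the analyses assume:

* calibration tables — log-linear concentration response plus Gaussian
  noise;
* transport traces — plug-flow convection fronts (with optional lateral
  smoothing) plus multiplicative sensor noise;
* wave traces — propagating fronts with direction-dependent velocity,
  exponential distance decay of amplitude, amplitude-dependent rise time
  with a kinetic floor, a saturating rise and a slow exponential tail, plus
  additive Gaussian noise.

Wave traces are constructed so that the *5×-noise threshold crossing* falls
exactly at the programmed take-off time (take-off is defined by that
crossing, so this is what "programmed take-off" must mean for the
generator/analyser pair to close).  All generators are deterministic given
their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationPoint
from .errors import DomainError, ZeroDistanceWarning
from .kinetics import Trace
from .transport import FlowScenario, StemGeometry, convection_concentration

__all__ = [
    "WaveScenario",
    "TransportScenario",
    "gen_calibration_dataset",
    "gen_transport_traces",
    "gen_wave_traces",
]

#: Rise phase is truncated this many time constants after onset; beyond it
#: the waveform hands over to the exponential tail.
_RISE_CAP = 6.0
#: Fraction of the nominal amplitude actually attained at the cap.
_PEAK_FRACTION = 1.0 - np.exp(-_RISE_CAP)
#: Threshold multiple used by the take-off rule the traces are built for.
_TAKEOFF_K = 5.0


@dataclass
class WaveScenario:
    """Parameters of a propagating-wave recording session.

    Defaults follow the empirical regularities of wound-induced H₂O₂
    waves: downstream velocity 0.39 cm/s vs counterstream 0.16 cm/s,
    amplitude decay constant 1.53 cm, rise-time floor 9.9 s.  For VP-like
    traces use ``kind='vp'`` with floor 0.72 s and amplitude decay 1.29 cm.

    ``sensor_positions`` are signed distances from the stimulus (cm,
    positive = downstream).  ``amplitude0`` is the extrapolated amplitude
    at the stimulus site in the trace's response units.
    """

    stimulus_time: float = 50.0
    stimulus_position: float = 0.0
    sensor_positions: Sequence[float] = (1.0, 2.0)
    velocity_down: float = 0.39
    velocity_counter: float = 0.16
    amplitude0: float = 1.0
    amplitude_decay: float = 1.53
    risetime_floor: float = 9.9
    risetime_scale: float = 0.3
    risetime_prefactor: float = 30.0
    tail_tau: float = 100.0
    noise_sd: float = 0.001
    sample_rate: float = 10.0
    kind: str = "h2o2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_down <= 0 or self.velocity_counter <= 0:
            raise DomainError("velocities must be > 0")
        if self.amplitude_decay <= 0 or self.tail_tau <= 0:
            raise DomainError("decay constants must be > 0")
        if self.risetime_floor < 0 or self.risetime_scale <= 0 or self.risetime_prefactor < 0:
            raise DomainError("rise-time parameters must be non-negative (scale > 0)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.sample_rate <= 0:
            raise DomainError("sample_rate must be > 0")

    def velocity(self, position: float) -> float:
        """Propagation velocity toward a signed sensor position."""
        return self.velocity_down if position >= self.stimulus_position else self.velocity_counter

    def programmed_features(self, position: float) -> dict:
        """The ground-truth kinetic features a perfect analyser should
        recover at a signed sensor position."""
        d = abs(position - self.stimulus_position)
        v = self.velocity(position)
        amp = self.amplitude0 * np.exp(-d / self.amplitude_decay)
        rise = self.risetime_floor + self.risetime_prefactor * np.exp(
            -amp / self.risetime_scale
        )
        return {
            "takeoff_time": self.stimulus_time + d / v,
            "delay": d / v,
            "amplitude": amp * _PEAK_FRACTION,
            "nominal_amplitude": amp,
            "rise_time": rise,
            "velocity": v,
        }


@dataclass
class TransportScenario:
    """Parameters of a bath-uptake transport recording: constant flow ``u``
    through xylem fraction ``r`` from a bath of ``source_mM``, sensors at
    ``positions`` (cm above the bath), lateral smoothing ``lateral_tau``
    and multiplicative sensor noise of relative SD ``noise_sd``."""

    u: float = 0.35
    r: float = 0.012
    source_mM: float = 75.0
    positions: Sequence[float] = (1.0, 2.0)
    lateral_tau: float = 60.0
    noise_sd: float = 0.02
    seed: int = 0

    def geometry(self) -> StemGeometry:
        return StemGeometry(r=self.r, source_concentration=self.source_mM,
                            positions=self.positions)

    def flow(self) -> FlowScenario:
        return FlowScenario.constant(self.u, self.lateral_tau)


def gen_calibration_dataset(
    sensitivity: float,
    intercept: float,
    reference: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    relative: bool = False,
) -> list[CalibrationPoint]:
    """Synthetic calibration table on the log-linear model
    ``response = intercept + sensitivity·log10(C/reference)`` plus Gaussian
    noise — absolute SD ``noise_sd``, or relative (multiplicative
    ``1 + noise_sd·N(0,1)``) when ``relative=True``.  Reproducible per seed.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0) or reference <= 0:
        raise DomainError("concentrations and reference must be > 0")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    resp = intercept + sensitivity * np.log10(conc / reference)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=conc.size)
        resp = resp * (1.0 + noise_sd * noise) if relative else resp + noise_sd * noise
    return [CalibrationPoint(float(c), float(r)) for c, r in zip(conc, resp)]


def gen_transport_traces(
    scenario: TransportScenario,
    t_grid,
) -> list[Trace]:
    """Forward convection-model traces at each sensor position with
    multiplicative Gaussian noise.  Traces start solute-free; fronts arrive
    at x/(u·r)."""
    t = np.asarray(t_grid, dtype=float)
    geom = scenario.geometry()
    flow = scenario.flow()
    rng = np.random.default_rng(scenario.seed)
    traces = []
    for x in np.asarray(scenario.positions, dtype=float):
        c = convection_concentration(geom, flow, float(x), t)
        if scenario.noise_sd > 0:
            c = c * (1.0 + scenario.noise_sd * rng.normal(size=t.size))
        traces.append(
            Trace(times=t, values=c, position=float(x), kind="cation",
                  channel=f"x{x:g}cm", units="mM")
        )
    return traces


def _wave_time_constant(rise_time: float, crossing_level: float,
                        amplitude: float) -> float:
    """Time constant of the saturating rise such that the interval from the
    crossing of ``crossing_level`` to 63.2% of the attained peak equals
    ``rise_time`` (both closed-form points on 1 − exp(−Δ/τ))."""
    denom = np.log(1.0 - crossing_level / amplitude) - np.log(
        1.0 - 0.632 * _PEAK_FRACTION
    )
    return rise_time / denom


def _wave_template(t: np.ndarray, onset: float, amplitude: float,
                   tau_rise: float, tail_tau: float) -> np.ndarray:
    """Saturating rise 1 − exp(−Δ/τ) capped at ``_RISE_CAP`` time
    constants, then an exponential tail from the attained peak."""
    dt = t - onset
    rise_end = _RISE_CAP * tau_rise
    rising = (dt > 0) & (dt <= rise_end)
    tailing = dt > rise_end
    out = np.zeros_like(t)
    out[rising] = amplitude * (1.0 - np.exp(-dt[rising] / tau_rise))
    peak = amplitude * _PEAK_FRACTION
    out[tailing] = peak * np.exp(-(dt[tailing] - rise_end) / tail_tau)
    return out


def gen_wave_traces(
    scenario: WaveScenario,
    duration: float | None = None,
) -> list[Trace]:
    """Generate one trace per sensor with the scenario's programmed
    kinetics.

    Take-off placement: the waveform is shifted so that it reaches the
    5×``noise_sd`` take-off threshold exactly at
    ``stimulus_time + distance/velocity`` (for a noiseless scenario the
    onset itself sits there).  Membrane-potential traces (``kind='vp'``)
    deflect negative, as depolarisation does against a surface electrode.

    ``duration`` (s) is the recorded span after the stimulus; by default it
    covers the slowest sensor's rise plus one tail time constant.
    """
    positions = np.asarray(scenario.sensor_positions, dtype=float)
    feats = [scenario.programmed_features(float(p)) for p in positions]
    if duration is None:
        latest = max(
            f["delay"] + _RISE_CAP * abs(f["rise_time"]) + scenario.tail_tau
            for f in feats
        )
        duration = latest + 10.0
    dt = 1.0 / scenario.sample_rate
    t = np.arange(0.0, scenario.stimulus_time + duration + dt / 2, dt)
    rng = np.random.default_rng(scenario.seed)
    sign = -1.0 if scenario.kind == "vp" else 1.0
    level = _TAKEOFF_K * scenario.noise_sd
    traces = []
    for p, f in zip(positions, feats):
        if p == scenario.stimulus_position:
            warnings.warn(
                f"sensor at the stimulus position {p} cm: zero travel distance",
                ZeroDistanceWarning, stacklevel=2,
            )
        amp = f["nominal_amplitude"]
        if level >= amp:
            # wave never clears the take-off threshold; emit noise only
            values = scenario.noise_sd * rng.normal(size=t.size)
            traces.append(Trace(times=t, values=sign * values, position=float(p),
                                kind=scenario.kind, channel=f"s{p:+g}cm"))
            continue
        tau_rise = _wave_time_constant(f["rise_time"], level, amp)
        # shift onset so the threshold crossing lands on the programmed take-off
        t_cross_offset = -tau_rise * np.log(1.0 - level / amp)
        onset = f["takeoff_time"] - t_cross_offset
        values = _wave_template(t, onset, amp, tau_rise, scenario.tail_tau)
        if scenario.noise_sd > 0:
            values = values + scenario.noise_sd * rng.normal(size=t.size)
        traces.append(
            Trace(times=t, values=sign * values, position=float(p),
                  kind=scenario.kind, channel=f"s{p:+g}cm")
        )
    return traces
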