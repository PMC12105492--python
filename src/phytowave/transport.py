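"""1D xylem transport models and flow-rate inference.

A rootless stem stands in a solute bath.  Transpiration pulls bath solution
up through the xylem vessels, which occupy an area fraction ``r`` of the
stem cross-section.  A sensor threaded through the stem reads the
*stem-average* solute concentration C(x, t), which — assuming fast lateral
equilibration between xylem and the surrounding tissue — obeys the scalar
conservation law

    ∂C/∂t = −(u · r) ∂C/∂x,          C(0, t) = C_source,  C(x, 0) = 0,

so the concentration front advances at the *effective* speed u·r (the xylem
flow rate u diluted over the whole cross-section).  The equation is solved
exactly by the method of characteristics; an optional first-order
lateral-equilibration constant smooths the plug front into the smooth rises
seen in recordings.

The competing null model is semi-infinite 1D diffusion with a constant
boundary, C = C_source·erfc(x / 2√(Dt)); its characteristic time at
centimetre distances is ~10⁵ s, three orders slower than the convective
front, which is what rules diffusion out as the transport mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfc, erfcinv

from .errors import (
    BoundaryWarning,
    DomainError,
    NonIdentifiableError,
)

__all__ = [
    "StemGeometry",
    "FlowScenario",
    "FlowFit",
    "DiffusionParams",
    "FlowEvent",
    "convection_concentration",
    "front_arrival_time",
    "diffusion_concentration",
    "diffusion_timescale",
    "fit_flow_rate",
    "detect_flow_events",
]

#: Default solute diffusivity for the null model: aqueous K+ at 25 °C (cm²/s).
D_POTASSIUM_25C = 1.96e-5


@dataclass
class StemGeometry:
    """Stem cross-section and sensor layout.

    r : xylem area fraction (0 < r < 1)
    source_concentration : bath concentration at x = 0 (mM)
    positions : sensor positions along the stem (cm, > 0, sorted)
    """

    r: float
    source_concentration: float
    positions: Sequence[float]

    def __post_init__(self) -> None:
        if not (0.0 < self.r < 1.0):
            raise DomainError(f"xylem fraction r must be in (0, 1), got {self.r}")
        if self.source_concentration < 0:
            raise DomainError("source_concentration must be >= 0")
        pos = np.asarray(self.positions, dtype=float)
        if pos.size == 0 or np.any(pos <= 0):
            raise DomainError("sensor positions must be strictly positive")
        if np.any(np.diff(pos) <= 0):
            raise DomainError("sensor positions must be strictly increasing")
        self.positions = pos


@dataclass
class FlowScenario:
    """Piecewise-constant xylem flow u(t) plus a lateral-equilibration lag.

    ``segments`` is a list of ``(t_start, t_end, u)`` triples covering the
    simulation window contiguously; the final segment may end at
    ``numpy.inf``.  ``lateral_tau`` (s) is the first-order time constant
    with which the stem average relaxes toward the xylem concentration
    after the plug front passes; 0 gives a sharp step front.
    """

    segments: Sequence[tuple[float, float, float]]
    lateral_tau: float = 0.0

    def __post_init__(self) -> None:
        segs = [(float(a), float(b), float(u)) for a, b, u in self.segments]
        if not segs:
            raise DomainError("scenario needs at least one flow segment")
        segs.sort(key=lambda s: s[0])
        for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if not np.isclose(b0, a1):
                raise DomainError(f"flow segments must be contiguous: gap at t={b0}..{a1}")
        for a, b, u in segs:
            if b <= a:
                raise DomainError(f"segment end must exceed start, got [{a}, {b}]")
            if u < 0:
                raise DomainError(f"flow rate must be >= 0, got {u}")
        if self.lateral_tau < 0:
            raise DomainError("lateral_tau must be >= 0")
        self.segments = segs

    @classmethod
    def constant(cls, u: float, lateral_tau: float = 0.0) -> "FlowScenario":
        """A single constant-flow segment over [0, ∞)."""
        return cls(segments=[(0.0, np.inf, u)], lateral_tau=lateral_tau)

    def front_position(self, t, r: float):
        """Distance travelled by the stem-average front by time t:
        ∫₀ᵗ u(t')·r dt' (cm).  Vectorised in t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, b, u in self.segments:
            dt = np.clip(np.minimum(t, b) - a, 0.0, None)
            out = out + u * r * dt
        return out

    def front_arrival(self, x: float, r: float) -> float:
        """Earliest t with front_position(t) = x; inf if never reached."""
        if x <= 0:
            raise DomainError(f"x must be > 0, got {x}")
        travelled = 0.0
        for a, b, u in self.segments:
            speed = u * r
            seg_len = speed * (b - a) if np.isfinite(b) else np.inf
            if travelled + seg_len >= x:
                if speed == 0.0:
                    continue
                return a + (x - travelled) / speed
            travelled += seg_len
        return np.inf


@dataclass
class FlowFit:
    """Result of fitting a single constant flow rate to sensor traces.

    u_hat : fitted xylem flow rate (cm/s)
    residual_rms : RMS model–data residual (concentration units)
    tau_effective : per-sensor time for the modelled concentration to reach
        63.2% of the source (s); with ``lateral_tau = 0`` this is the front
        arrival time x/(u·r)
    """

    u_hat: float
    residual_rms: float
    tau_effective: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.u_hat < 0 or self.residual_rms < 0:
            raise DomainError("u_hat and residual_rms must be >= 0")

    @property
    def tau_mean(self) -> float:
        return float(np.mean(self.tau_effective))

    def to_dict(self) -> dict:
        return {
            "u_hat_cm_per_s": self.u_hat,
            "residual_rms": self.residual_rms,
            "tau_effective_s": list(np.asarray(self.tau_effective, dtype=float)),
            "tau_mean_s": self.tau_mean,
        }


@dataclass
class DiffusionParams:
    """Diffusion null model parameter: solute diffusivity D (cm²/s)."""

    D: float = D_POTASSIUM_25C

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise DomainError(f"diffusivity D must be > 0, got {self.D}")


def convection_concentration(
    geometry: StemGeometry,
    scenario: FlowScenario,
    x: float,
    t,
):
    """Stem-average concentration under the convection model (mM).

    Exact method-of-characteristics solution: zero until the front arrives
    at ``t_a = front_arrival(x)``, then either a step to the source value
    (``lateral_tau = 0``) or a first-order relaxation
    ``C = source · (1 − exp(−(t − t_a)/lateral_tau))``.

    Vectorised over ``t``; scalar in ``x``.
    """
    if x <= 0:
        raise DomainError(f"x must be > 0, got {x}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    t_a = scenario.front_arrival(x, geometry.r)
    src = geometry.source_concentration
    elapsed = t_arr - t_a
    if scenario.lateral_tau > 0:
        c = np.where(elapsed > 0, src * (1.0 - np.exp(-np.clip(elapsed, 0, None) / scenario.lateral_tau)), 0.0)
    else:
        c = np.where(elapsed > 0, src, 0.0)
    return float(c) if np.isscalar(t) else c


def front_arrival_time(x: float, u: float, r: float) -> float:
    """Plug-front arrival time x/(u·r) for constant flow (s)."""
    if x <= 0:
        raise DomainError(f"x must be > 0, got {x}")
    if u <= 0 or not (0 < r < 1):
        raise DomainError("need u > 0 and 0 < r < 1 for a finite arrival time")
    return x / (u * r)


def diffusion_concentration(params: DiffusionParams, source: float, x: float, t):
    """Semi-infinite 1D diffusion with constant boundary:
    C(x, t) = source · erfc(x / (2√(D t)))."""
    if x <= 0:
        raise DomainError(f"x must be > 0, got {x}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise DomainError("t must be > 0")
    c = source * erfc(x / (2.0 * np.sqrt(params.D * t_arr)))
    return float(c) if np.isscalar(t) else c


def diffusion_timescale(params: DiffusionParams, x: float, fraction: float) -> float:
    """Time for the diffusion solution to reach ``fraction``·source at x.

    Closed form: erfc(z) = fraction at z = erfcinv(fraction), and
    t = (x / 2z)² / D.  Monotone increasing in x (∝ x²), decreasing in D.
    """
    if not (0.0 < fraction < 1.0):
        raise DomainError(f"fraction must be in (0, 1), got {fraction}")
    if x <= 0:
        raise DomainError(f"x must be > 0, got {x}")
    z = erfcinv(fraction)
    return float((x / (2.0 * z)) ** 2 / params.D)


def fit_flow_rate(
    traces,
    geometry: StemGeometry,
    lateral_tau: float = 0.0,
    u_max: float = 5.0,
) -> FlowFit:
    """Fit a single constant xylem flow rate to concentration traces.

    Parameters
    ----------
    traces:
        Sequence of :class:`~phytowave.kinetics.Trace` objects (or any
        object with ``times``, ``values`` and ``position`` attributes), one
        per sensor; each position must appear in ``geometry.positions``.
    lateral_tau:
        Lateral-equilibration constant used in the forward model (s).
    u_max:
        Upper search bound (cm/s).

    The flow rate minimising the summed squared residual across all sensors
    is found by bounded scalar minimisation (golden-section/Brent).  Raises
    :class:`NonIdentifiableError` when every trace is flat, and warns when
    the optimum sits at the search bound.
    """
    traces = list(traces)
    if not traces:
        raise DomainError("need at least one trace")
    pos_set = set(np.round(np.asarray(geometry.positions, dtype=float), 9))
    for tr in traces:
        if tr.position is None or round(float(tr.position), 9) not in pos_set:
            raise DomainError(
                f"trace position {tr.position} not among geometry positions "
                f"{list(geometry.positions)}"
            )
    spread = max(float(np.ptp(np.asarray(tr.values, dtype=float))) for tr in traces)
    if spread <= 1e-12 * max(1.0, geometry.source_concentration):
        raise NonIdentifiableError(
            "all traces are flat; the flow rate is not identifiable"
        )

    def sse(u: float) -> float:
        scen = FlowScenario.constant(u, lateral_tau)
        total = 0.0
        for tr in traces:
            model = convection_concentration(geometry, scen, float(tr.position), tr.times)
            total += float(np.sum((np.asarray(tr.values, dtype=float) - model) ** 2))
        return total

    res = minimize_scalar(sse, bounds=(0.0, u_max), method="bounded",
                          options={"xatol": 1e-9})
    u_hat = float(res.x)
    if u_hat > 0.999 * u_max or u_hat < 1e-12:
        warnings.warn(
            f"fitted flow rate {u_hat:g} cm/s sits at the search bound [0, {u_max}]",
            BoundaryWarning,
            stacklevel=2,
        )
    n = sum(len(tr.times) for tr in traces)
    rms = float(np.sqrt(sse(u_hat) / n))
    # time for the modelled concentration to reach 63.2% of source at each
    # sensor: front arrival plus one lateral time constant
    tau_eff = np.array(
        [front_arrival_time(float(p), u_hat, geometry.r) + lateral_tau
         for p in np.asarray(geometry.positions, dtype=float)]
    ) if u_hat > 0 else np.full(len(geometry.positions), np.inf)
    return FlowFit(u_hat=u_hat, residual_rms=rms, tau_effective=tau_eff)


@dataclass(frozen=True)
class FlowEvent:
    """A detected transpiration event in an inferred-flow series.

    kind : 'acceleration' (stomatal opening), 'suppression' (closure) or
        'recovery' (return into the baseline band)
    time : event time (s, absolute)
    delay : s since the stimulus, or — for a recovery — since the event it
        recovers from
    """

    kind: str
    time: float
    delay: float


def detect_flow_events(
    flow_series,
    stimulus_time: float,
    k: float = 5.0,
    persistence: float = 10.0,
    baseline_window: tuple[float, float] | None = None,
) -> list[FlowEvent]:
    """Detect stomatal opening/closure events in an inferred u(t) series.

    A departure from the pre-stimulus mean by more than ``k`` times the
    pre-stimulus fluctuation, sustained for ``persistence`` seconds, opens
    an event — classified *acceleration* if the flow rose and *suppression*
    if it fell.  A sustained return inside the band afterwards closes it
    with a *recovery* event whose delay is measured from the opening event.

    ``flow_series`` is a Trace-like object whose values are flow rates
    (cm/s).  Raises :class:`DomainError` when the stimulus lies outside the
    trace span.
    """
    times = np.asarray(flow_series.times, dtype=float)
    values = np.asarray(flow_series.values, dtype=float)
    if not (times[0] <= stimulus_time <= times[-1]):
        raise DomainError(
            f"stimulus_time {stimulus_time} outside trace span "
            f"[{times[0]}, {times[-1]}]"
        )
    if baseline_window is None:
        baseline_window = (times[0], stimulus_time)
    b0, b1 = baseline_window
    base_mask = (times >= b0) & (times <= b1)
    if base_mask.sum() < 2:
        raise DomainError("baseline window holds fewer than 2 samples")
    base_mean = float(np.mean(values[base_mask]))
    fluct = max(float(np.std(values[base_mask])), 1e-12)

    dev = values - base_mean
    outside = np.abs(dev) > k * fluct

    events: list[FlowEvent] = []
    post = times >= stimulus_time
    idx = np.nonzero(post)[0]
    in_event = False
    last_event_time = np.nan
    i = 0
    while i < idx.size:
        j = idx[i]
        if not in_event and outside[j]:
            # require the excursion to persist
            t_end = times[j] + persistence
            span = (times >= times[j]) & (times <= t_end)
            if np.all(outside[span]):
                kind = "acceleration" if dev[j] > 0 else "suppression"
                events.append(FlowEvent(kind, float(times[j]),
                                        float(times[j] - stimulus_time)))
                last_event_time = times[j]
                in_event = True
        elif in_event and not outside[j]:
            t_end = times[j] + persistence
            span = (times >= times[j]) & (times <= t_end)
            if np.all(~outside[span]):
                events.append(FlowEvent("recovery", float(times[j]),
                                        float(times[j] - last_event_time)))
                in_event = False
        i += 1
    return events
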