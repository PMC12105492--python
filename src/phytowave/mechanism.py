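"""Mechanistic 1D simulator of the H₂O₂–VP mutual-reinforcement loop.

The proposed propagation mechanism for wound-induced systemic signals is a
positive feedback between apoplastic H₂O₂ production and membrane
depolarisation, relayed cell-to-cell along the stem:

* RBOHD on the plasma membrane produces apoplastic H₂O₂, activated by
  cytosolic Ca²⁺ (and transiently boosted at the wound site);
* apoplastic H₂O₂ above a threshold opens plasma-membrane Ca²⁺ channels;
* cytosolic Ca²⁺ above a threshold triggers TPC1-mediated release from the
  vacuolar store (Ca²⁺-induced Ca²⁺ release);
* cytosolic Ca²⁺ depolarises the membrane (H⁺-ATPase inhibition and anion
  efflux, lumped into one saturating term) — the variation potential;
* Ca²⁺ passes to neighbouring cells through plasmodesmata (symplastic,
  bidirectional), regenerating the loop in both directions;
* H₂O₂ leaking into the xylem is advected downstream with the
  transpiration stream at speed u and leaks back out ahead of the front,
  so downstream propagation outruns counterstream propagation.

Inhibitor zones reproduce the pharmacology: DPI silences RBOHD
(``rbohd_blocked``), Gd³⁺ blocks the H₂O₂-gated Ca²⁺ channels
(``ca_channel_blocked``); either interrupts the relay, so both waves die
beyond the treated zone.

No rate laws are measured for this loop; the functional forms here (Hill
activation, hard channel thresholds, first-order decays, explicit Euler
with upwind advection) are the package's own, with defaults chosen so the
emergent wave velocities fall in the observed 0.1–0.7 cm/s band.  The
simulator's claims are ordinal — orderings, blockades, asymmetries — never
exact numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationCurve, predict_response
from .errors import DomainError, ExtrapolationWarning, StabilityError
from .kinetics import Trace, WaveFeatures, wave_features
from .errors import NoWaveDetected

__all__ = [
    "CellState",
    "StemLattice",
    "MechanismParams",
    "StressEvent",
    "step",
    "simulate",
    "exogenous_h2o2_response",
    "virtual_sensor",
]


@dataclass
class MechanismParams:
    """Rate constants and thresholds of the feedback loop.

    Units: concentrations μM, times s, lengths cm, membrane potential mV
    (deviation from rest; depolarisation positive internally — traces are
    emitted with the electrode's negative-going convention).

    k_rboh : max RBOHD H₂O₂ production rate (μM/s)
    K_ca : Ca²⁺ half-activation of RBOHD (μM)
    theta_h : apoplastic H₂O₂ threshold gating Ca²⁺ influx (μM)
    g_h : Ca²⁺ influx rate through open H₂O₂-gated channels (μM/s)
    theta_ca : cytosolic Ca²⁺ threshold for TPC1 vacuolar release (μM)
    k_tpc : vacuolar release rate constant above threshold (1/s)
    k_dep : maximal depolarisation (mV); lumped H⁺-ATPase + anion efflux
    K_vm : Ca²⁺ giving half-maximal depolarisation (μM)
    tau_vm : membrane-potential relaxation time (s)
    k_ao : apoplastic antioxidant degradation rate of H₂O₂ (1/s)
    d_pd : plasmodesmal Ca²⁺ exchange coefficient between neighbours (1/s)
    k_xfer : apoplast↔xylem H₂O₂ exchange rate (1/s, symmetric)
    k_ca_rec : cytosolic Ca²⁺ clearance rate (1/s)
    tau_drive : decay time of the wound-site RBOHD boost (s)
    bolus_gain : apoplastic H₂O₂ bolus per unit wound intensity (μM)
    drive_gain : RBOHD stress drive per unit wound intensity
    """

    k_rboh: float = 6.0
    K_ca: float = 1.8
    theta_h: float = 4.0
    g_h: float = 2.0
    theta_ca: float = 1.0
    k_tpc: float = 0.02
    k_dep: float = 40.0
    K_vm: float = 2.0
    tau_vm: float = 0.5
    k_ao: float = 1.0
    d_pd: float = 60.0
    k_xfer: float = 0.3
    k_ca_rec: float = 2.0
    tau_drive: float = 10.0
    bolus_gain: float = 300.0
    drive_gain: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k_rboh", "g_h", "k_tpc", "k_dep", "tau_vm", "k_ao",
                     "d_pd", "k_xfer", "k_ca_rec", "tau_drive",
                     "bolus_gain", "drive_gain"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("K_ca", "theta_h", "theta_ca", "K_vm"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


@dataclass
class CellState:
    """State of a single cell — a scalar view into the lattice, mainly for
    inspection and single-cell tests."""

    h2o2_apo: float = 0.0
    h2o2_xyl: float = 0.0
    ca_cyt: float = 0.0
    ca_vac: float = 10.0
    vm: float = 0.0


@dataclass
class StemLattice:
    """1D chain of cells with a shared xylem compartment.

    Arrays are indexed by cell; cell i sits at ``x = i · dx`` cm.  ``u`` is
    the xylem flow rate (cm/s, toward +x = downstream) and ``r`` the xylem
    area fraction (kept for geometry bookkeeping; the apoplast↔xylem
    exchange rate already absorbs the volume ratio).  Inhibitor flags mark
    DPI (``rbohd_blocked``) and Gd³⁺ (``ca_channel_blocked``) zones.
    """

    h2o2_apo: np.ndarray
    h2o2_xyl: np.ndarray
    ca_cyt: np.ndarray
    ca_vac: np.ndarray
    vm: np.ndarray
    dx: float = 0.1
    u: float = 0.0
    r: float = 0.012
    rbohd_blocked: np.ndarray | None = None
    ca_channel_blocked: np.ndarray | None = None
    stress_drive: np.ndarray | None = None
    ca_vac0: float = 10.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise DomainError("dx must be > 0")
        if self.u < 0:
            raise DomainError("u must be >= 0")
        n = self.h2o2_apo.size
        for name in ("h2o2_xyl", "ca_cyt", "ca_vac", "vm"):
            if getattr(self, name).size != n:
                raise DomainError(f"{name} length mismatch")
        if self.rbohd_blocked is None:
            self.rbohd_blocked = np.zeros(n, dtype=bool)
        if self.ca_channel_blocked is None:
            self.ca_channel_blocked = np.zeros(n, dtype=bool)
        if self.stress_drive is None:
            self.stress_drive = np.zeros(n, dtype=float)

    @property
    def n_cells(self) -> int:
        return int(self.h2o2_apo.size)

    @property
    def length(self) -> float:
        return (self.n_cells - 1) * self.dx

    @classmethod
    def at_rest(cls, length_cm: float = 8.0, dx: float = 0.1, u: float = 0.0,
                r: float = 0.012, ca_vac0: float = 10.0) -> "StemLattice":
        """A quiescent lattice: all species at rest, full vacuolar store."""
        n = int(round(length_cm / dx)) + 1
        zeros = lambda: np.zeros(n, dtype=float)  # noqa: E731
        return cls(h2o2_apo=zeros(), h2o2_xyl=zeros(), ca_cyt=zeros(),
                   ca_vac=np.full(n, float(ca_vac0)), vm=zeros(),
                   dx=dx, u=u, r=r, ca_vac0=float(ca_vac0))

    def cell_index(self, x: float) -> int:
        i = int(round(x / self.dx))
        if not (0 <= i < self.n_cells):
            raise DomainError(
                f"position {x} cm outside lattice [0, {self.length:g}] cm"
            )
        return i

    def mark_zone(self, start_cm: float, end_cm: float, kind: str) -> None:
        """Flag an inhibitor zone: ``kind`` is 'dpi' (RBOHD block) or
        'gd' (Ca²⁺-channel block)."""
        i0, i1 = self.cell_index(start_cm), self.cell_index(end_cm)
        sl = slice(min(i0, i1), max(i0, i1) + 1)
        if kind.lower() == "dpi":
            self.rbohd_blocked[sl] = True
        elif kind.lower() in ("gd", "gd3+"):
            self.ca_channel_blocked[sl] = True
        else:
            raise DomainError(f"unknown inhibitor kind {kind!r}; use 'dpi' or 'gd'")

    def cell(self, i: int) -> CellState:
        return CellState(
            h2o2_apo=float(self.h2o2_apo[i]), h2o2_xyl=float(self.h2o2_xyl[i]),
            ca_cyt=float(self.ca_cyt[i]), ca_vac=float(self.ca_vac[i]),
            vm=float(self.vm[i]),
        )

    def total_h2o2(self) -> float:
        """Summed apoplastic + xylem H₂O₂ over the lattice (μM·cells)."""
        return float(np.sum(self.h2o2_apo) + np.sum(self.h2o2_xyl))


@dataclass(frozen=True)
class StressEvent:
    """A localised stress: at ``time`` (s) and ``position`` (cm), wound
    ``intensity`` ≥ 0 maps linearly to an apoplastic H₂O₂ bolus plus a
    transient RBOHD drive."""

    position: float
    time: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise DomainError("intensity must be >= 0")


def _check_stability(lattice: StemLattice, params: MechanismParams, dt: float) -> None:
    if dt <= 0:
        raise StabilityError("dt must be > 0")
    if lattice.u > 0 and dt * lattice.u / lattice.dx > 1.0:
        raise StabilityError(
            f"CFL bound violated: dt*u/dx = {dt * lattice.u / lattice.dx:.3f} > 1"
        )
    if 2.0 * params.d_pd * dt > 1.0:
        raise StabilityError(
            f"PD-exchange bound violated: 2*d_pd*dt = {2 * params.d_pd * dt:.3f} > 1"
        )
    fastest = max(params.k_ao, params.k_ca_rec, params.k_xfer, params.k_tpc)
    if fastest * dt >= 1.0:
        raise StabilityError(
            f"rate bound violated: dt*max_rate = {fastest * dt:.3f} >= 1"
        )


def step(lattice: StemLattice, params: MechanismParams, dt: float) -> StemLattice:
    """Advance the lattice by one explicit-Euler step of length ``dt`` (s).

    The update, in order: RBOHD production (Hill in Ca²⁺, boosted by the
    decaying stress drive, silenced where DPI-blocked); H₂O₂-gated Ca²⁺
    influx (silenced where Gd³⁺-blocked); TPC1 vacuolar release above the
    Ca²⁺ threshold; plasmodesmal Ca²⁺ exchange with both neighbours
    (reflecting ends); apoplast↔xylem H₂O₂ exchange and upwind advection
    of the xylem pool at speed u (open outflow, clean inflow); first-order
    clearance of every species; membrane potential relaxing toward a
    saturating function of cytosolic Ca²⁺.

    The lattice is updated in place and returned.  Raises
    :class:`StabilityError` when a stability bound is violated or the
    state leaves the physical domain.
    """
    _check_stability(lattice, params, dt)
    apo, xyl = lattice.h2o2_apo, lattice.h2o2_xyl
    ca, vac, vm = lattice.ca_cyt, lattice.ca_vac, lattice.vm
    drive = lattice.stress_drive

    production = (
        params.k_rboh * ca / (ca + params.K_ca) * (1.0 + drive)
    )
    production[lattice.rbohd_blocked] = 0.0
    # wound drive also primes RBOHD directly (stretch activation), letting a
    # wound fire the loop from rest where ca_cyt is still zero
    prime = params.k_rboh * drive / (1.0 + drive)
    prime[lattice.rbohd_blocked] = 0.0

    # graded saturating gates with half-activation at the thresholds.  A
    # binary gate would renormalise the pulse at every cell (constant
    # amplitude); Michaelis gating makes the relay gain maximal at small
    # amplitude and monotonically saturating, so a sub-unity linear gain
    # guarantees a decremental wave with an exponential far-field.
    influx = params.g_h * apo / (apo + params.theta_h)
    influx[lattice.ca_channel_blocked] = 0.0
    release = params.k_tpc * vac * ca / (ca + params.theta_ca)
    # Gd3+ blocks cation channels generally, TPC1 included
    release[lattice.ca_channel_blocked] = 0.0

    lap = np.zeros_like(ca)
    lap[1:-1] = ca[:-2] + ca[2:] - 2.0 * ca[1:-1]
    lap[0] = ca[1] - ca[0]
    lap[-1] = ca[-2] - ca[-1]

    exch = params.k_xfer * (apo - xyl)
    adv = np.zeros_like(xyl)
    if lattice.u > 0:
        adv[1:] = -lattice.u * (xyl[1:] - xyl[:-1]) / lattice.dx
        adv[0] = -lattice.u * xyl[0] / lattice.dx

    d_apo = production + prime - params.k_ao * apo - exch
    d_xyl = exch + adv
    d_ca = influx + release - params.k_ca_rec * ca + params.d_pd * lap
    d_vac = -release
    vm_target = params.k_dep * ca / (ca + params.K_vm)
    d_vm = (vm_target - vm) / params.tau_vm

    apo += dt * d_apo
    xyl += dt * d_xyl
    ca += dt * d_ca
    vac += dt * d_vac
    vm += dt * d_vm
    drive *= np.exp(-dt / params.tau_drive)

    for name, arr in (("h2o2_apo", apo), ("h2o2_xyl", xyl),
                      ("ca_cyt", ca), ("ca_vac", vac)):
        if np.any(np.isnan(arr)) or np.any(arr < -1e-9):
            raise StabilityError(
                f"{name} left the physical domain (NaN or negative); "
                f"reduce dt or rates"
            )
        np.clip(arr, 0.0, None, out=arr)
    lattice.time += dt
    return lattice


def simulate(
    lattice: StemLattice,
    params: MechanismParams,
    events: Sequence[StressEvent],
    t_end: float,
    sensors: Sequence[float],
    dt: float = 0.008,
    record_dt: float = 0.1,
    exo_route: str = "apoplast",
) -> dict[str, list[Trace]]:
    """Run the lattice to ``t_end`` and record H₂O₂ and Vm at the sensors.

    Events inject ``intensity·bolus_gain`` μM of H₂O₂ (apoplastic by
    default; ``exo_route='xylem'`` for infusions through a stem hole) and
    set the local RBOHD stress drive to ``intensity·drive_gain``.

    Returns ``{'h2o2': [...], 'vp': [...]}`` with one trace per sensor.
    The H₂O₂ trace is the apoplast+xylem sum at the sensor cell (what an
    implanted sensor sees); the Vm trace is emitted negative-going, the
    electrode convention for a depolarisation.  Traces are noiseless;
    feed them through :func:`virtual_sensor` for device realism.
    """
    sensors = [float(s) for s in sensors]
    sensor_idx = [lattice.cell_index(s) for s in sensors]
    for ev in events:
        lattice.cell_index(ev.position)  # raises if outside
    pending = sorted(events, key=lambda e: e.time)
    n_rec = int(np.floor(t_end / record_dt)) + 1
    rec_t = np.zeros(n_rec)
    rec_h = np.zeros((n_rec, len(sensors)))
    rec_v = np.zeros((n_rec, len(sensors)))

    k_rec = 0
    n_steps = int(np.ceil(t_end / dt))
    for istep in range(n_steps + 1):
        t = istep * dt
        while pending and pending[0].time <= t + dt / 2:
            ev = pending.pop(0)
            i = lattice.cell_index(ev.position)
            if exo_route == "xylem":
                lattice.h2o2_xyl[i] += params.bolus_gain * ev.intensity
            else:
                lattice.h2o2_apo[i] += params.bolus_gain * ev.intensity
            lattice.stress_drive[i] += params.drive_gain * ev.intensity
        if k_rec < n_rec and t >= k_rec * record_dt - dt / 2:
            rec_t[k_rec] = t
            for j, i in enumerate(sensor_idx):
                rec_h[k_rec, j] = lattice.h2o2_apo[i] + lattice.h2o2_xyl[i]
                rec_v[k_rec, j] = lattice.vm[i]
            k_rec += 1
        if istep < n_steps:
            step(lattice, params, dt)

    out: dict[str, list[Trace]] = {"h2o2": [], "vp": []}
    for j, s in enumerate(sensors):
        out["h2o2"].append(Trace(times=rec_t[:k_rec], values=rec_h[:k_rec, j],
                                 position=s, kind="h2o2",
                                 channel=f"h2o2@{s:g}cm", units="uM"))
        out["vp"].append(Trace(times=rec_t[:k_rec], values=-rec_v[:k_rec, j],
                               position=s, kind="vp",
                               channel=f"vp@{s:g}cm", units="mV"))
    return out


def exogenous_h2o2_response(
    lattice: StemLattice,
    params: MechanismParams,
    dose: float,
    distance: float,
    injection_position: float | None = None,
    t_end: float = 60.0,
    route: str = "xylem",
    min_fluctuation: float = 1e-3,
) -> WaveFeatures | None:
    """VP response to an exogenous H₂O₂ bolus without mechanical stress.

    ``dose`` (μM, added to the xylem pool by default — an infusion through
    a pre-made stem hole) is injected at ``injection_position`` (default:
    lattice midpoint); the VP is read ``distance`` cm downstream of it.
    Returns the VP :class:`WaveFeatures`, or ``None`` when no wave clears
    the take-off threshold (including dose = 0).
    """
    if dose < 0:
        raise DomainError("dose must be >= 0")
    if injection_position is None:
        injection_position = lattice.length / 2.0
    sensor = injection_position + distance
    lattice.cell_index(sensor)
    i = lattice.cell_index(injection_position)
    t0 = 5.0  # quiet pre-injection span for the baseline window
    pre = simulate(lattice, params, [], t0, [sensor], record_dt=0.1)["vp"][0]
    # the dose enters directly: exogenous H2O2 carries no RBOHD stress drive,
    # unlike a wound event
    if route == "xylem":
        lattice.h2o2_xyl[i] += dose
    else:
        lattice.h2o2_apo[i] += dose
    post = simulate(lattice, params, [], t_end - t0, [sensor],
                    record_dt=0.1)["vp"][0]
    full = Trace(
        times=np.concatenate([pre.times, post.times[1:] + t0]),
        values=np.concatenate([pre.values, post.values[1:]]),
        position=pre.position, kind="vp", channel=pre.channel, units="mV",
    )
    try:
        return wave_features(full, stimulus_time=t0,
                             min_fluctuation=min_fluctuation)
    except NoWaveDetected:
        return None


def virtual_sensor(
    concentration_trace: Trace,
    curve: CalibrationCurve,
    device_tau: float = 0.11,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Read a concentration trace through a virtual fOECT.

    The concentration is mapped through the calibration curve, low-passed
    with the device's first-order response (time constant ``device_tau``,
    default the measured 0.11 s), and Gaussian read noise is added
    (deterministic per seed).  ``device_tau = 0`` returns the calibrated
    signal exactly.
    """
    if device_tau < 0:
        raise DomainError("device_tau must be >= 0")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    t = concentration_trace.times
    # the device saturates below its working range; clamp concentrations to
    # the bottom of the curve's fitted span before the log-linear map
    floor = curve.valid_range[0]
    if not (np.isfinite(floor) and floor > 0):
        floor = curve.reference_concentration * 1e-3
    conc = np.clip(concentration_trace.values, floor, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        resp = np.asarray(predict_response(curve, conc), dtype=float)
    if device_tau > 0:
        out = np.empty_like(resp)
        out[0] = resp[0]
        dts = np.diff(t)
        alpha = 1.0 - np.exp(-dts / device_tau)
        for i in range(1, resp.size):
            out[i] = out[i - 1] + alpha[i - 1] * (resp[i] - out[i - 1])
        resp = out
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + noise_sd * rng.normal(size=resp.size)
    return Trace(times=t.copy(), values=resp,
                 position=concentration_trace.position,
                 kind=concentration_trace.kind or "sensor",
                 channel=concentration_trace.channel,
                 units=curve.response_units)
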