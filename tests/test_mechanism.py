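"""Mechanistic lattice simulator: ordinal properties of the H2O2-VP loop.

Feature extraction on noiseless simulator output uses explicit fluctuation
floors (the 5x-baseline rule needs a finite noise scale): 0.005 uM for the
H2O2 traces and 0.02 mV for membrane potential, i.e. detection thresholds
of 0.025 uM and 0.1 mV — roughly the resolution of the recording devices
being emulated.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from phytowave.calibration import CalibrationCurve
from phytowave.errors import DomainError, NoWaveDetected, StabilityError
from phytowave.kinetics import (
    Trace,
    fit_exponential_decay,
    pair_velocity,
    wave_features,
)
from phytowave.mechanism import (
    MechanismParams,
    StemLattice,
    StressEvent,
    exogenous_h2o2_response,
    simulate,
    step,
    virtual_sensor,
)

H_FLOOR, V_FLOOR = 0.005, 0.02
WOUND, STIM_T = 6.0, 5.0


def wound_sim(u=0.0, intensity=1.0, t_end=120.0, zones=(), sensors=(7.0, 8.0),
              record_dt=0.1, length=12.0):
    lat = StemLattice.at_rest(length_cm=length, u=u)
    for z in zones:
        lat.mark_zone(*z)
    return simulate(lat, MechanismParams(),
                    [StressEvent(position=WOUND, time=STIM_T, intensity=intensity)],
                    t_end, list(sensors), record_dt=record_dt)


def feat(trace, kind):
    floor = H_FLOOR if kind == "h2o2" else V_FLOOR
    try:
        return wave_features(trace, STIM_T, min_fluctuation=floor,
                             analysis_window=1000.0)
    except NoWaveDetected:
        return None


def features_by_position(traces, kind):
    return {t.position: feat(t, kind) for t in traces[kind]}


class TestStep:
    def test_rest_is_a_fixed_point(self):
        lat = StemLattice.at_rest(length_cm=4.0)
        traces = simulate(lat, MechanismParams(), [], 20.0, [2.0])
        assert np.max(np.abs(traces["h2o2"][0].values)) == 0.0
        assert np.max(np.abs(traces["vp"][0].values)) == 0.0
        assert float(np.max(lat.ca_cyt)) == 0.0

    def test_single_cell_transient_matches_independent_integrator(self):
        # 3-cell lattice with PD exchange off reduces each cell to the
        # point ODE; compare the explicit-Euler path against solve_ivp on
        # the same right-hand side
        p = MechanismParams(d_pd=0.0, k_xfer=0.3)
        bolus = 30.0

        def rhs(_, y):
            apo, xyl, ca, vac, vm = y
            prod = p.k_rboh * ca / (ca + p.K_ca)
            influx = p.g_h * apo / (apo + p.theta_h)
            release = p.k_tpc * vac * ca / (ca + p.theta_ca)
            exch = p.k_xfer * (apo - xyl)
            vm_target = p.k_dep * ca / (ca + p.K_vm)
            return [
                prod - p.k_ao * apo - exch,
                exch,
                influx + release - p.k_ca_rec * ca,
                -release,
                (vm_target - vm) / p.tau_vm,
            ]

        sol = solve_ivp(rhs, (0.0, 20.0), [bolus, 0.0, 0.0, 10.0, 0.0],
                        rtol=1e-9, atol=1e-12, dense_output=True)
        lat = StemLattice.at_rest(length_cm=0.2)
        lat.h2o2_apo[1] = bolus
        dt = 0.002
        for _ in range(int(20.0 / dt)):
            step(lat, p, dt)
        y = sol.sol(20.0)
        mid = lat.cell(1)
        assert mid.h2o2_apo == pytest.approx(y[0], rel=0.01, abs=1e-6)
        assert mid.ca_cyt == pytest.approx(y[2], rel=0.01, abs=1e-6)
        assert mid.ca_vac == pytest.approx(y[3], rel=0.01)
        assert mid.vm == pytest.approx(y[4], rel=0.01, abs=1e-6)

    def test_bolus_ordering_ca_then_vm_follow_h2o2(self):
        # a single-cell H2O2 bolus first raises Ca, then depolarises;
        # onset order: h2o2 (instant) -> ca -> vm
        p = MechanismParams(d_pd=0.0)
        lat = StemLattice.at_rest(length_cm=0.2)
        lat.h2o2_apo[1] = 30.0
        t_ca = t_vm = None
        dt = 0.002
        for i in range(int(10.0 / dt)):
            step(lat, p, dt)
            if t_ca is None and lat.ca_cyt[1] > 0.05:
                t_ca = lat.time
            if t_vm is None and lat.vm[1] > 1.0:
                t_vm = lat.time
        assert t_ca is not None and t_vm is not None
        assert 0.0 < t_ca < t_vm

    def test_bolus_with_blocked_channels_keeps_vm_at_rest(self):
        p = MechanismParams(d_pd=0.0)
        lat = StemLattice.at_rest(length_cm=0.2)
        lat.ca_channel_blocked[:] = True
        lat.h2o2_apo[1] = 30.0
        for _ in range(2000):
            step(lat, p, 0.005)
        assert float(np.max(lat.vm)) == 0.0
        assert float(np.max(lat.ca_cyt)) == 0.0

    def test_h2o2_mass_conserved_without_sources_or_sinks(self):
        p = MechanismParams(k_rboh=0.0, k_ao=0.0)
        lat = StemLattice.at_rest(length_cm=2.0, u=0.0)
        lat.h2o2_apo[5] = 50.0
        lat.h2o2_xyl[10] = 25.0
        total0 = lat.total_h2o2()
        for _ in range(4000):
            step(lat, p, 0.005)
        assert lat.total_h2o2() == pytest.approx(total0, rel=1e-9)

    def test_stability_guard_names_violated_bound(self):
        lat = StemLattice.at_rest(length_cm=1.0, u=50.0)
        with pytest.raises(StabilityError, match="CFL"):
            step(lat, MechanismParams(), 0.01)
        lat = StemLattice.at_rest(length_cm=1.0)
        with pytest.raises(StabilityError, match="PD-exchange"):
            step(lat, MechanismParams(d_pd=100.0), 0.01)


class TestEmergentProperties:
    def test_distance_decay_of_amplitude_and_velocity(self):
        traces = wound_sim(sensors=(7.0, 8.0, 9.0, 10.0), t_end=120.0)
        for kind in ("h2o2", "vp"):
            fs = features_by_position(traces, kind)
            feats = [fs[7.0 + i] for i in range(4)]
            assert all(f is not None for f in feats)
            amps = [f.amplitude for f in feats]
            assert all(a1 >= a2 for a1, a2 in zip(amps, amps[1:]))
            vels = [pair_velocity(feats[i], feats[i + 1]) for i in range(3)]
            assert all(v1 >= v2 for v1, v2 in zip(vels, vels[1:]))
            for series, xs in ((amps, [1, 2, 3, 4]), (vels, [1.5, 2.5, 3.5])):
                fit = fit_exponential_decay(xs, series)
                assert fit.decaying
                assert fit.rms < 0.10 * np.ptp(series)

    def test_velocities_in_observed_band(self):
        traces = wound_sim(sensors=(7.0, 8.0), t_end=60.0)
        f1, f2 = (features_by_position(traces, "h2o2")[p] for p in (7.0, 8.0))
        assert 0.1 <= pair_velocity(f1, f2) <= 0.7

    def test_direction_symmetric_without_flow(self):
        traces = wound_sim(u=0.0, sensors=(7.0, 8.0, 5.0, 4.0), t_end=90.0)
        for kind in ("h2o2", "vp"):
            fs = features_by_position(traces, kind)
            down = pair_velocity(fs[7.0], fs[8.0])
            counter = pair_velocity(fs[5.0], fs[4.0])
            assert down == pytest.approx(counter, rel=0.05)

    def test_downstream_beats_counterstream_with_flow(self):
        traces = wound_sim(u=0.35, sensors=(7.0, 8.0, 5.0, 4.0), t_end=120.0,
                           record_dt=0.05)
        for kind in ("h2o2", "vp"):
            fs = features_by_position(traces, kind)
            down = pair_velocity(fs[7.0], fs[8.0])
            counter = pair_velocity(fs[5.0], fs[4.0])
            assert down > counter
            assert fs[7.0].amplitude > fs[5.0].amplitude

    def test_amplitude_and_velocity_scale_with_intensity(self):
        amps, vels = [], []
        for intensity in (0.5, 1.0, 2.0):
            traces = wound_sim(intensity=intensity, sensors=(7.0, 9.0),
                               t_end=120.0, record_dt=0.05)
            fs = features_by_position(traces, "h2o2")
            amps.append(fs[7.0].amplitude)
            vels.append(pair_velocity(fs[7.0], fs[9.0]))
        assert amps[0] < amps[1] < amps[2]
        assert vels[0] <= vels[1] <= vels[2]

    def test_vp_takes_off_before_h2o2_at_same_sensor(self):
        traces = wound_sim(sensors=(7.0, 8.0), t_end=90.0)
        h = features_by_position(traces, "h2o2")
        v = features_by_position(traces, "vp")
        for pos in (7.0, 8.0):
            assert v[pos].takeoff_time < h[pos].takeoff_time

    @pytest.mark.parametrize("zone_kind", ["dpi", "gd"])
    def test_inhibitor_zone_abolishes_both_waves_beyond_it(self, zone_kind):
        traces = wound_sim(zones=[(4.2, 5.7, zone_kind)],
                           sensors=(8.5, 3.5), t_end=200.0)
        for kind in ("h2o2", "vp"):
            fs = features_by_position(traces, kind)
            assert fs[8.5] is not None, f"{kind} lost on the untreated side"
            assert fs[3.5] is None, f"{kind} crossed the {zone_kind} zone"

    def test_event_outside_lattice_rejected(self):
        lat = StemLattice.at_rest(length_cm=4.0)
        with pytest.raises(DomainError):
            simulate(lat, MechanismParams(),
                     [StressEvent(position=20.0, time=1.0, intensity=1.0)],
                     10.0, [2.0])


class TestExogenousH2O2:
    def test_zero_dose_no_vp(self):
        lat = StemLattice.at_rest(length_cm=8.0)
        assert exogenous_h2o2_response(lat, MechanismParams(), 0.0, 1.0,
                                       min_fluctuation=V_FLOOR) is None

    def test_subthreshold_dose_undetected_at_1cm(self):
        lat = StemLattice.at_rest(length_cm=8.0)
        f = exogenous_h2o2_response(lat, MechanismParams(), 0.5, 1.0,
                                    t_end=80.0, min_fluctuation=V_FLOOR)
        assert f is None

    def test_dose_dependent_vp_amplitude(self):
        amps = []
        for dose in (30.0, 100.0, 300.0):
            lat = StemLattice.at_rest(length_cm=8.0)
            f = exogenous_h2o2_response(lat, MechanismParams(), dose, 1.0,
                                        t_end=80.0, min_fluctuation=V_FLOOR)
            assert f is not None
            amps.append(f.amplitude)
        assert amps[0] < amps[1] < amps[2]


class TestVirtualSensor:
    CURVE = CalibrationCurve(sensitivity=0.109, intercept=0.0,
                             reference_concentration=0.1,
                             response_units="mA", valid_range=(0.1, 100.0))

    @staticmethod
    def step_conc(level=10.0, t0=5.0, dt=0.01, t_end=10.0):
        t = np.arange(0.0, t_end, dt)
        vals = np.where(t >= t0, level, 0.05)
        return Trace(times=t, values=vals, kind="h2o2")

    def test_first_order_response_time(self):
        out = virtual_sensor(self.step_conc(), self.CURVE, device_tau=0.11)
        lo = out.values[out.times < 5.0][-1]
        hi = out.values[-1]
        target = lo + 0.632 * (hi - lo)
        crossing = out.times[np.searchsorted(out.values, target)]
        assert crossing - 5.0 == pytest.approx(0.11, abs=0.02)

    def test_zero_tau_is_identity_through_the_curve(self):
        out = virtual_sensor(self.step_conc(), self.CURVE, device_tau=0.0)
        lo, hi = out.values[0], out.values[-1]
        assert lo == pytest.approx(0.0, abs=1e-12)  # clamped at range floor
        assert hi == pytest.approx(0.109 * np.log10(10.0 / 0.1), rel=1e-9)

    def test_seeded_noise_reproducible(self):
        conc = self.step_conc()
        a = virtual_sensor(conc, self.CURVE, 0.11, noise_sd=0.01, seed=3)
        b = virtual_sensor(conc, self.CURVE, 0.11, noise_sd=0.01, seed=3)
        c = virtual_sensor(conc, self.CURVE, 0.11, noise_sd=0.01, seed=4)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_negative_noise_rejected(self):
        with pytest.raises(DomainError):
            virtual_sensor(self.step_conc(), self.CURVE, 0.11, noise_sd=-1.0)
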