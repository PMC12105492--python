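# Methods

This note records the models behind each module, the defaults that matter,
and the design choices made where the underlying physiology fixes no unique
answer.

## Sensor calibration

The fitted model is `R = b + S·log₁₀(C/C_ref)`, estimated by ordinary least
squares of response on log-concentration. `C_ref` is the lowest measured
concentration, so `b` reads as the response at the bottom of the working
range and `valid_range` is exactly the fitted span. Either absolute current
change or percentage change may serve as the response; the curve carries a
units label rather than imposing one, because device sensitivities are
conventionally quoted in current per decade while traces are often plotted
as percentage change.

The S/N-limited detection limit inverts the fitted line at
`blank + snr·σ_noise`. The blank defaults to *zero response change*: for
percentage-change responses the blank solution reads zero by construction,
and only this convention lets a device whose line passes `3σ` at some
concentration report exactly that concentration as its limit. Referencing
the limit to the fitted intercept instead is available by passing
`blank_response=curve.intercept`. A zero or negative noise level is
rejected rather than mapped to a zero limit — a log-linear response never
reaches zero signal at finite concentration.

Extrapolation beyond `valid_range` warns but does not fail; detection
limits are, by nature, extrapolated.

## Xylem transport

The convection model treats the stem-average concentration as a passive
scalar with inflow boundary `C(0,t) = C_source` and effective front speed
`u·r` — the xylem flow `u` diluted over the whole cross-section because the
sensor reads the entire stem while only the xylem fraction `r` (default
0.012) carries flow. The written transport equation is solved by the method
of characteristics, which is exact for piecewise-constant `u(t)`; a gridded
upwind solver exists only as a test oracle. For the nominal `u = 0.35
cm/s`, fronts reach 1 and 2 cm at 238 and 476 s (mean ≈ 357 s), matching
the observed uptake timescale.

Pure plug flow yields step fronts; recorded rises are smooth. A single
first-order *lateral equilibration* constant (default 60 s) models the
radial exchange between xylem and surrounding tissue:
`C = C_source·(1 − e^{−(t−t_a)/τ_lat})` after front arrival `t_a`. The
value is a smoothing scale, not a measured quantity; it also makes the
least-squares objective smooth in `u` (with sharp fronts the objective is
piecewise-constant between sampling instants and the optimum is only
determined to one sample's worth of front travel).

The diffusion null model is the semi-infinite half-space solution
`C/C₀ = erfc(x/2√(Dt))` with `D = 1.96×10⁻⁵ cm²/s` (aqueous K⁺ at 25 °C).
Its characteristic time — 63.2 % of source at `x = 1 cm` — is
`t = (x/2z)²/D` with `z = erfcinv(0.632)`, ≈ 1.29 days: the closed-form
statement of why uptake in minutes requires convection.

`fit_flow_rate` minimises the summed squared residual over all sensors by
bounded scalar minimisation (`u ∈ [0, 5] cm/s` by default), reports the RMS
residual and per-sensor times-to-63.2 % (front arrival plus one lateral
time constant), raises on all-flat traces (non-identifiable) and warns when
the optimum sits on a bound. On noiseless forward-model traces the recovery
is exact to the optimiser tolerance; under 2 % multiplicative noise the
median bias across 50 seeds is below 1 %.

Stomatal events in an inferred-flow series are sustained (≥ 10 s)
departures beyond 5× the pre-stimulus fluctuation — the same convention as
wave take-off, since no separate criterion is established for flow traces —
classified by sign (acceleration = opening, suppression = closure), with
recovery upon sustained return into the band.

## Wave kinetics

*Baseline fluctuation* is the standard deviation of the linearly detrended
pre-stimulus window (≥ 10 samples), floored at 10⁻¹² trace units; linear
detrending stops slow drift from inflating the threshold. A scaled-MAD
estimator is available for spike-contaminated baselines.

*Take-off* is the first sample at or after the stimulus whose deviation
from the baseline mean reaches `k = 5` fluctuations and holds for three
consecutive samples (the hold suppresses single-sample noise triggers; an
instantaneous criterion is recovered with `hold=0`). Take-off is
sample-aligned — the event is defined by recorded samples crossing a level,
so a step registers at the sample where it lands. The 63.2 %-of-peak
crossing used for *rise time* is interpolated between samples, because
sampling rates differ across experiments and the crossing is a point on a
smooth rise. *Amplitude* is the largest |deviation| within a post-stimulus
analysis window (default 300 s) to exclude late drift. Membrane-potential
traces deflect negative on depolarisation; magnitudes are used throughout
so amplitudes are positive.

*Velocity* divides sensor separation by take-off time difference; equal
take-offs are an error (unbounded velocity), reversed ordering warns and
returns a signed value.

The distance-decay fit `y = y₀·e^{−x/λ}` starts from the closed-form
log-linear solution (exact on noiseless data) and refines by nonlinear
least squares on the original scale. Flat series are flagged non-decaying
(λ = ∞), increasing series yield a flagged negative λ. The rise-time model
`t_rise = floor + a·e^{−A/b}` is fitted with `floor ≥ 0` by bounded
least squares; exponential-with-floor is an assumption — the empirical
claim is only that rise time falls with amplitude toward a positive limit —
and near-constant inputs short-circuit to `floor = mean, a = 0` since `b`
is then unidentifiable.

## Mechanism simulator

State per cell: apoplastic H₂O₂, xylem H₂O₂, cytosolic Ca²⁺, vacuolar
Ca²⁺ store, membrane-potential deviation. One explicit-Euler step applies,
in order: RBOHD production (Hill in Ca²⁺, `k_rboh·ca/(ca+K_ca)`, boosted by
a decaying wound drive, silenced in DPI zones); Ca²⁺ influx through
H₂O₂-gated channels; TPC1 vacuolar release; plasmodesmal Ca²⁺ exchange
with both neighbours (reflecting ends); symmetric apoplast↔xylem H₂O₂
exchange with upwind advection of the xylem pool at speed `u`; first-order
clearance of every species; membrane potential relaxing toward a
saturating function of Ca²⁺ (`k_dep·ca/(ca+K_vm)`, τ = 0.5 s).

Two design choices deserve emphasis:

1. **Graded, not binary, gating.** The channel gates use Michaelis forms
   with half-activation at `theta_h` and `theta_ca`. A hard threshold makes
   the lattice an excitable medium whose travelling pulse renormalises to a
   fixed amplitude at every cell — it either dies outright or propagates
   unchanged, and no parameter choice yields the *decremental* behaviour
   recordings show (amplitude and velocity decaying smoothly over
   centimetres). With saturating gates the relay gain is highest at small
   amplitude, so setting the linearised loop gain slightly below unity
   guarantees a decaying wave everywhere, with a clean exponential
   far-field whose decay length is `√(D_eff/κ_eff)` — `D_eff = d_pd·dx²`
   the plasmodesmal diffusivity and `κ_eff` the net linear decay rate.

2. **Sub-unity loop gain as the default operating point.** With the default
   rates (`k_rboh = 6 μM/s`, `K_ca = 1.8 μM`, `g_h = 2 μM/s`,
   `theta_h = 4 μM`, `k_ao = 1 /s`, `k_ca_rec = 2 /s`, TPC1 contributing
   0.2 /s), the linearised gain is ≈ 0.93, giving emergent decay constants
   of ~1.4–1.6 cm for amplitude and velocity and pair velocities of
   ~0.1–0.5 cm/s over 1–4 cm — inside the observed 0.1–0.7 cm/s band.
   These defaults were calibrated once to that band; the simulator's claims
   are ordinal (orderings, blockades, asymmetries), never exact values.

Wound events inject an apoplastic H₂O₂ bolus (`300 μM × intensity` into
one cell) and a transient RBOHD drive (decay 10 s). Exogenous H₂O₂ enters
the xylem pool by default — an infusion through a stem hole — with
apoplastic entry as an option, and carries no RBOHD drive. DPI zones zero
RBOHD production; Gd³⁺ zones zero both plasma-membrane influx *and* TPC1
release, Gd³⁺ being a general cation-channel blocker — with influx alone
blocked, vacuolar release lets a Ca²⁺ wave re-form beyond the zone, which
the pharmacology contradicts.

Grid and stability: `dx = 0.1 cm`, `dt = 0.008 s` by default; the step
checks the advection CFL bound `u·dt/dx ≤ 1`, the exchange bound
`2·d_pd·dt ≤ 1` and `dt·max(rates) < 1`, and raises naming the violated
bound, as well as on NaN/negative states. With production, decay and
advection disabled, total H₂O₂ is conserved exactly (the exchange terms
are antisymmetric and the Euler update preserves their sum).

Downstream/counterstream asymmetry emerges from the xylem pathway: H₂O₂
entering the xylem is advected at `u` (not `u·r` — within vessels the flow
is undiluted), leaks out ahead of the front and opens Ca²⁺ channels
earlier, so downstream take-offs lead counterstream ones for both the
H₂O₂ and VP waves; at `u = 0` the lattice is symmetric and velocities
match to timing resolution. VP take-off precedes H₂O₂ take-off at a given
sensor because the diffusing Ca²⁺ front leads the H₂O₂ it subsequently
induces, and the membrane responds to Ca²⁺ within τ_vm = 0.5 s.

Feature extraction on noiseless simulator output uses explicit fluctuation
floors (0.005 μM for H₂O₂, 0.02 mV for potential — detection thresholds of
0.025 μM and 0.1 mV at the 5× rule), roughly the resolution of the devices
being emulated; the simulated waves themselves are deterministic, with
stochasticity confined to the virtual sensor (calibration map, first-order
device lag of 0.11 s, seeded Gaussian read noise).

## Synthetic data generator

Wave traces are a saturating rise `A(1 − e^{−Δt/τ_r})` truncated six time
constants after onset, followed by an exponential tail (default 100 s,
echoing the long-lasting tails of recorded waves); no waveform equation is
established for these signals, and the template's virtue is that take-off
and rise time have closed forms. Per signed sensor position the generator
programs: take-off at `stimulus + distance/velocity` with
direction-dependent velocity (defaults 0.39 cm/s downstream, 0.16
counterstream), amplitude `A₀·e^{−d/λ_A}` (λ_A default 1.53 cm; 1.29 for
VP-like traces), and rise time from the floor law (floor 9.9 s H₂O₂-like,
0.72 s VP-like). The waveform is *shifted so that the 5×noise threshold
crossing falls exactly at the programmed take-off* — take-off is defined by
that crossing, so this is the only placement under which the
generator/analyser pair closes; `τ_r` is then solved from the two
closed-form points (threshold crossing, 63.2 % of attained peak) so the
programmed rise time is reproduced to discretisation error.

Sampling defaults to 10 Hz. Read noise defaults to 0.1 % of the
stimulus-site amplitude — light additive Gaussian noise, i.i.d. per sample
(no 1/f component; none is characterised for these devices). At this level
the take-off jitter stays below the per-sample signal increment at
threshold, so two-sensor velocity recovery is limited by the sampling grid
(worst case one 0.1 s interval per take-off) rather than by noise.
Transport traces apply 2 % multiplicative noise to the forward convection
model; calibration tables apply absolute or relative Gaussian noise to the
log-linear model. Identical seeds give bit-identical tables.

What the generators do *not* emulate: multi-phase heat/flg22 kinetics,
baseline drift and electrode polarisation, 1/f noise, plant-to-plant
parameter scatter, or any coupling between channels beyond the programmed
regularities. Passing tests therefore demonstrate that the analysis
pipeline recovers the regularities it assumes, under the noise model
stated — not that real recordings satisfy those regularities.

## Problem sizes and numerics

Test and acceptance runs use: transport grids of ~1200–2400 samples at
1–2 s spacing; wave traces of ~2500–9000 samples at 10 Hz; 50-seed
Monte-Carlo recovery studies for the noisy-fit claims; mechanism lattices
of 121 cells (12 cm) for 1–3 simulated minutes. Velocity acceptance values
average three replicate recordings, mirroring the replicate-plant averaging
conventional for such measurements. All optimisers are deterministic;
every stochastic element takes an explicit seed.

## Known limitations

* Transport is 1-D and loss-free: no radial gradients, osmotic uptake or
  phloem contribution (the few-percent equilibrium offset below the bath
  concentration is deliberately not modelled).
* The mechanism simulator is phenomenological: rate laws and constants are
  the package's own, constrained only by ordinal behaviour; it makes no
  claim about absolute concentrations or potentials.
* The rise-time floor functional form (exponential in amplitude) is an
  assumption shared with the analyses it reproduces.
* Take-off detection is sample-aligned; velocities inherit up to one
  sampling interval of quantisation per sensor.
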