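# Methods

## Headspace-equilibrium N₂O quantification

A crimp-sealed serum bottle holds N₂O in the gas headspace (volume
*V*<sub>G</sub>, L) and dissolved in the liquid medium (*V*<sub>L</sub>, L).
Gas-chromatograph readings give the headspace mixing ratio *C*<sub>g</sub>
in ppm (µmol N₂O per mol of gas). Assuming the two phases are at partition
equilibrium — the standard assumption for gently shaken bottles sampled at
discrete times; no gas-transfer kinetics are modelled — the three
quantities per reading are

- *C*<sub>G</sub> = *P*·*C*<sub>g</sub> / (1013.25·*R*·*T*)  (µmol L⁻¹),
- *C*<sub>L</sub> = *C*<sub>G</sub>·(*K*₀·*R*·*T*)  (µmol L⁻¹),
- *Q* = *C*<sub>G</sub>·*V*<sub>G</sub> + *C*<sub>L</sub>·*V*<sub>L</sub>  (µmol),

with *P* the in-bottle pressure in hPa (1013.25 converts to atm), *T* the
equilibration temperature in K, and *R* = 0.082057 L atm mol⁻¹ K⁻¹. *R* is
deliberately this 6-digit value, not a higher-precision constant, so worked
values match the arithmetic of the published headspace equations this form
reconstructs. The first equation's published form is typographically
garbled in its source; the form used here is the dimensionally forced
reconstruction (mole fraction × ideal-gas molar density). The conservation
identity *Q* = *C*<sub>G</sub>*V*<sub>G</sub> + *C*<sub>L</sub>*V*<sub>L</sub>
holds bit-exactly because *Q* is computed as that expression.

*K*₀(*T*, *S*) (mol L⁻¹ atm⁻¹) is the Weiss & Price (1980) N₂O solubility
function, ln *K*₀ = A₁ + A₂(100/*T*) + A₃ ln(*T*/100) +
*S*[B₁ + B₂(*T*/100) + B₃(*T*/100)²], with the published coefficients
stored as named constants and validated in the test suite against an
independent evaluation (*K*₀(298.15 K, 0 ‰) = 0.02478 mol L⁻¹ atm⁻¹).
Calibration range is roughly 0–40 °C; a `CalibrationRangeWarning` is issued
outside [271, 320] K.

Defaults: salinity 0 ‰ (defined freshwater media; the salting-out
correction is <1% at lab-media ionic strengths, and the medium's ionic
strength is not a practical salinity anyway), pressure 1013.25 hPa when
unmeasured (sampling withdrawals are not pressure-corrected), and the
incubation temperature as the equilibration temperature. All three are
config keys. The inverse operation (ppm for a target amount) exists for the
simulator and round-trips with the forward calculation to 1e-9 relative
tolerance; both are linear, so the inverse is exact division by the
vessel's µmol-per-ppm capacity.

## Electron-balance stoichiometry

For a C/H/O/N species with ionic charge *z*, the degree of reduction

  e = 4C + H − 2O − 3N − z

is the number of electrons released per mole on complete oxidation to
CO₂/HCO₃⁻ and H₂O, with organic nitrogen leaving at the ammonium level
(the −3N term; no nitrogen-containing donors are in the built-in registry,
so that path is exercised only by property tests and should be considered
experimental). N₂O reduction (N₂O + 2H⁺ + 2e⁻ → N₂ + H₂O) accepts 2
electrons per mole — exposed as a parameter for reuse with other acceptors
— so the theoretical donor:acceptor ratio is e/2: acetate (C₂H₃O₂⁻, e = 8)
supports 4 mol N₂O per mol, lactate (C₃H₅O₃⁻, e = 12) supports 6.

Overall reactions are assembled per electron equivalent in exact
`fractions.Fraction` arithmetic: donor coefficient 1/e, ½ N₂O → ½ N₂, and
the donor's carbon split between CO₂ and HCO₃⁻ with one bicarbonate per
unit of anionic charge — an inference from the printed convention for the
acetate and lactate rows of the source chemistry, not a universal chemical
claim. Free protons and water close the charge and H balances (protons
cancel for the common anionic carboxylates), and every emitted reaction is
re-verified element-by-element and for charge before being returned. The
reconstructed acetate water coefficient is ⅛; the printed row is corrupted
and cannot confirm it.

The bioavailability efficiency is 100 × (observed molar ratio of N₂O
reduced per donor consumed) / (theoretical ratio): the fraction of donor
electrons realized as N₂O reduction, the rest going to biomass synthesis
and maintenance (no f<sub>s</sub>/f<sub>e</sub> partitioning is modelled).
Reports carry both the full-precision efficiency and an "as-printed"
variant computed from the ratio rounded to 2 decimals, because the
conventional reporting rounds before forming the percentage; for the
worked acetate consumptions (94.61 and 83.23 µmol) the full-precision
ratio is 0.8797 → 0.88 at 2 d.p. → 22.00%, whereas the value 0.89 → 22.25%
circulates in the literature for the same endpoints. Both are reported;
the discrepancy is documented rather than resolved.

## Kinetics

Consumption is the first-minus-last finite measurement inside an explicit
window; windows are never inferred, because published per-condition rates
use different monotone windows (0–24 h or 0–18 h). Negative consumption
(net production) is returned with a warning, not raised.

Exponential growth rates are ln(OD-ratio)/Δt for two points, or an
ordinary-least-squares fit of ln OD₆₀₀ against time over a user-selected
window; both agree to numerical precision on noiseless exponentials. The
fit makes no attempt to detect lag or plateau phases — the window is the
user's statement of where growth is exponential.

Per-cell rates divide consumption by the interval and a time-averaged cell
count. OD₆₀₀ → cells mL⁻¹ conversion is an empirical strain/instrument
property with no safe default, so `cells_per_ml_per_od` is a required
configuration parameter; published absolute per-cell rates (e.g.
5.10 × 10⁻⁹ µmol h⁻¹ cell⁻¹) are not reproducible without the conversion
their authors used, and this package does not claim to reproduce them. The
time-average is the arithmetic mean of the endpoint counts, or the
trapezoidal time-average when more than two OD points are available — a
documented choice; the source arithmetic never defines its averaging.

The donor–acceptor coupling is the OLS regression of cumulative N₂O
consumed on cumulative donor consumed (scipy.stats.linregress); the slope
is the observed coupling ratio. Whether published R² values on such
experiments regress concentrations or cumulative consumptions, and over
which timepoints, is typically unstated; this package documents its choice
(cumulative consumption from the window start) and does not claim to
reproduce any particular printed R². Rate enhancements between treatments
are plain ratios, conventionally reported to 1 decimal.

Reporting precisions in the text renderer: molar ratios 2 d.p., efficiency
2 d.p. of a percent, growth rates 4 d.p., fold-changes 1 d.p.

## Synthetic incubations

The simulator is an emulation, not a mechanistic claim: real incubations
report only measurements, and the minimal dynamical form reproducing their
slow/fast/plateau shape is a lag phase followed by Monod-in-amount
consumption,

  dQ/dt = −v_max · X(t) · f_env · Q/(K_s + Q)    for t ≥ lag,

with donor drawdown ΔQ/observed_ratio and OD gain growth_yield·ΔQ slaved
to the N₂O consumed. Slaving growth to reduction makes the no-N₂O control
flat automatically; the true cause of the growth plateau (donor vs
acceptor limitation) is an assumption, and here growth stops when N₂O is
exhausted. Because OD and donor are algebraic in the consumed amount, the
system is a single ODE in Q, integrated with fixed-step classical RK4 on
the sampling grid with substeps capped at 0.05 h and the state clipped at
zero; mass balance (donor consumed × ratio = N₂O consumed) holds to 1e-9
on noiseless runs.

Environmental response is multiplicative: a pH gate (0 at pH ≤ 6, ramping
to 1 at pH 7, full activity pH 7–9), a strict O₂ gate (0 at any headspace
O₂), and temperature factors normalized to 1 at 30 °C. The consumption
ramp rises linearly from 10 °C and keeps rising to 40 °C (capped at 1.5) —
observed reduction rates increase 20→40 °C — while the growth factor peaks
at 30 °C, where growth is optimal; the two are deliberately separate.
Values above 1 are permitted for the consumption temperature factor above
the 30 °C reference.

Defaults are the standard experimental conditions: 30/30 mL vessel at
303.15 K; initial N₂O 83.8 µmol (the measured initial amount under a 10%
N₂O headspace), acetate 173.45 µmol (5 mM × 30 mL ≈ 150 µmol nominal, as
measured), OD₆₀₀ 0.0675; lag 4 h; observed ratio 0.88; growth yield 0.0016
OD per µmol N₂O (= measured ΔOD 0.125 over ≈78 µmol reduced). v_max = 45
µmol h⁻¹ per OD unit and K_s = 5 µmol were chosen once so the default 24 h
run shows the characteristic shape (lag to 4 h, near-exhaustion by ~20 h,
OD roughly tripling). Measurement noise is additive Gaussian truncated at
zero, on the ppm readings (SD 900 ppm ≈ 1.65 µmol in the default vessel,
the scale of reported replicate SDs) and on OD (SD 0.002); donor
measurements are emitted noiseless, as their replicate scatter in real
data is dominated by between-bottle variation the simulator does not model.
Identical seeds give bit-identical outputs (`numpy.random.default_rng`).

What the simulator does *not* emulate — and therefore what passing
recovery tests do not show about real data: bottle-to-bottle biological
variation, pressure drift from repeated sampling, donor measurement error,
partial (non-gate) pH/O₂ responses, heavy-metal dose–response beyond an
optional multiplicative factor, and any electron-transport or ATP-level
mechanism.

The parameter-recovery suite simulates replicates (independent noise seeds
spawned from one master seed), pushes each through the full
partition → kinetics analysis, and reports bias and spread of the
recovered coupling ratio, growth rate (log-linear fit over the active
window, lag to N₂O near-exhaustion), and consumption total against the
noiseless twin's values. Noiseless recovery is exact to numerical
tolerance; with noise at 1% of the initial headspace signal and 20
replicates the ratio is recovered within 5%.

## Pipeline determinism and provenance

Reports embed SHA-256 checksums of the input series and config, the
resolved configuration, the package version and the seed. No wall-clock
timestamp is included, so rendering the same inputs twice yields
byte-identical JSON; `report_hash` is the SHA-256 of the canonical
serialization. Timepoints missing the N₂O reading are excluded from
consumption windows but retained for OD-based growth fitting; missing
values propagate as absent, never as zero.

## Problem sizes

Default grids are 13 timepoints over 24 h (2 h sampling, matching typical
experimental sampling); recovery suites use 20 replicates. The whole test
suite, including the recovery Monte-Carlo, runs in a few seconds on one
CPU.

## Known limitations

- Equilibrium partitioning only; bottles sampled faster than gas exchange
  equilibrates will bias totals.
- The degree-of-reduction formula covers C/H/O/N species with |charge| ≤ 3;
  sulfur or phosphorus donors are out of scope.
- The bicarbonate-per-anionic-charge split is a reporting convention, not
  thermodynamics; no Gibbs-energy or redox-potential calculations.
- Absolute per-cell rates require the user's own OD-to-cell calibration.
- The simulator's Monod/lag form is phenomenological; its parameters are
  not estimates of any organism's physiology.
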