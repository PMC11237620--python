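"""Synthetic sealed-bottle incubation generator.

Emulates the canonical N2O-respiration experiment: a 60 mL serum bottle
with 30 mL of defined medium under a 10% N2O headspace, inoculated at low
OD600, where donor oxidation, N2O reduction and biomass growth are tightly
coupled. The dynamics are an emulation choice, not a claim about mechanism:
a lag phase followed by Monod-in-amount consumption,

    dQ/dt = -v_max * X(t) * f_env * Q / (K_s + Q)        (t >= lag),

with donor drawdown ΔQ/observed_ratio and OD gain growth_yield*ΔQ slaved
to the N2O consumed (growth stops when the acceptor is exhausted, matching
the no-N2O control). Environmental on/off behaviour enters as a
multiplicative factor: acidic pH or any headspace O2 silences consumption
and growth entirely; the consumption temperature response ramps upward
through the 20-40 °C range while the growth response peaks at 30 °C.

Observations are emitted in instrument units — GC mixing ratios (ppm) via
the inverse headspace-partition calculation, OD600, donor µmol — with
additive Gaussian noise truncated at zero; a noiseless twin carries the
exact state so parameter recovery can be measured against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .gas_partition import VesselConditions, mixing_ratio_for_amount
from . import kinetics
from .gas_partition import GasReading, total_amount

#: Reference incubation temperature (30 °C), where both temperature
#: factors are normalized to 1.
REFERENCE_TEMPERATURE_K = 303.15


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated incubation.

    Defaults reproduce the standard acetate experiment: ~83.8 µmol N2O and
    173.45 µmol acetate in a 30/30 mL bottle at 30 °C, inoculum OD600
    0.0675, a 4 h lag, an observed coupling ratio of 0.88 mol N2O per mol
    acetate, and a growth yield of 0.0016 OD units per µmol N2O (the
    measured ΔOD 0.125 over ~78 µmol reduced). v_max = 45 µmol h⁻¹ per OD
    unit and K_s = 5 µmol give the characteristic slow/fast/plateau shape
    over a 24 h horizon. Noise SDs sit at the scale of reported replicate
    SDs: ~1.65 µmol of N2O (≈900 ppm in the default vessel) and 0.002 OD.
    """

    v_max: float = 45.0  # µmol N2O h⁻¹ per OD unit
    k_s: float = 5.0  # µmol, half-saturation amount
    lag: float = 4.0  # h
    observed_ratio: float = 0.88  # mol N2O per mol donor
    growth_yield: float = 0.0016  # OD units per µmol N2O reduced
    initial_n2o: float = 83.8  # µmol
    initial_donor: float = 173.45  # µmol
    initial_od: float = 0.0675
    noise_sd_ppm: float = 900.0
    noise_sd_od: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        non_negative = (
            "v_max", "k_s", "lag", "growth_yield",
            "initial_n2o", "initial_donor", "initial_od",
            "noise_sd_ppm", "noise_sd_od",
        )
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.observed_ratio <= 0:
            raise ArgumentError(f"observed_ratio must be > 0, got {self.observed_ratio}")


@dataclass(frozen=True)
class EnvironmentalState:
    """Temperature, pH and headspace O2, with their rate modifiers.

    The pH and O2 factors are hard gates in [0, 1]: consumption requires a
    neutral-to-alkaline medium (zero at pH <= 6) and strict anoxia (zero at
    any headspace O2). The consumption temperature factor is a linear ramp
    normalized to 1 at 30 °C that keeps rising toward 40 °C (capped at
    1.5), so it can exceed 1 above the reference; the growth factor peaks
    at 30 °C and declines on both sides.
    """

    temperature: float = REFERENCE_TEMPERATURE_K
    ph: float = 7.5
    oxygen_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ArgumentError(f"temperature must be > 0 K, got {self.temperature}")
        if not 0 <= self.ph <= 14:
            raise ArgumentError(f"ph must be in [0, 14], got {self.ph}")
        if not 0 <= self.oxygen_fraction <= 1:
            raise ArgumentError(
                f"oxygen_fraction must be in [0, 1], got {self.oxygen_fraction}"
            )

    @property
    def ph_factor(self) -> float:
        if self.ph <= 6.0:
            return 0.0
        return min(1.0, self.ph - 6.0)

    @property
    def oxygen_factor(self) -> float:
        return 0.0 if self.oxygen_fraction > 0 else 1.0

    @property
    def temperature_factor(self) -> float:
        # consumption ramp: 0 at <=10 °C, 1 at 30 °C, 1.5 at >=40 °C
        ramp = (self.temperature - 283.15) / (REFERENCE_TEMPERATURE_K - 283.15)
        return float(np.clip(ramp, 0.0, 1.5))

    @property
    def growth_temperature_factor(self) -> float:
        # triangular optimum at 30 °C, zero 15 °C away on either side
        return float(max(0.0, 1.0 - abs(self.temperature - REFERENCE_TEMPERATURE_K) / 15.0))


def environmental_modifier(state: EnvironmentalState) -> float:
    """Multiplicative consumption-rate factor for an environmental state.

    Product of the independent temperature, pH and O2 factors; zero
    whenever the medium is acidic (pH <= 6) or any O2 is present.
    """
    return state.temperature_factor * state.ph_factor * state.oxygen_factor


def growth_modifier(state: EnvironmentalState) -> float:
    """Multiplicative growth-yield factor (temperature optimum at 30 °C)."""
    return state.growth_temperature_factor * state.ph_factor * state.oxygen_factor


@dataclass(frozen=True)
class SimulationResult:
    """Noisy observations plus the exact noiseless twin of one simulation.

    ``observations`` uses instrument units (time_h, n2o_ppm, od600,
    donor_umol) — the same CSV dialect the analysis pipeline reads.
    ``truth`` carries the exact state (total_n2o_umol, od600, donor_umol)
    and the noiseless ppm column.
    """

    observations: pd.DataFrame
    truth: pd.DataFrame
    params: SimulationParams
    state: EnvironmentalState
    conditions: VesselConditions = field(default_factory=VesselConditions)

    @property
    def truth_series(self) -> kinetics.IncubationSeries:
        return kinetics.IncubationSeries(
            times=self.truth["time_h"].to_numpy(),
            total_n2o=self.truth["total_n2o_umol"].to_numpy(),
            od600=self.truth["od600"].to_numpy(),
            donor=self.truth["donor_umol"].to_numpy(),
            label="truth",
            vessel=self.conditions,
        )


_MAX_STEP_H = 0.05  # RK4 substep ceiling, h


def _rk4_consume(q0: float, od0: float, donor0: float, dt: float,
                 params: SimulationParams, f_env: float, g_env: float) -> float:
    """Advance consumed-N2O over dt with classical RK4; returns new Q.

    OD and donor are algebraic in the consumed amount, so the system
    reduces to a single ODE in Q. Consumption halts if donor runs out.
    """

    def rate(q: float) -> float:
        if q <= 0:
            return 0.0
        consumed = q0 - q
        donor = donor0 - consumed / params.observed_ratio
        if donor <= 0:
            return 0.0
        od = od0 + params.growth_yield * g_env * consumed
        return -params.v_max * od * f_env * q / (params.k_s + q)

    q = q0
    n_sub = max(1, int(np.ceil(dt / _MAX_STEP_H)))
    h = dt / n_sub
    for _ in range(n_sub):
        k1 = rate(q)
        k2 = rate(max(q + 0.5 * h * k1, 0.0))
        k3 = rate(max(q + 0.5 * h * k2, 0.0))
        k4 = rate(max(q + h * k3, 0.0))
        q = max(q + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, 0.0)
    return q


def simulate_incubation(
    params: SimulationParams,
    state: EnvironmentalState | None = None,
    conditions: VesselConditions | None = None,
    time_grid: np.ndarray | list[float] | None = None,
) -> SimulationResult:
    """Simulate one sealed-bottle incubation on the given time grid.

    Deterministic for a fixed ``params.seed``. Default grid is 0-24 h
    sampled every 2 h. Returns noisy observations and the noiseless twin.
    """
    state = state or EnvironmentalState()
    conditions = conditions or VesselConditions(temperature=state.temperature)
    grid = np.asarray(
        time_grid if time_grid is not None else np.arange(0.0, 24.0 + 1e-9, 2.0),
        dtype=float,
    )
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ArgumentError("time_grid must be a strictly increasing 1-D grid")
    if grid[0] < 0:
        raise ArgumentError("time_grid must start at t >= 0")

    f_env = environmental_modifier(state)
    g_env = growth_modifier(state)

    q = np.empty_like(grid)
    q[0] = params.initial_n2o
    for i in range(1, grid.size):
        t0, t1 = grid[i - 1], grid[i]
        if t1 <= params.lag or f_env == 0.0 or q[i - 1] <= 0:
            q[i] = q[i - 1]
            continue
        start = max(t0, params.lag)  # lag consumes the front of the step
        q[i] = _rk4_consume(
            q[i - 1], _od_at(params, g_env, q[0] - q[i - 1]),
            params.initial_donor - (q[0] - q[i - 1]) / params.observed_ratio,
            t1 - start, params, f_env, g_env,
        )

    consumed = q[0] - q
    donor = np.maximum(params.initial_donor - consumed / params.observed_ratio, 0.0)
    od = params.initial_od + params.growth_yield * g_env * consumed
    ppm = np.array([mixing_ratio_for_amount(x, conditions) for x in q])

    truth = pd.DataFrame(
        {
            "time_h": grid,
            "total_n2o_umol": q,
            "n2o_ppm": ppm,
            "od600": od,
            "donor_umol": donor,
        }
    )

    rng = np.random.default_rng(params.seed)
    obs = pd.DataFrame(
        {
            "time_h": grid,
            "n2o_ppm": np.maximum(
                ppm + rng.normal(0.0, params.noise_sd_ppm, grid.size)
                if params.noise_sd_ppm > 0 else ppm, 0.0
            ),
            "od600": np.maximum(
                od + rng.normal(0.0, params.noise_sd_od, grid.size)
                if params.noise_sd_od > 0 else od, 0.0
            ),
            "donor_umol": donor,
        }
    )
    return SimulationResult(
        observations=obs, truth=truth, params=params, state=state, conditions=conditions
    )


def _od_at(params: SimulationParams, g_env: float, consumed: float) -> float:
    return params.initial_od + params.growth_yield * g_env * consumed


def observations_to_series(
    observations: pd.DataFrame, conditions: VesselConditions, label: str = ""
) -> kinetics.IncubationSeries:
    """Convert an instrument-unit observation table into total-amount space."""
    totals = np.array(
        [
            total_amount(GasReading(t, ppm), conditions).total_amount
            if np.isfinite(ppm)
            else np.nan
            for t, ppm in zip(observations["time_h"], observations["n2o_ppm"])
        ]
    )
    return kinetics.IncubationSeries(
        times=observations["time_h"].to_numpy(dtype=float),
        total_n2o=totals,
        od600=observations["od600"].to_numpy(dtype=float),
        donor=observations["donor_umol"].to_numpy(dtype=float),
        label=label,
        vessel=conditions,
    )


@dataclass(frozen=True)
class RecoveryQuantity:
    """Recovery statistics for one scalar across replicates."""

    truth: float
    estimates: np.ndarray
    name: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1)) if self.estimates.size > 1 else 0.0

    @property
    def bias(self) -> float:
        return self.mean - self.truth

    @property
    def relative_bias(self) -> float:
        return self.bias / self.truth if self.truth != 0 else float("nan")


@dataclass(frozen=True)
class RecoveryReport:
    """Bias and spread of pipeline estimates against simulator ground truth."""

    observed_ratio: RecoveryQuantity
    growth_rate: RecoveryQuantity
    n2o_consumed: RecoveryQuantity
    replicates: int
    seed: int


def parameter_recovery_suite(
    true_params: SimulationParams,
    replicates: int = 20,
    seed: int = 0,
    state: EnvironmentalState | None = None,
    conditions: VesselConditions | None = None,
    time_grid: np.ndarray | list[float] | None = None,
) -> RecoveryReport:
    """Simulate, analyze, and measure how well the pipeline recovers truth.

    Each replicate gets an independent noise seed derived from ``seed``.
    Recovered quantities: the coupling ratio (N2O consumed over donor
    consumed), the exponential growth rate fitted on the active window
    (lag to N2O exhaustion), and total N2O consumed. Truth for the growth
    rate and consumption comes from applying the same estimators to the
    noiseless twin, so recovery error reflects measurement noise alone.
    """
    if replicates < 1:
        raise ArgumentError(f"replicates must be >= 1, got {replicates}")
    state = state or EnvironmentalState()
    conditions = conditions or VesselConditions(temperature=state.temperature)
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates)

    base = replace(true_params, seed=int(child_seeds[0]))
    reference = simulate_incubation(base, state, conditions, time_grid)
    truth_df = reference.truth
    window = _active_window(truth_df, base)
    truth_series = reference.truth_series
    truth_report = kinetics.analyze_series(truth_series, growth_window=window)

    ratios, rates, totals = [], [], []
    for child in child_seeds:
        sim = simulate_incubation(
            replace(true_params, seed=int(child)), state, conditions, time_grid
        )
        series = observations_to_series(sim.observations, conditions)
        report = kinetics.analyze_series(series, growth_window=window)
        if report.donor_consumed and report.donor_consumed > 0:
            ratios.append(report.n2o_consumed / report.donor_consumed)
        if report.growth_rate is not None:
            rates.append(report.growth_rate)
        totals.append(report.n2o_consumed)

    return RecoveryReport(
        observed_ratio=RecoveryQuantity(
            true_params.observed_ratio, np.asarray(ratios), "observed_ratio"
        ),
        growth_rate=RecoveryQuantity(
            truth_report.growth_rate if truth_report.growth_rate is not None else float("nan"),
            np.asarray(rates),
            "growth_rate",
        ),
        n2o_consumed=RecoveryQuantity(
            truth_report.n2o_consumed, np.asarray(totals), "n2o_consumed"
        ),
        replicates=replicates,
        seed=seed,
    )


def _active_window(truth: pd.DataFrame, params: SimulationParams) -> tuple[float, float]:
    """Window from end of lag to N2O near-exhaustion (or the grid end)."""
    t = truth["time_h"].to_numpy()
    q = truth["total_n2o_umol"].to_numpy()
    active = q > 0.05 * max(q[0], 1e-12)
    end = t[active][-1] if active.any() else t[-1]
    start = min(params.lag, end - (t[1] - t[0]))
    return (max(start, t[0]), float(end))


#: The canonical experimental arms, as (name, params overrides, state).
FIXTURE_ARMS: tuple[tuple[str, dict, EnvironmentalState], ...] = (
    ("acetate", {}, EnvironmentalState()),
    (
        "lactate",
        {"initial_n2o": 89.63, "initial_donor": 105.99, "observed_ratio": 2.07},
        EnvironmentalState(),
    ),
    ("ph5_control", {}, EnvironmentalState(ph=5.0)),
    ("o2_control", {}, EnvironmentalState(oxygen_fraction=0.05)),
    ("no_cell_control", {"initial_od": 0.0, "growth_yield": 0.0, "v_max": 0.0}, EnvironmentalState()),
    ("no_n2o_control", {"initial_n2o": 0.0}, EnvironmentalState()),
)


def write_fixture_pack(outdir, seed: int = 0) -> list[str]:
    """Write the canned dataset pack mirroring the standard experimental arms.

    One CSV per arm in the pipeline's input dialect, plus a config file for
    the shared vessel. Returns the written paths.
    """
    from pathlib import Path
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = VesselConditions()
    written = []
    for i, (name, overrides, state) in enumerate(FIXTURE_ARMS):
        params = replace(SimulationParams(seed=seed + i), **overrides)
        sim = simulate_incubation(params, state, conditions)
        path = outdir / f"{name}.csv"
        sim.observations.to_csv(path, index=False)
        written.append(str(path))
    config_path = outdir / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "gas_volume_L": conditions.gas_volume,
                "liquid_volume_L": conditions.liquid_volume,
                "temperature_K": conditions.temperature,
                "pressure_hPa": conditions.pressure,
                "salinity_psu": conditions.salinity,
            },
            fh,
        )
    written.append(str(config_path))
    return written
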