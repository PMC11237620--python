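"""Headspace-equilibrium partitioning of N2O in sealed incubation vessels.

A sealed serum bottle holds N2O in two compartments: the gas headspace and
the liquid medium. Assuming partition equilibrium, a GC reading of the
headspace mixing ratio (ppm, µmol N2O per mol of gas) determines both
compartment concentrations and hence the total amount in the vessel:

    C_G = P * C_g / (1013.25 * R * T)        headspace, µmol L⁻¹
    C_L = C_G * K0 * R * T                   dissolved, µmol L⁻¹
    Q   = C_G * V_G + C_L * V_L              total, µmol

where P is the in-bottle pressure (hPa), R = 0.082057 L atm mol⁻¹ K⁻¹,
T the equilibration temperature (K) and K0 the temperature- and
salinity-dependent solubility constant (mol L⁻¹ atm⁻¹) from the
Weiss & Price solubility function. The dimensionless product K0*R*T is
the liquid/gas partition ratio.

All amounts are µmol, volumes litres, concentrations µmol L⁻¹; unit
conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ArgumentError, CalibrationRangeWarning

#: Ideal gas constant, L atm mol⁻¹ K⁻¹. Deliberately the 6-digit value used
#: in the headspace equations rather than a higher-precision CODATA value,
#: so derived quantities match the worked arithmetic they are compared to.
GAS_CONSTANT = 0.082057

#: Standard atmosphere in hectopascal; the 1013.25 divisor converting P from
#: hPa to atm in the headspace-concentration equation.
STANDARD_PRESSURE_HPA = 1013.25

# Weiss & Price (1980) Mar. Chem. 8:347-359, N2O solubility in water and
# seawater, K0 in mol L-1 atm-1:
#   ln K0 = a1 + a2*(100/T) + a3*ln(T/100) + S*(b1 + b2*(T/100) + b3*(T/100)^2)
# Calibration range roughly 0-40 degC; a warning is issued outside [271, 320] K.
_WEISS_A1 = -62.7062
_WEISS_A2 = 97.3066
_WEISS_A3 = 24.1406
_WEISS_B1 = -0.058420
_WEISS_B2 = 0.033193
_WEISS_B3 = -0.0051313

_CALIBRATION_RANGE_K = (271.0, 320.0)


@dataclass(frozen=True)
class VesselConditions:
    """Geometry and physics of one sealed incubation vessel.

    Defaults describe the standard 60 mL serum bottle: 30 mL headspace over
    30 mL liquid medium, incubated at 30 °C under 1 atm, freshwater medium.

    Parameters
    ----------
    gas_volume : float
        Headspace volume V_G, litres. Must be positive.
    liquid_volume : float
        Liquid volume V_L, litres. Non-negative (0 = dry vessel).
    temperature : float
        Equilibration temperature T, kelvin. A warning is raised outside
        the solubility function's calibration range [271, 320] K.
    pressure : float
        In-bottle pressure P, hectopascal.
    salinity : float
        Practical salinity S, per mil. 0 for defined freshwater media.
    """

    gas_volume: float = 0.030
    liquid_volume: float = 0.030
    temperature: float = 303.15
    pressure: float = STANDARD_PRESSURE_HPA
    salinity: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gas_volume", "liquid_volume", "temperature", "pressure", "salinity"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ArgumentError(f"{name} must be finite, got {v!r}")
        if self.gas_volume <= 0:
            raise ArgumentError(f"gas_volume must be > 0, got {self.gas_volume}")
        if self.liquid_volume < 0:
            raise ArgumentError(f"liquid_volume must be >= 0, got {self.liquid_volume}")
        if self.temperature <= 0:
            raise ArgumentError(f"temperature must be > 0 K, got {self.temperature}")
        if self.pressure <= 0:
            raise ArgumentError(f"pressure must be > 0 hPa, got {self.pressure}")
        if self.salinity < 0:
            raise ArgumentError(f"salinity must be >= 0, got {self.salinity}")
        lo, hi = _CALIBRATION_RANGE_K
        if not lo <= self.temperature <= hi:
            warnings.warn(
                f"temperature {self.temperature} K is outside the solubility "
                f"function's calibration range [{lo}, {hi}] K",
                CalibrationRangeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class GasReading:
    """One GC headspace measurement: time (h) and mixing ratio (ppm)."""

    time: float
    mixing_ratio: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and math.isfinite(self.mixing_ratio)):
            raise ArgumentError("time and mixing_ratio must be finite")
        if self.time < 0:
            raise ArgumentError(f"time must be >= 0 h, got {self.time}")
        if self.mixing_ratio < 0:
            raise ArgumentError(f"mixing_ratio must be >= 0 ppm, got {self.mixing_ratio}")


@dataclass(frozen=True)
class PartitionResult:
    """Partitioned N2O for one reading.

    ``total_amount`` satisfies the conservation identity
    ``total_amount == headspace_conc * V_G + dissolved_conc * V_L`` exactly
    (it is computed as that expression, never independently).
    """

    headspace_conc: float  # C_G, µmol L⁻¹
    dissolved_conc: float  # C_L, µmol L⁻¹
    total_amount: float  # Q, µmol
    solubility_constant: float  # K0, mol L⁻¹ atm⁻¹
    gas_constant: float = field(default=GAS_CONSTANT)


def solubility_constant(temperature: float, salinity: float = 0.0) -> float:
    """Solubility constant K0 of N2O, mol L⁻¹ atm⁻¹.

    Evaluates the Weiss & Price ln-polynomial in T/100 and salinity.
    K0 decreases with temperature (colder water dissolves more gas) and
    with salinity (salting-out).

    Parameters
    ----------
    temperature : float
        Kelvin; must be positive. Warns outside [271, 320] K.
    salinity : float
        Practical salinity, per mil; must be non-negative.
    """
    if not (math.isfinite(temperature) and math.isfinite(salinity)):
        raise ArgumentError("temperature and salinity must be finite")
    if temperature <= 0:
        raise ArgumentError(f"temperature must be > 0 K, got {temperature}")
    if salinity < 0:
        raise ArgumentError(f"salinity must be >= 0, got {salinity}")
    lo, hi = _CALIBRATION_RANGE_K
    if not lo <= temperature <= hi:
        warnings.warn(
            f"temperature {temperature} K is outside the solubility function's "
            f"calibration range [{lo}, {hi}] K",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    t = temperature / 100.0
    ln_k0 = (
        _WEISS_A1
        + _WEISS_A2 / t
        + _WEISS_A3 * math.log(t)
        + salinity * (_WEISS_B1 + _WEISS_B2 * t + _WEISS_B3 * t * t)
    )
    return math.exp(ln_k0)


def headspace_concentration(mixing_ratio: float, conditions: VesselConditions) -> float:
    """Headspace concentration C_G (µmol L⁻¹) from a GC mixing ratio (ppm).

    C_G = P * C_g / (1013.25 * R * T): the ideal-gas molar density of the
    headspace, P/(RT) in atm over L atm mol⁻¹ K⁻¹ K, times the mole fraction
    C_g*1e-6, expressed in µmol L⁻¹. Linear in both mixing ratio and pressure.
    """
    if not math.isfinite(mixing_ratio) or mixing_ratio < 0:
        raise ArgumentError(f"mixing_ratio must be >= 0 ppm, got {mixing_ratio}")
    return (
        conditions.pressure
        * mixing_ratio
        / (STANDARD_PRESSURE_HPA * GAS_CONSTANT * conditions.temperature)
    )


def dissolved_concentration(
    headspace_conc: float, solubility_constant: float, temperature: float
) -> float:
    """Dissolved concentration C_L (µmol L⁻¹) at partition equilibrium.

    C_L = C_G * (K0 * R * T); the bracketed factor is the dimensionless
    liquid/gas partition ratio, so C_L/C_G is independent of C_G.
    """
    if headspace_conc < 0 or solubility_constant < 0:
        raise ArgumentError("headspace_conc and solubility_constant must be >= 0")
    if temperature <= 0:
        raise ArgumentError(f"temperature must be > 0 K, got {temperature}")
    return headspace_conc * solubility_constant * GAS_CONSTANT * temperature


def total_amount(reading: GasReading, conditions: VesselConditions) -> PartitionResult:
    """Partition one GC reading into both compartments and total it.

    Composes the headspace, dissolved and totalling equations;
    Q = C_G*V_G + C_L*V_L holds bit-exactly by construction.
    """
    k0 = solubility_constant(conditions.temperature, conditions.salinity)
    c_g = headspace_concentration(reading.mixing_ratio, conditions)
    c_l = dissolved_concentration(c_g, k0, conditions.temperature)
    q = c_g * conditions.gas_volume + c_l * conditions.liquid_volume
    return PartitionResult(
        headspace_conc=c_g, dissolved_conc=c_l, total_amount=q, solubility_constant=k0
    )


def mixing_ratio_for_amount(target_amount: float, conditions: VesselConditions) -> float:
    """Mixing ratio (ppm) whose partitioned total equals ``target_amount`` µmol.

    Inverse of :func:`total_amount`; used by the incubation simulator to emit
    GC-style readings. Round-trips with the forward calculation to better
    than 1e-9 relative tolerance.
    """
    if not math.isfinite(target_amount) or target_amount < 0:
        raise ArgumentError(f"target_amount must be >= 0 µmol, got {target_amount}")
    k0 = solubility_constant(conditions.temperature, conditions.salinity)
    partition_ratio = k0 * GAS_CONSTANT * conditions.temperature
    effective_volume = conditions.gas_volume + partition_ratio * conditions.liquid_volume
    # µmol of N2O per ppm of mixing ratio in this vessel
    umol_per_ppm = (
        conditions.pressure
        / (STANDARD_PRESSURE_HPA * GAS_CONSTANT * conditions.temperature)
        * effective_volume
    )
    if umol_per_ppm <= 0:
        raise ArgumentError("degenerate vessel: no capacity to hold gas")
    return target_amount / umol_per_ppm
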