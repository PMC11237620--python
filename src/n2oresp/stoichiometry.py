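"""Electron-balance bookkeeping for donor oxidation coupled to N2O reduction.

A heterotrophic N2O-respiring bacterium oxidizes an organic electron donor
completely to CO2/HCO3⁻ and water and passes the liberated electrons to
nitrous oxide, which is reduced to N2 (N2O + 2H⁺ + 2e⁻ → N2 + H2O, two
electrons per mole of N2O). The degree of reduction of a C/H/O/N species
with ionic charge z,

    e = 4*C + H - 2*O - 3*N - z,

counts the electrons released per mole on complete oxidation (organic
nitrogen leaves at the ammonium level). Dividing by the two electrons each
N2O accepts gives the theoretical donor:acceptor ratio; the observed molar
ratio of N2O reduced per donor consumed, as a percentage of the theoretical
ratio, is the donor's bioavailability efficiency — the fraction of donor
electrons actually realized as N2O reduction (the remainder supports
biomass synthesis and maintenance).

Balanced overall reactions are assembled per electron equivalent in exact
rational arithmetic and verified element-by-element before being returned.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from importlib import resources

from .errors import (
    ArgumentError,
    StoichiometryError,
    UnknownDonorError,
    UnsupportedSpeciesError,
)

#: Electrons accepted per mole of N2O on reduction to N2. Exposed so the
#: module can be reused for other two-or-more-electron acceptors.
ELECTRONS_PER_N2O = 2


@dataclass(frozen=True)
class ElementalComposition:
    """A donor's C/H/O/N atom counts and ionic charge.

    The unit of electron bookkeeping: everything downstream (available
    electrons, theoretical ratio, balanced reaction) derives from it.
    """

    carbon: int
    hydrogen: int
    oxygen: int
    nitrogen: int = 0
    charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        counts = (self.carbon, self.hydrogen, self.oxygen, self.nitrogen)
        if any(c < 0 for c in counts):
            raise ArgumentError(f"atom counts must be >= 0: {self}")
        if sum(counts) == 0:
            raise ArgumentError("composition must contain at least one atom")
        if not -3 <= self.charge <= 3:
            raise ArgumentError(f"charge must be in [-3, 3], got {self.charge}")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_SUPPORTED_ELEMENTS = ("C", "H", "O", "N")


def parse_formula(formula: str, charge: int = 0, name: str = "") -> ElementalComposition:
    """Parse a Hill-notation C/H/O/N formula string like ``"C2H3O2"``.

    Elements other than C, H, O, N are rejected.
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ArgumentError(f"malformed formula {formula!r}")
    counts = {el: 0 for el in _SUPPORTED_ELEMENTS}
    for element, digits in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        if element not in counts:
            raise ArgumentError(f"unsupported element {element!r} in {formula!r}")
        counts[element] += int(digits) if digits else 1
    return ElementalComposition(
        carbon=counts["C"],
        hydrogen=counts["H"],
        oxygen=counts["O"],
        nitrogen=counts["N"],
        charge=charge,
        name=name or formula,
    )


@lru_cache(maxsize=1)
def donor_registry() -> dict[str, ElementalComposition]:
    """Built-in electron donors, loaded from the packaged registry file."""
    registry: dict[str, ElementalComposition] = {}
    with resources.files("n2oresp.data").joinpath("donors.csv").open(
        encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(fh):
            name = row["name"].strip().lower()
            registry[name] = parse_formula(
                row["formula"].strip(), charge=int(row["charge"]), name=name
            )
    return registry


def get_donor(name: str) -> ElementalComposition:
    """Look up a donor by (case-insensitive) name in the registry."""
    try:
        return donor_registry()[name.strip().lower()]
    except KeyError:
        known = ", ".join(sorted(donor_registry()))
        raise UnknownDonorError(f"unknown donor {name!r}; registry has: {known}") from None


def available_electrons(composition: ElementalComposition) -> int:
    """Electrons released per mole on complete oxidation (degree of reduction).

    4C + H - 2O - 3N - charge: the electron count of the oxidation
    half-reaction to CO2/HCO3⁻, H2O, H⁺ and (for organic N) NH4⁺. A
    negative result means the species is more oxidized than CO2 and cannot
    serve as a donor.
    """
    e = (
        4 * composition.carbon
        + composition.hydrogen
        - 2 * composition.oxygen
        - 3 * composition.nitrogen
        - composition.charge
    )
    if e < 0:
        raise UnsupportedSpeciesError(
            f"{composition.name or composition}: {e} available electrons "
            "(more oxidized than CO2)"
        )
    return e


def theoretical_acceptor_ratio(
    electrons_per_donor: float, electrons_per_acceptor: int = ELECTRONS_PER_N2O
) -> float:
    """Moles of acceptor reducible per mole of donor at full electron coupling."""
    if electrons_per_donor < 0:
        raise ArgumentError(f"electrons_per_donor must be >= 0, got {electrons_per_donor}")
    if electrons_per_acceptor <= 0:
        raise ArgumentError("electrons_per_acceptor must be positive")
    return electrons_per_donor / electrons_per_acceptor


@dataclass(frozen=True)
class OverallReaction:
    """Balanced donor-oxidation/N2O-reduction reaction per electron equivalent.

    Coefficients are exact :class:`fractions.Fraction` values; ``donor``,
    ``n2o`` and ``h_plus`` sit on the left, the rest on the right. The carbon
    is split between CO2 and HCO3⁻ with one bicarbonate per unit of the
    donor's negative charge, the pattern of the acetate and lactate rows of
    the source chemistry (an inference about the printed convention, not a
    universal claim). Element and charge balance are verified at
    construction in rational arithmetic.
    """

    composition: ElementalComposition
    donor: Fraction
    n2o: Fraction
    h_plus: Fraction
    co2: Fraction
    hco3: Fraction
    nh4: Fraction
    n2: Fraction
    h2o: Fraction

    def balance_residuals(self) -> dict[str, Fraction]:
        """Left-minus-right totals per element and for charge; all must be 0."""
        c = self.composition
        return {
            "C": self.donor * c.carbon - self.co2 - self.hco3,
            "H": self.donor * c.hydrogen + self.h_plus
            - (self.hco3 + 4 * self.nh4 + 2 * self.h2o),
            "O": self.donor * c.oxygen + self.n2o
            - (2 * self.co2 + 3 * self.hco3 + self.h2o),
            "N": self.donor * c.nitrogen + 2 * self.n2o - (self.nh4 + 2 * self.n2),
            "charge": self.donor * c.charge + self.h_plus - (-self.hco3 + self.nh4),
        }


def balanced_overall_reaction(composition: ElementalComposition) -> OverallReaction:
    """Combine donor oxidation with N2O reduction, normalized to 1 e⁻.

    The donor oxidation half-reaction (normalized to one electron) is added
    to ½N2O + H⁺ + e⁻ → ½N2 + ½H2O. With the bicarbonate split following
    the donor's anionic charge, the free protons cancel for the anionic
    carboxylates, reproducing e.g. the acetate reaction
    ⅛CH3COO⁻ + ½N2O → ⅛CO2 + ⅛HCO3⁻ + ½N2 + ⅛H2O.
    """
    e = available_electrons(composition)
    if e <= 0:
        raise StoichiometryError(
            f"{composition.name or composition} has no available electrons"
        )
    donor = Fraction(1, e)
    hco3 = Fraction(max(0, -composition.charge), e)
    co2 = Fraction(composition.carbon, e) - hco3
    nh4 = Fraction(composition.nitrogen, e)
    n2o = Fraction(1, 2)
    # donor nitrogen leaves at the ammonium level, so N2 mirrors the acceptor
    n2 = n2o + (donor * composition.nitrogen - nh4) / 2
    # charge balance fixes the free protons; H balance then fixes water
    h_plus = -hco3 + nh4 - donor * composition.charge
    h2o = (donor * composition.hydrogen + h_plus - hco3 - 4 * nh4) / 2
    reaction = OverallReaction(
        composition=composition,
        donor=donor,
        n2o=n2o,
        h_plus=h_plus,
        co2=co2,
        hco3=hco3,
        nh4=nh4,
        n2=n2,
        h2o=h2o,
    )
    residuals = reaction.balance_residuals()
    if any(r != 0 for r in residuals.values()):
        raise StoichiometryError(
            f"unbalanceable composition {composition}: residuals {residuals}"
        )
    if co2 < 0 or h2o < 0:
        raise StoichiometryError(
            f"negative product coefficient for {composition.name or composition}"
        )
    return reaction


def observed_ratio(donor_consumed: float, acceptor_consumed: float) -> float:
    """Observed mol N2O reduced per mol donor consumed (full precision).

    The conventional printed form rounds to 2 decimals; see
    :func:`as_printed_ratio`.
    """
    if not math.isfinite(donor_consumed) or donor_consumed <= 0:
        raise ArgumentError(f"donor_consumed must be > 0, got {donor_consumed}")
    if not math.isfinite(acceptor_consumed) or acceptor_consumed < 0:
        raise ArgumentError(f"acceptor_consumed must be >= 0, got {acceptor_consumed}")
    return acceptor_consumed / donor_consumed


def as_printed_ratio(ratio: float) -> float:
    """Round a molar ratio to the 2-decimal reporting convention."""
    return round(ratio, 2)


def bioavailability_efficiency(observed: float, theoretical: float) -> float:
    """Observed ratio as a percentage of the theoretical ratio."""
    if theoretical <= 0:
        raise ArgumentError(f"theoretical ratio must be > 0, got {theoretical}")
    if observed < 0:
        raise ArgumentError(f"observed ratio must be >= 0, got {observed}")
    return 100.0 * observed / theoretical


@dataclass(frozen=True)
class StoichiometryReport:
    """Electron bookkeeping for one donor/acceptor pair.

    Carries both full-precision and "as-printed" (2-decimal ratio)
    efficiencies: the printed convention rounds the observed ratio before
    forming the percentage, which can shift the efficiency by a few tenths
    of a point.
    """

    donor: str
    electrons_per_donor: int
    theoretical_ratio: float
    observed_ratio: float
    observed_ratio_2dp: float
    efficiency: float
    efficiency_as_printed: float

    def to_dict(self) -> dict:
        return {
            "donor": self.donor,
            "electrons_per_donor": self.electrons_per_donor,
            "theoretical_ratio": self.theoretical_ratio,
            "observed_ratio": self.observed_ratio,
            "observed_ratio_2dp": self.observed_ratio_2dp,
            "efficiency_percent": self.efficiency,
            "efficiency_percent_as_printed": self.efficiency_as_printed,
        }


def stoichiometry_report(
    donor: ElementalComposition | str,
    donor_consumed: float,
    acceptor_consumed: float,
) -> StoichiometryReport:
    """Full electron-balance report for measured consumptions.

    Efficiencies above 100% are physically suspect (more N2O reduced than
    the donor's electrons allow) and trigger a warning, but are reported.
    """
    composition = get_donor(donor) if isinstance(donor, str) else donor
    electrons = available_electrons(composition)
    theoretical = theoretical_acceptor_ratio(electrons)
    ratio = observed_ratio(donor_consumed, acceptor_consumed)
    ratio_2dp = as_printed_ratio(ratio)
    efficiency = bioavailability_efficiency(ratio, theoretical)
    if efficiency > 100.0:
        warnings.warn(
            f"{composition.name}: efficiency {efficiency:.2f}% exceeds 100% "
            "(more acceptor reduced than donor electrons supplied)",
            stacklevel=2,
        )
    return StoichiometryReport(
        donor=composition.name,
        electrons_per_donor=electrons,
        theoretical_ratio=theoretical,
        observed_ratio=ratio,
        observed_ratio_2dp=ratio_2dp,
        efficiency=efficiency,
        efficiency_as_printed=bioavailability_efficiency(ratio_2dp, theoretical),
    )
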