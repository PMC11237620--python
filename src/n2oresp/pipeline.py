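"""End-to-end analysis: CSV + config in, reproducible report out.

Composes the stages in measurement order: GC mixing ratios are partitioned
into per-vessel total N2O amounts, consumption and growth kinetics are
summarized, and the donor's electron-balance stoichiometry (theoretical
ratio, observed ratio, bioavailability efficiency) is evaluated against the
measured consumptions. The report carries a provenance block (input
checksums, config, package version, seed) sufficient to recompute every
derived number, and renders losslessly to JSON, or rounded per the
conventional reporting precisions to text, or per-timepoint to CSV.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ArgumentError, SchemaError
from .gas_partition import GasReading, VesselConditions, total_amount
from .io import read_config, read_series
from .kinetics import IncubationSeries, KineticsReport, analyze_series
from .stoichiometry import StoichiometryReport, stoichiometry_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisReport:
    """One vessel's complete analysis with provenance.

    ``partition`` has one row per timepoint with a finite GC reading;
    ``provenance`` records SHA-256 checksums of the input files, the
    resolved config, the package version, and any seed, so the report is
    recomputable (and tamper-evident) from its inputs alone.
    """

    label: str
    donor: str
    partition: list[dict]
    kinetics: KineticsReport
    stoichiometry: StoichiometryReport | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "donor": self.donor,
            "partition": self.partition,
            "kinetics": self.kinetics.to_dict(),
            "stoichiometry": None
            if self.stoichiometry is None
            else self.stoichiometry.to_dict(),
            "provenance": self.provenance,
        }

    @property
    def report_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_series(df, conditions: VesselConditions, label: str = "") -> IncubationSeries:
    """Partition each GC reading and assemble the total-amount series."""
    times = df["time_h"].to_numpy(dtype=float)
    ppm = df["n2o_ppm"].to_numpy(dtype=float)
    totals = np.full_like(times, np.nan)
    for i, (t, x) in enumerate(zip(times, ppm)):
        if np.isfinite(x):
            totals[i] = total_amount(GasReading(t, x), conditions).total_amount
    return IncubationSeries(
        times=times,
        total_n2o=totals,
        od600=df["od600"].to_numpy(dtype=float),
        donor=df["donor_umol"].to_numpy(dtype=float),
        label=label,
        vessel=conditions,
    )


def run_analysis(
    series_path: str | Path,
    config_path: str | Path,
    donor_name: str,
    *,
    cells_per_ml_per_od: float | None = None,
    growth_window: tuple[float, float] | None = None,
    rate_window: tuple[float, float] | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full pipeline on one incubation CSV.

    Raises :class:`SchemaError` for malformed tables, ``UnknownDonorError``
    for donors absent from the registry, and ``ValidationError`` for
    non-monotone time; no partial report is produced on failure.
    """
    conditions, extras = read_config(config_path)
    if cells_per_ml_per_od is None and "cells_per_ml_per_od" in extras:
        cells_per_ml_per_od = float(extras["cells_per_ml_per_od"])
    df = read_series(series_path)
    logger.info("read %d timepoints from %s", len(df), series_path)

    series = build_series(df, conditions, label=str(series_path))
    partition_rows = []
    for t, x in zip(df["time_h"], df["n2o_ppm"]):
        if not np.isfinite(x):
            continue
        result = total_amount(GasReading(float(t), float(x)), conditions)
        partition_rows.append(
            {
                "time_h": float(t),
                "n2o_ppm": float(x),
                "headspace_conc_umol_L": result.headspace_conc,
                "dissolved_conc_umol_L": result.dissolved_conc,
                "total_n2o_umol": result.total_amount,
                "solubility_constant_mol_L_atm": result.solubility_constant,
            }
        )
    logger.info("partitioned %d GC readings", len(partition_rows))

    kin = analyze_series(
        series,
        cells_per_ml_per_od=cells_per_ml_per_od,
        growth_window=growth_window,
        rate_window=rate_window,
    )
    logger.info(
        "kinetics: N2O consumed %.2f µmol, donor consumed %s µmol",
        kin.n2o_consumed,
        f"{kin.donor_consumed:.2f}" if kin.donor_consumed is not None else "n/a",
    )

    stoich = None
    if kin.donor_consumed is not None and kin.donor_consumed > 0:
        stoich = stoichiometry_report(donor_name, kin.donor_consumed, kin.n2o_consumed)
        logger.info(
            "stoichiometry: observed ratio %.4f, efficiency %.2f%%",
            stoich.observed_ratio,
            stoich.efficiency,
        )

    provenance = {
        "series_sha256": _sha256(series_path),
        "config_sha256": _sha256(config_path),
        "config": {**asdict(conditions), **extras},
        "donor": donor_name,
        "software_version": __version__,
        "seed": seed,
    }
    return AnalysisReport(
        label=str(series_path),
        donor=donor_name,
        partition=partition_rows,
        kinetics=kin,
        stoichiometry=stoich,
        provenance=provenance,
    )


_FORMATS = ("json", "csv", "text")


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialize a report: lossless JSON, per-timepoint CSV, or rounded text.

    The text view applies the conventional reporting precisions: molar
    ratios to 2 decimals, efficiencies to 2 decimals of a percent, growth
    rates to 4 decimals, fold-changes to 1 decimal.
    """
    if format not in _FORMATS:
        raise ArgumentError(f"unknown format {format!r}; choose from {_FORMATS}")
    data = report.to_dict()
    if format == "json":
        return json.dumps(data, sort_keys=True, indent=2) + "\n"
    if format == "csv":
        buf = _stdio.StringIO()
        cols = list(report.partition[0]) if report.partition else ["time_h"]
        buf.write(",".join(cols) + "\n")
        for row in report.partition:
            buf.write(",".join(repr(row[c]) for c in cols) + "\n")
        buf.write("\n# summary\n")
        for section in ("kinetics", "stoichiometry"):
            block = data[section] or {}
            for key, value in block.items():
                buf.write(f"{section}.{key},{value!r}\n")
        return buf.getvalue()

    lines = [
        f"Incubation analysis: {report.label}",
        f"  donor: {report.donor}",
        f"  timepoints partitioned: {len(report.partition)}",
        f"  N2O consumed: {report.kinetics.n2o_consumed:.2f} µmol",
    ]
    if report.kinetics.donor_consumed is not None:
        lines.append(f"  donor consumed: {report.kinetics.donor_consumed:.2f} µmol")
    if report.kinetics.od_increase is not None:
        lines.append(f"  OD600 increase: {report.kinetics.od_increase:.4f}")
    if report.kinetics.growth_rate is not None:
        lines.append(f"  exponential growth rate: {report.kinetics.growth_rate:.4f} h⁻¹")
    if report.kinetics.mean_rate_per_cell is not None:
        lines.append(
            f"  mean rate per cell: {report.kinetics.mean_rate_per_cell:.3e} µmol·h⁻¹·cell⁻¹"
        )
    if report.stoichiometry is not None:
        s = report.stoichiometry
        lines += [
            f"  electrons per donor: {s.electrons_per_donor}",
            f"  theoretical ratio: {s.theoretical_ratio:g} mol N2O/mol donor",
            f"  observed ratio: {s.observed_ratio_2dp:.2f} (full precision {s.observed_ratio:.4f})",
            f"  bioavailability efficiency: {s.efficiency_as_printed:.2f}% "
            f"(full precision {s.efficiency:.2f}%)",
        ]
    if report.kinetics.coupling_r2 is not None:
        lines.append(
            f"  coupling fit: slope {report.kinetics.coupling_slope:.4f}, "
            f"R² {report.kinetics.coupling_r2:.4f}"
        )
    return "\n".join(lines) + "\n"
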