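"""Readers for the incubation CSV dialect and the vessel config file."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .gas_partition import VesselConditions

#: Required columns of the incubation time-series CSV. Values may be
#: missing (empty cells), and missing propagates as NaN, never as zero.
SERIES_COLUMNS = ("time_h", "n2o_ppm", "od600", "donor_umol")

_CONFIG_KEYS = {
    "gas_volume_L": "gas_volume",
    "liquid_volume_L": "liquid_volume",
    "temperature_K": "temperature",
    "pressure_hPa": "pressure",
    "salinity_psu": "salinity",
}


def read_series(path: str | Path) -> pd.DataFrame:
    """Read one incubation time series (UTF-8 CSV, '.' decimals, header row).

    Validates the schema and that time is present, finite and strictly
    increasing; raises :class:`SchemaError` naming the first missing column.
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, ValueError) as exc:
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    for col in SERIES_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if len(df) == 0:
        raise SchemaError(f"empty series in {path}")
    times = df["time_h"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise ValidationError(f"time_h contains missing or non-finite values in {path}")
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"time_h must be strictly increasing in {path}")
    return df[list(SERIES_COLUMNS)].astype(float)


def read_config(path: str | Path) -> tuple[VesselConditions, dict]:
    """Read the vessel config (YAML key-value file).

    Recognized keys: gas_volume_L, liquid_volume_L, temperature_K,
    pressure_hPa, salinity_psu; anything else (e.g. cells_per_ml_per_od)
    is returned untouched in the extras dict. Missing vessel keys fall
    back to the standard serum-bottle defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a key-value mapping")
    vessel_kwargs = {
        attr: float(raw[key]) for key, attr in _CONFIG_KEYS.items() if key in raw
    }
    extras = {k: v for k, v in raw.items() if k not in _CONFIG_KEYS}
    return VesselConditions(**vessel_kwargs), extras
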