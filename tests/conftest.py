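"""Shared fixtures: the standard vessel, config files, and endpoint series."""

import pytest
import yaml

from n2oresp import VesselConditions


@pytest.fixture
def vessel() -> VesselConditions:
    """The standard 60 mL serum bottle: 30/30 mL at 30 °C, 1 atm, fresh water."""
    return VesselConditions()


@pytest.fixture
def config_path(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text(
        yaml.safe_dump(
            {
                "gas_volume_L": 0.030,
                "liquid_volume_L": 0.030,
                "temperature_K": 303.15,
                "pressure_hPa": 1013.25,
                "salinity_psu": 0.0,
            }
        ),
        encoding="utf-8",
    )
    return path


@pytest.fixture
def series_writer(tmp_path):
    """Write an incubation CSV from parallel column lists; returns the path."""

    def _write(name, time_h, n2o_ppm, od600, donor_umol):
        rows = ["time_h,n2o_ppm,od600,donor_umol"]
        for vals in zip(time_h, n2o_ppm, od600, donor_umol):
            rows.append(",".join("" if v is None else repr(v) for v in vals))
        path = tmp_path / name
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        return path

    return _write
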