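"""Registry of the marine habitat indicators the toolkit handles.

Each variable carries canonical units and the default quantile-mapping mode:
additive corrections for variables that can change sign or sit near zero
(temperature, salinity anomalies, pH), multiplicative (ratio) corrections for
strictly positive concentrations so corrected oxygen and chlorophyll can never
go negative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class VariableInfo:
    name: str
    units: str
    dqm_mode: str  # "additive" | "multiplicative"
    standard_name: str


VARIABLES: dict[str, VariableInfo] = {
    "temperature": VariableInfo("temperature", "degC", "additive", "sea_water_temperature"),
    "salinity": VariableInfo("salinity", "1", "additive", "sea_water_practical_salinity"),
    "ph": VariableInfo("ph", "1", "additive", "sea_water_ph_reported_on_total_scale"),
    "oxygen": VariableInfo("oxygen", "ml l-1", "multiplicative", "volume_fraction_of_oxygen_in_sea_water"),
    "chlorophyll": VariableInfo(
        "chlorophyll", "kg m-3", "multiplicative", "mass_concentration_of_chlorophyll_in_sea_water"
    ),
}

DEPTH_LABELS = ("surface", "subsurface", "seafloor")

#: Nominal depth in metres of the fixed product levels.
DEPTH_OF_LABEL = {"surface": 5.0, "subsurface": 25.0}


def variable_info(name: str) -> VariableInfo:
    try:
        return VARIABLES[name]
    except KeyError:
        raise ValidationError(
            f"unknown variable {name!r}; expected one of {sorted(VARIABLES)}"
        ) from None
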