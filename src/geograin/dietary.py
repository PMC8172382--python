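"""Dietary supply as percent of the estimated average requirement (EAR).

A kriged grain-concentration surface is converted, nodewise, into the
percentage of a reference EAR met by a fixed per-capita staple intake:

    percent = 100 * concentration * (intake_g_day / 1000) / EAR

Concentrations are mg per kg dry matter (Se: ug per kg) so intake/1000
converts g/day to kg/day and the delivered dose shares the EAR's unit.
Default intakes are FAO per-capita figures (wheat 97.6, teff 89.3, maize
342.8 g/day); default EARs are for an adult woman aged 18-24 on an
unrefined, high-phytate diet: Ca 860 mg, Fe 22.4 mg, Zn 10.2 mg and Se
45 ug per day. Note the Se requirement is on the microgram scale,
matching the ug/kg scale of grain Se — a mg-scale Se EAR paired with ug/kg
concentrations is rejected as a unit mismatch. Percentages are not capped
at 100. Display maps use quartile classes of the unmasked nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

#: FAO reference staple intakes, g per capita per day.
DEFAULT_INTAKES_G_DAY = {"wheat": 97.6, "teff": 89.3, "maize": 342.8}

#: EAR per element: (requirement per day, unit). Concentration units must match.
DEFAULT_EARS = {"Ca": (860.0, "mg"), "Fe": (22.4, "mg"),
                "Se": (45.0, "ug"), "Zn": (10.2, "mg")}

#: Unit of grain concentration per element (per kg dry matter).
CONCENTRATION_UNITS = {"Ca": "mg", "Fe": "mg", "Se": "ug", "Zn": "mg"}


@dataclass
class IntakeEarTable:
    """Editable intake / EAR configuration with per-element units."""

    intakes_g_day: dict = field(default_factory=lambda: dict(DEFAULT_INTAKES_G_DAY))
    ears: dict = field(default_factory=lambda: dict(DEFAULT_EARS))

    def __post_init__(self):
        for crop, i in self.intakes_g_day.items():
            if not i > 0:
                raise ValueError(f"intake for {crop} must be positive")
        for el, (e, _unit) in self.ears.items():
            if not e > 0:
                raise ValueError(f"EAR for {el} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "IntakeEarTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ears = {el: (float(v[0]), str(v[1])) for el, v in raw["ears"].items()}
        return cls(intakes_g_day={k: float(v) for k, v in raw["intakes_g_day"].items()},
                   ears=ears)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"intakes_g_day": self.intakes_g_day,
                            "ears": {el: list(v) for el, v in self.ears.items()}}, fh)


def percent_ear(concentration, intake_g_day: float, ear: float):
    """Percent of the daily requirement met: 100 * c * (I/1000) / EAR.

    ``concentration`` per kg and ``ear`` per day must share their mass unit
    (mg with mg, ug with ug). Linear in both concentration and intake; not
    capped at 100.
    """
    c = np.asarray(concentration, dtype=float)
    if not (intake_g_day > 0 and ear > 0) or np.any(c[np.isfinite(c)] < 0):
        raise ValueError("concentration, intake and EAR must be positive")
    out = 100.0 * c * (intake_g_day / 1000.0) / ear
    return out if out.ndim else float(out)


def concentration_for_percent(percent, intake_g_day: float, ear: float):
    """Inverse of :func:`percent_ear`: the concentration delivering ``percent``."""
    p = np.asarray(percent, dtype=float)
    out = p * ear / (100.0 * intake_g_day / 1000.0)
    return out if out.ndim else float(out)


def percent_ear_for(table: IntakeEarTable, crop: str, element: str, concentration):
    """Table-driven :func:`percent_ear` with a per-element unit check."""
    if crop not in table.intakes_g_day:
        raise KeyError(f"no reference intake for crop {crop!r}")
    if element not in table.ears:
        raise KeyError(f"no EAR for element {element!r}")
    ear, ear_unit = table.ears[element]
    conc_unit = CONCENTRATION_UNITS.get(element, "mg")
    if ear_unit != conc_unit:
        raise ValueError(
            f"unit mismatch for {element}: EAR given in {ear_unit}/day but grain "
            f"concentrations are {conc_unit}/kg; express both on the same scale")
    return percent_ear(concentration, table.intakes_g_day[crop], ear)


def quartile_classes(values, mask=None):
    """Quartile display classes (1-4) over the unmasked map nodes.

    Breaks are the 25th/50th/75th percentiles of unmasked, finite values;
    masked or non-finite nodes get class 0 and do not influence the breaks.
    Classing is monotone in the value. All-identical values collapse to a
    single class with a warning.
    """
    v = np.asarray(values, dtype=float)
    excluded = ~np.isfinite(v)
    if mask is not None:
        excluded = excluded | np.asarray(mask, dtype=bool)
    use = v[~excluded]
    if use.size < 4:
        raise ValueError("need at least 4 unmasked values for quartile classes")
    classes = np.zeros(v.shape, dtype=int)
    if np.all(use == use[0]):
        warnings.warn("all unmasked values identical; single display class",
                      stacklevel=2)
        classes[~excluded] = 1
        return classes
    breaks = np.percentile(use, [25.0, 50.0, 75.0])
    classes[~excluded] = 1 + np.searchsorted(breaks, use, side="left")
    return classes
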