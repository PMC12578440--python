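"""beta-galactosidase reporter activity from ONPG assays.

Two-hybrid interaction strength is read out colorimetrically: lacZ
expression hydrolyses o-nitrophenyl-beta-D-galactopyranoside (ONPG) to
o-nitrophenol, whose absorbance at 420 nm accumulates with time.  Two
published normalizations are supported:

* ``amberg`` — specific activity against extract protein content:
  activity (nmol/min/mg) = OD420 x 1.7 /
  [0.0045 x protein (mg/ml) x extract volume (ml) x time (min)]
* ``paiano`` — units against culture density:
  units = 1000 x OD420 / [T (min) x V (ml of culture) x OD595]

Both are linear in OD420 and inversely proportional to elapsed time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "OnpgMeasurement",
    "ActivityResult",
    "activity_amberg",
    "activity_paiano",
    "activity",
    "mean_sd",
    "read_measurements_csv",
    "write_activities_csv",
]


@dataclass
class OnpgMeasurement:
    od420: float
    elapsed_min: float
    extract_volume_ml: float
    method: str  # {amberg, paiano}
    protein_mgml: float | None = None
    od595: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("amberg", "paiano"):
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("od420", "elapsed_min", "extract_volume_ml"):
            v = getattr(self, name)
            if v is None or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.elapsed_min <= 0:
            raise ValueError("elapsed_min must be > 0")
        if self.method == "amberg" and (self.protein_mgml is None):
            raise ValueError("amberg method requires protein_mgml")
        if self.method == "paiano" and (self.od595 is None):
            raise ValueError("paiano method requires od595")


@dataclass
class ActivityResult:
    value: float
    units: str  # {nmol/min/mg, units}

    def to_dict(self) -> dict:
        return {"value": self.value, "units": self.units}


def activity_amberg(m: OnpgMeasurement) -> ActivityResult:
    """Specific activity normalized to extract protein (nmol/min/mg)."""
    if m.method != "amberg":
        raise ValueError("measurement is not an amberg-method record")
    if m.protein_mgml is None or m.protein_mgml <= 0:
        raise ValueError("protein concentration must be > 0")
    if m.extract_volume_ml <= 0 or m.elapsed_min <= 0:
        raise ValueError("extract volume and time must be > 0")
    value = m.od420 * 1.7 / (0.0045 * m.protein_mgml * m.extract_volume_ml * m.elapsed_min)
    return ActivityResult(value=value, units="nmol/min/mg")


def activity_paiano(m: OnpgMeasurement) -> ActivityResult:
    """Activity units normalized to culture density (OD595)."""
    if m.method != "paiano":
        raise ValueError("measurement is not a paiano-method record")
    if m.od595 is None or m.od595 <= 0:
        raise ValueError("od595 must be > 0")
    if m.extract_volume_ml <= 0 or m.elapsed_min <= 0:
        raise ValueError("culture volume and time must be > 0")
    value = 1000.0 * m.od420 / (m.elapsed_min * m.extract_volume_ml * m.od595)
    return ActivityResult(value=value, units="units")


def activity(m: OnpgMeasurement) -> ActivityResult:
    return activity_amberg(m) if m.method == "amberg" else activity_paiano(m)


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Replicate mean and sample standard deviation (ddof=1)."""
    n = len(values)
    if n == 0:
        raise ValueError("no values")
    mu = sum(values) / n
    if n == 1:
        return mu, float("nan")
    var = sum((v - mu) ** 2 for v in values) / (n - 1)
    return mu, math.sqrt(var)


# ---------------------------------------------------------------------------
# CSV I/O: one measurement per row with a 'method' column.
# ---------------------------------------------------------------------------

_COLUMNS = ["od420", "elapsed_min", "extract_volume_ml", "method", "protein_mgml", "od595"]


def read_measurements_csv(path: str | Path) -> list[OnpgMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = row[col] if col == "method" else float(row[col])
        out.append(OnpgMeasurement(**kwargs))
    return out


def write_activities_csv(
    measurements: Iterable[OnpgMeasurement], path: str | Path
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        res = activity(m)
        rows.append(
            {
                "method": m.method,
                "od420": m.od420,
                "elapsed_min": m.elapsed_min,
                "value": res.value,
                "units": res.units,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
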