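"""Sample metadata model: ecosystems, size fractions, and the sample sheet.

The study design spans three connected compartments: the sea surface
(floating foam, the <1 mm surface microlayer "SML", and 1-m subsurface
water "SSW"), the atmospheric boundary layer (aerosol filters), and
precipitation (rain, one mixed snow/rain sample).  Handling/sequencing
controls are carried through parsing but are excluded from every
downstream statistic.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigError, ValidationError


class Ecosystem(str, Enum):
    FOAM = "foam"
    SML = "SML"
    SSW = "SSW"
    AEROSOL = "aerosol"
    RAIN = "rain"
    SNOW = "snow"
    CONTROL = "control"


class Fraction(str, Enum):
    """Filter size fraction of a sample."""

    GT5UM = "gt5um"            # >5 µm prefilter
    UM5_02 = "um5_02"          # 5–0.2 µm ("prokaryote") fraction
    VIROME = "virome_lt02um"   # <0.2 µm FeCl3-flocculated virome
    NA = "na"


#: Marine compartments (sea surface system).
MARINE: frozenset[Ecosystem] = frozenset(
    {Ecosystem.FOAM, Ecosystem.SML, Ecosystem.SSW}
)
#: Precipitation compartments; snow grouping is configurable downstream.
PRECIPITATION: frozenset[Ecosystem] = frozenset({Ecosystem.RAIN, Ecosystem.SNOW})

_REQUIRED_COLUMNS = ("sample_id", "ecosystem", "fraction", "station", "date")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    ecosystem: Ecosystem
    fraction: Fraction = Fraction.NA
    station: Optional[str] = None
    date: Optional[_dt.date] = None
    volume: Optional[float] = None
    volume_unit: Optional[str] = None  # "L" or "m3"

    @property
    def is_control(self) -> bool:
        return self.ecosystem is Ecosystem.CONTROL

    @property
    def is_marine(self) -> bool:
        return self.ecosystem in MARINE

    @property
    def is_precipitation(self) -> bool:
        return self.ecosystem in PRECIPITATION


def load_sample_sheet(path) -> list[SampleRecord]:
    """Parse a TSV sample sheet into :class:`SampleRecord` rows.

    The reader is tolerant (unknown extra columns are ignored) but strict
    on the required columns and on enum values.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"sample sheet missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample_id(s): {dups}")

    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        try:
            eco = Ecosystem(row["ecosystem"])
        except ValueError:
            raise ValidationError(
                f"unknown ecosystem {row['ecosystem']!r} for sample "
                f"{row['sample_id']!r}"
            ) from None
        frac_raw = row["fraction"] or "na"
        try:
            frac = Fraction(frac_raw)
        except ValueError:
            raise ValidationError(
                f"unknown fraction {frac_raw!r} for sample {row['sample_id']!r}"
            ) from None
        date = None
        if row["date"]:
            date = _dt.date.fromisoformat(row["date"])
        vol = None
        unit = None
        if "volume" in df.columns and row.get("volume", ""):
            vol = float(row["volume"])
            unit = row.get("volume_unit", "L") or "L"
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                ecosystem=eco,
                fraction=frac,
                station=row["station"] or None,
                date=date,
                volume=vol,
                volume_unit=unit,
            )
        )
    return records


def write_sample_sheet(records: Iterable[SampleRecord], path) -> None:
    """Strict writer: fixed header, ISO dates, '.' decimal separator."""
    rows = [
        {
            "sample_id": r.sample_id,
            "ecosystem": r.ecosystem.value,
            "fraction": r.fraction.value,
            "station": r.station or "",
            "date": r.date.isoformat() if r.date else "",
            "volume": "" if r.volume is None else repr(r.volume),
            "volume_unit": r.volume_unit or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def analysis_samples(records: Iterable[SampleRecord]) -> list[SampleRecord]:
    """Samples contributing to occupancy/abundance: everything but controls."""
    return [r for r in records if not r.is_control]


def ecosystem_of(records: Iterable[SampleRecord]) -> dict[str, Ecosystem]:
    return {r.sample_id: r.ecosystem for r in records}
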