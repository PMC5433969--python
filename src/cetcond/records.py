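"""Morphometric records for stranded small cetaceans.

A :class:`MorphRecord` holds one animal's necropsy morphometrics (mass,
length, girth, blubber depths) together with the stratification labels used
by the condition analyses: cause-of-death class (acute trauma vs chronic
debilitation), age class (from length cutoffs at sexual maturity), and
life-history season (breeding vs nonbreeding months).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ClassCutoffs",
    "MorphRecord",
    "MissingFieldError",
    "SchemaError",
    "assign_age_class",
    "assign_season",
    "read_morphometrics_csv",
    "records_to_frame",
    "write_morphometrics_csv",
    "MORPH_CSV_COLUMNS",
]

SEXES = ("male", "female")
COD_CLASSES = ("acute", "chronic")
AGE_CLASSES = ("calf", "juvenile", "adult")
SEASONS = ("breeding", "nonbreeding")

#: exact header of the morphometrics CSV interchange format
MORPH_CSV_COLUMNS = [
    "id",
    "sex",
    "date",
    "cod_class",
    "age_class",
    "season",
    "mass_kg",
    "length_cm",
    "girth_cm",
    "blubber_dorsal_mm",
    "blubber_lateral_mm",
    "blubber_ventral_mm",
]


class MissingFieldError(ValueError):
    """A record lacks a field required by the requested computation."""

    def __init__(self, field: str, record_id: str | None = None):
        self.field = field
        self.record_id = record_id
        where = f" in record {record_id!r}" if record_id else ""
        super().__init__(f"missing required field {field!r}{where}")


class SchemaError(ValueError):
    """An input table does not match the expected column schema."""


@dataclass(frozen=True)
class ClassCutoffs:
    """Length cutoffs (cm) and months defining the stratification labels.

    Adults are animals at or above the length at sexual maturity for males
    of the study species; calves at or below the weaning length; the
    breeding season covers the peak calving/mating months.
    """

    adult_min_cm: float = 135.0
    calf_max_cm: float = 90.0
    breeding_months: tuple[int, ...] = (6, 7, 8)


def assign_age_class(length_cm: float, cutoffs: ClassCutoffs = ClassCutoffs()) -> str:
    if length_cm >= cutoffs.adult_min_cm:
        return "adult"
    if length_cm <= cutoffs.calf_max_cm:
        return "calf"
    return "juvenile"


def assign_season(date: _dt.date, cutoffs: ClassCutoffs = ClassCutoffs()) -> str:
    return "breeding" if date.month in cutoffs.breeding_months else "nonbreeding"


@dataclass
class MorphRecord:
    """One stranded animal's morphometrics plus strata labels.

    Units: mass kg, length and girth cm, blubber depths mm.  ``age_class``
    and ``season`` may be omitted, in which case they are derived from the
    length and the stranding date under the configured cutoffs.
    """

    id: str
    sex: str
    date: _dt.date
    cod_class: str
    mass: float
    length: float
    girth: float | None = None
    blubber_dorsal: float | None = None
    blubber_lateral: float | None = None
    blubber_ventral: float | None = None
    age_class: str | None = None
    season: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cod_class not in COD_CLASSES:
            raise ValueError(
                f"cod_class must be one of {COD_CLASSES}, got {self.cod_class!r}"
            )
        if not (self.mass > 0):
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if not (self.length > 0):
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.girth is not None and not (self.girth > 0):
            raise ValueError(f"girth must be > 0, got {self.girth}")
        for name in ("blubber_dorsal", "blubber_lateral", "blubber_ventral"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.age_class is None:
            self.age_class = assign_age_class(self.length)
        elif self.age_class not in AGE_CLASSES:
            raise ValueError(f"age_class must be one of {AGE_CLASSES}")
        if self.season is None:
            self.season = assign_season(self.date)
        elif self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")

    def require(self, *fields: str) -> None:
        """Raise :class:`MissingFieldError` if any named field is absent."""
        for f in fields:
            v = getattr(self, f)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise MissingFieldError(f, self.id)


def records_to_frame(records: Sequence[MorphRecord]) -> pd.DataFrame:
    """Tabulate records in the interchange CSV column layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "date": r.date.isoformat(),
                "cod_class": r.cod_class,
                "age_class": r.age_class,
                "season": r.season,
                "mass_kg": r.mass,
                "length_cm": r.length,
                "girth_cm": r.girth,
                "blubber_dorsal_mm": r.blubber_dorsal,
                "blubber_lateral_mm": r.blubber_lateral,
                "blubber_ventral_mm": r.blubber_ventral,
            }
        )
    return pd.DataFrame(rows, columns=MORPH_CSV_COLUMNS)


def write_morphometrics_csv(records: Sequence[MorphRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_morphometrics_csv(
    path,
    cutoffs: ClassCutoffs = ClassCutoffs(),
    on_bad_row: str = "log",
) -> tuple[list[MorphRecord], list[str]]:
    """Read the morphometrics interchange CSV.

    Returns ``(records, rejected_messages)``.  Malformed rows are rejected
    individually (``on_bad_row='log'``) or raise (``on_bad_row='raise'``);
    the run continues past bad rows by default so that one corrupt line does
    not discard a strandings dataset.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MORPH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"morphometrics CSV {path} is missing columns {missing}; "
            f"expected exactly {MORPH_CSV_COLUMNS}"
        )
    records: list[MorphRecord] = []
    rejected: list[str] = []
    for i, row in df.iterrows():
        try:
            date = _dt.date.fromisoformat(str(row["date"]))
            age = row.get("age_class")
            season = row.get("season")
            age = None if pd.isna(age) or str(age).strip() == "" else str(age)
            season = (
                None if pd.isna(season) or str(season).strip() == "" else str(season)
            )
            if age is None:
                age = assign_age_class(float(row["length_cm"]), cutoffs)
            if season is None:
                season = assign_season(date, cutoffs)
            rec = MorphRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                date=date,
                cod_class=str(row["cod_class"]),
                mass=float(row["mass_kg"]),
                length=float(row["length_cm"]),
                girth=_opt_float(row["girth_cm"]),
                blubber_dorsal=_opt_float(row["blubber_dorsal_mm"]),
                blubber_lateral=_opt_float(row["blubber_lateral_mm"]),
                blubber_ventral=_opt_float(row["blubber_ventral_mm"]),
                age_class=age,
                season=season,
            )
        except (ValueError, KeyError) as exc:
            msg = f"row {i}: {exc}"
            if on_bad_row == "raise":
                raise SchemaError(msg) from exc
            rejected.append(msg)
            continue
        records.append(rec)
    return records, rejected
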