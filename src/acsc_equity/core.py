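"""Domain types, tabular readers and stratified tabulation for ACSC encounters.

Everything downstream (catchment construction, expected counts, equity
scoring) operates on three validated tables:

* encounter-level hospital/ED visit records with patient demographics,
  a diagnosis code and the patient's census tract of residence;
* census-tract population counts broken down by stratum (age band x
  race/ethnicity x gender), ACS style;
* condition prevalence entries, either at full stratum granularity or as
  marginals (race-only, age-only, overall).

A *stratum* is one cell of the demographic grid in which all counting
happens; under the default 3 age bands x 4 race/ethnicity categories x
2 genders there are 24 cells. Age bands are half-open integer intervals
``[lo, hi)`` so that labels like "20-44 / 45-64 / 65+" are unambiguous at
their boundaries.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "AgeBand",
    "Stratum",
    "ConditionConfig",
    "SchemaError",
    "RowValidationError",
    "DuplicateKeyError",
    "ReadResult",
    "read_encounters",
    "read_population",
    "read_prevalence",
    "write_table",
    "assign_stratum",
    "add_age_bands",
    "filter_encounters",
    "tabulate_observed",
    "ENCOUNTER_COLUMNS",
    "POPULATION_COLUMNS",
    "PREVALENCE_COLUMNS",
]

ENCOUNTER_COLUMNS = (
    "patient_id",
    "encounter_id",
    "date",
    "facility_id",
    "diagnosis_code",
    "tract_id",
    "age",
    "gender",
    "race_ethnicity",
)
POPULATION_COLUMNS = ("tract_id", "age_band", "race", "gender", "population")
PREVALENCE_COLUMNS = ("condition", "age_band", "race", "gender", "prevalence", "source")


class SchemaError(ValueError):
    """A required column is missing or the file cannot be read as a table."""


class RowValidationError(ValueError):
    """One or more rows violate an invariant; messages carry CSV row numbers."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        preview = "; ".join(self.messages[:5])
        more = "" if len(self.messages) <= 5 else f" (+{len(self.messages) - 5} more)"
        super().__init__(f"{len(self.messages)} invalid row(s): {preview}{more}")


class DuplicateKeyError(ValueError):
    """Duplicate (tract, stratum) or encounter_id keys within one table."""


@dataclasses.dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[lo, hi)`` in integer years; ``hi=None`` means open-ended."""

    lo: int
    hi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lo}")
        if self.hi is not None and self.hi <= self.lo:
            raise ValueError(f"age band upper bound must exceed lower bound: [{self.lo}, {self.hi})")

    @property
    def label(self) -> str:
        return f"{self.lo}+" if self.hi is None else f"{self.lo}-{self.hi - 1}"

    def contains(self, age: int) -> bool:
        return age >= self.lo and (self.hi is None or age < self.hi)

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        """Parse a band label: ``"20-44"`` -> [20, 45), ``"65+"`` -> [65, inf)."""
        text = str(text).strip()
        if text.endswith("+"):
            return cls(int(text[:-1]), None)
        lo, _, hi = text.partition("-")
        if not _:
            raise ValueError(f"cannot parse age band label {text!r}")
        return cls(int(lo), int(hi) + 1)


@dataclasses.dataclass(frozen=True, order=True)
class Stratum:
    """One age-band x race/ethnicity x gender cell of the demographic grid."""

    age_band: AgeBand
    race: str
    gender: str

    @property
    def label(self) -> str:
        return f"{self.age_band.label}|{self.race}|{self.gender}"


def _coerce_band(value) -> AgeBand:
    if isinstance(value, AgeBand):
        return value
    if isinstance(value, str):
        return AgeBand.parse(value)
    if isinstance(value, Mapping):
        return AgeBand(**value)
    lo, hi = value
    return AgeBand(int(lo), None if hi in (None, "", "+") else int(hi))


DEFAULT_RACES = ("AA", "Hispanic", "White", "Asian/Other")
DEFAULT_GENDERS = ("F", "M")


class ConditionConfig(BaseModel):
    """Run configuration: condition definition, stratification, window, facility.

    ``code_prefixes`` are ICD-10-CM prefixes matched against the start of each
    diagnosis code (``"J45"`` matches ``"J45.901"``), the standard way ACSC
    condition sets are specified. ``race_map``/``gender_map`` normalize raw EHR
    labels onto the configured category sets; configured categories always map
    to themselves, any other unmapped label is a validation error rather than a
    silent "Other". The analysis window is half-open ``[start, end)``.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    condition: str
    code_prefixes: tuple[str, ...]
    window_start: dt.date
    window_end: dt.date
    facility_id: str
    age_bands: tuple[AgeBand, ...] = (AgeBand(20, 45), AgeBand(45, 65), AgeBand(65, None))
    races: tuple[str, ...] = DEFAULT_RACES
    genders: tuple[str, ...] = DEFAULT_GENDERS
    race_map: dict[str, str] = {}
    gender_map: dict[str, str] = {}
    catchment_threshold: float = 0.80
    catchment_basis: Literal["all-cause", "condition"] = "all-cause"
    min_expected: float = 0.0
    encounter_class: Optional[str] = None
    index_weighting: Literal["excess", "all"] = "excess"

    @field_validator("age_bands", mode="before")
    @classmethod
    def _parse_bands(cls, v):
        return tuple(_coerce_band(b) for b in v)

    @model_validator(mode="after")
    def _check(self):
        if not self.code_prefixes:
            raise ValueError("diagnosis code prefix set must be non-empty")
        if self.window_start >= self.window_end:
            raise ValueError("analysis window start must precede end")
        if not (0.0 < self.catchment_threshold <= 1.0):
            raise ValueError("catchment threshold must lie in (0, 1]")
        if self.min_expected < 0:
            raise ValueError("minimum-expected flag threshold must be >= 0")
        bands = self.age_bands
        for a, b in zip(bands, bands[1:]):
            if a.hi is None or a.hi != b.lo:
                raise ValueError("age bands must be contiguous and non-overlapping")
        if len(set(self.races)) != len(self.races) or len(set(self.genders)) != len(self.genders):
            raise ValueError("race and gender category lists must be unique")
        for raw, cat in self.race_map.items():
            if cat not in self.races:
                raise ValueError(f"race_map target {cat!r} is not a configured category")
        for raw, cat in self.gender_map.items():
            if cat not in self.genders:
                raise ValueError(f"gender_map target {cat!r} is not a configured category")
        return self

    # -- stratification helpers -------------------------------------------------

    def band_of(self, age: int) -> Optional[AgeBand]:
        for band in self.age_bands:
            if band.contains(age):
                return band
        return None

    def full_race_map(self) -> dict[str, str]:
        out = {r: r for r in self.races}
        out.update(self.race_map)
        return out

    def full_gender_map(self) -> dict[str, str]:
        out = {g: g for g in self.genders}
        out.update(self.gender_map)
        return out

    def stratum_grid(self) -> list[Stratum]:
        return [
            Stratum(b, r, g)
            for b in self.age_bands
            for r in self.races
            for g in self.genders
        ]

    def grid_index(self) -> pd.MultiIndex:
        grid = self.stratum_grid()
        return pd.MultiIndex.from_tuples(
            [(s.age_band.label, s.race, s.gender) for s in grid],
            names=["age_band", "race", "gender"],
        )

    def band_labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.age_bands)

    # -- serialization ----------------------------------------------------------

    def to_dict(self) -> dict:
        d = self.model_dump(mode="json")
        d["age_bands"] = [b.label for b in self.age_bands]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConditionConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_window(self, start: dt.date, end: dt.date) -> "ConditionConfig":
        return self.model_copy(update={"window_start": start, "window_end": end})


@dataclasses.dataclass
class ReadResult:
    """A validated table plus the rows rejected during validation.

    ``rejected`` has the original columns plus ``row`` (1-based CSV line
    number, header = line 1) and ``reason``.
    """

    data: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise SchemaError(f"{path}: cannot be read as CSV: {exc}") from exc
    _require_columns(df, required, path)
    return df


def _finish(df: pd.DataFrame, reasons: pd.Series, strict: bool) -> ReadResult:
    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad]
    if strict and bad.any():
        msgs = [f"row {int(r.row)}: {r.reason}" for r in rejected.itertuples()]
        raise RowValidationError(msgs)
    return ReadResult(df.loc[~bad].reset_index(drop=True), rejected.reset_index(drop=True))


def read_encounters(path: str | Path, config: ConditionConfig, *, strict: bool = True) -> ReadResult:
    """Read and validate encounter records, normalizing race and gender labels.

    With ``strict=True`` (default) any invalid row raises
    :class:`RowValidationError` naming the offending CSV rows; with
    ``strict=False`` invalid rows are collected into ``result.rejected``
    for the data-quality report instead.
    """
    df = _read_csv(path, ENCOUNTER_COLUMNS)
    df["row"] = np.arange(2, len(df) + 2)  # CSV line numbers; header is line 1
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask & (reasons == "")
        reasons[mask] = reason

    for col in ("patient_id", "encounter_id", "facility_id", "tract_id"):
        flag(df[col].str.strip() == "", f"empty {col}")

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    flag(dates.isna(), "unparseable date (ISO-8601 required)")

    ages = pd.to_numeric(df["age"], errors="coerce")
    bad_age = ages.isna() | (ages < 0) | (ages != ages.round())
    flag(bad_age, "age must be a non-negative integer")

    race_map = config.full_race_map()
    races = df["race_ethnicity"].map(race_map)
    flag(races.isna(), "unknown race/ethnicity label with no config mapping")

    gender_map = config.full_gender_map()
    genders = df["gender"].map(gender_map)
    flag(genders.isna(), "unknown gender label with no config mapping")

    flag(df["encounter_id"].duplicated(keep="first"), "duplicate encounter_id")

    df["date"] = dates
    df["age"] = ages.astype("Int64")
    df["race_ethnicity"] = races.fillna(df["race_ethnicity"])
    df["gender"] = genders.fillna(df["gender"])
    out = _finish(df, reasons, strict)
    out.data["age"] = out.data["age"].astype(int)
    return out


def read_population(path: str | Path, config: ConditionConfig, *, strict: bool = True) -> ReadResult:
    """Read census-tract population counts by stratum (ACS-style long table)."""
    df = _read_csv(path, POPULATION_COLUMNS)
    df["row"] = np.arange(2, len(df) + 2)
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        reasons[mask & (reasons == "")] = reason

    flag(df["tract_id"].str.strip() == "", "empty tract_id")
    flag(~df["age_band"].isin(config.band_labels()), "age_band label not in configured bands")
    flag(~df["race"].isin(config.races), "race label not in configured categories")
    flag(~df["gender"].isin(config.genders), "gender label not in configured categories")

    pops = pd.to_numeric(df["population"], errors="coerce")
    flag(pops.isna() | (pops < 0), "population must be a non-negative number")
    df["population"] = pops

    dup = df.duplicated(subset=["tract_id", "age_band", "race", "gender"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["tract_id", "age_band", "race", "gender"]].drop_duplicates()
        raise DuplicateKeyError(
            f"{path}: duplicate (tract, stratum) rows for keys "
            + "; ".join("/".join(map(str, k)) for k in keys.itertuples(index=False))
        )
    return _finish(df, reasons, strict)


def read_prevalence(path: str | Path, config: ConditionConfig, *, strict: bool = True) -> ReadResult:
    """Read condition prevalence entries at stratum or marginal granularity.

    Empty ``age_band``/``race``/``gender`` cells mark a marginal entry; a row
    with all three empty is the overall prevalence, which must exist for the
    configured condition.
    """
    df = _read_csv(path, PREVALENCE_COLUMNS[:-1])  # source column optional
    if "source" not in df.columns:
        df["source"] = ""
    df["row"] = np.arange(2, len(df) + 2)
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        reasons[mask & (reasons == "")] = reason

    flag(df["condition"].str.strip() == "", "empty condition")
    nonempty_band = df["age_band"].str.strip() != ""
    flag(nonempty_band & ~df["age_band"].isin(config.band_labels()), "age_band label not in configured bands")
    nonempty_race = df["race"].str.strip() != ""
    flag(nonempty_race & ~df["race"].isin(config.races), "race label not in configured categories")
    nonempty_gender = df["gender"].str.strip() != ""
    flag(nonempty_gender & ~df["gender"].isin(config.genders), "gender label not in configured categories")

    prev = pd.to_numeric(df["prevalence"], errors="coerce")
    flag(prev.isna() | (prev < 0) | (prev > 1), "prevalence must lie in [0, 1]")
    df["prevalence"] = prev

    result = _finish(df, reasons, strict)
    data = result.data
    overall = (
        (data["condition"] == config.condition)
        & (data["age_band"].str.strip() == "")
        & (data["race"].str.strip() == "")
        & (data["gender"].str.strip() == "")
    )
    if not overall.any():
        raise RowValidationError(
            [f"no overall prevalence entry for configured condition {config.condition!r}"]
        )
    return result


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated table back to CSV (UTF-8, ISO dates, round-trip exact)."""
    out = df.drop(columns=[c for c in ("row",) if c in df.columns])
    if "date" in out.columns and np.issubdtype(out["date"].dtype, np.datetime64):
        out = out.assign(date=out["date"].dt.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.17g")


# -- stratum assignment and tabulation ------------------------------------------


def assign_stratum(age: int, gender: str, race: str, config: ConditionConfig) -> Optional[Stratum]:
    """Map normalized demographics to the unique stratum containing ``age``.

    Returns ``None`` for ages outside the configured analysis range; callers
    must treat such records as flagged (excluded from counting, reported in
    the data-quality output), never silently binned.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if race not in config.races:
        raise ValueError(f"race label {race!r} is not a configured category")
    if gender not in config.genders:
        raise ValueError(f"gender label {gender!r} is not a configured category")
    band = config.band_of(age)
    return None if band is None else Stratum(band, race, gender)


def add_age_bands(df: pd.DataFrame, config: ConditionConfig) -> pd.DataFrame:
    """Add an ``age_band`` label column; out-of-range ages get NaN."""
    bands = config.age_bands
    edges = [b.lo for b in bands] + [np.inf if bands[-1].hi is None else bands[-1].hi]
    labels = config.band_labels()
    out = df.copy()
    out["age_band"] = pd.cut(out["age"], bins=edges, right=False, labels=labels).astype(object)
    return out


def filter_encounters(
    encounters: pd.DataFrame,
    config: ConditionConfig,
    catchment=None,
    *,
    diagnosis: bool = True,
) -> pd.DataFrame:
    """Apply the analysis filters: diagnosis prefix, window, facility, catchment.

    ``catchment`` may be a :class:`~acsc_equity.catchment.CatchmentArea` or any
    container of tract ids; ``None`` skips the tract filter. The window is
    half-open ``[start, end)``.
    """
    df = encounters
    mask = df["facility_id"] == config.facility_id
    start = pd.Timestamp(config.window_start)
    end = pd.Timestamp(config.window_end)
    mask &= (df["date"] >= start) & (df["date"] < end)
    if diagnosis:
        mask &= df["diagnosis_code"].str.startswith(tuple(config.code_prefixes))
    if config.encounter_class is not None:
        if "encounter_class" not in df.columns:
            raise SchemaError(
                "config requests an encounter_class filter but the encounters "
                "table has no encounter_class column"
            )
        mask &= df["encounter_class"] == config.encounter_class
    if catchment is not None:
        tracts = set(getattr(catchment, "tract_ids", catchment))
        mask &= df["tract_id"].isin(tracts)
    return df.loc[mask]


def tabulate_observed(
    encounters: pd.DataFrame,
    catchment,
    config: ConditionConfig,
) -> pd.DataFrame:
    """Per-stratum observed encounter (``observed``) and distinct patient
    (``patients``) counts over the filtered, catchment-restricted table.

    Returns a frame indexed by the full stratum grid (zero-filled), with
    attrs ``n_filtered`` (rows surviving the filters), ``n_out_of_range``
    (in-filter rows whose age falls outside the configured bands; excluded
    from counts, reported separately), ``distinct_patients`` and ``empty``
    (True when the filtered table is empty — a warning, not an error).
    A patient is counted once per stratum they appear in: a patient ageing
    across a band boundary within the window contributes to both strata.
    """
    filtered = filter_encounters(encounters, config, catchment)
    banded = add_age_bands(filtered, config)
    out_of_range = banded[banded["age_band"].isna()]
    in_range = banded.dropna(subset=["age_band"])

    grouped = in_range.groupby(["age_band", "race_ethnicity", "gender"], observed=True).agg(
        observed=("encounter_id", "size"),
        patients=("patient_id", "nunique"),
    )
    grouped.index.names = ["age_band", "race", "gender"]
    table = grouped.reindex(config.grid_index(), fill_value=0).astype(int)
    table.attrs["n_filtered"] = int(len(filtered))
    table.attrs["n_out_of_range"] = int(len(out_of_range))
    table.attrs["distinct_patients"] = int(in_range["patient_id"].nunique())
    table.attrs["empty"] = bool(len(in_range) == 0)
    table.attrs["out_of_range_rows"] = out_of_range.drop(columns=["age_band"])
    return table
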