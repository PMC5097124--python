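"""Reading, validating and writing the tabular inputs of the pipeline.

The protected-area (PA) table is a comma-separated file with one row per PA
and the column names of :class:`PARecord`; missing values are empty cells.
Spend and multiplier estimates are one-column tables (an optional ``source``
column is ignored). Category-I PAs, where tourism is largely prohibited, are
dropped at read time with a logged count so that the modelling layer never
sees them.
"""

from __future__ import annotations

import logging
import math
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ValidationError, model_validator

logger = logging.getLogger("elevisits.io")

Region = Literal["central", "east", "south", "west"]
REGIONS: tuple[str, ...] = ("central", "east", "south", "west")

#: Column order of the PA table on disk.
PA_COLUMNS = [
    "pa_id", "name", "country", "region", "iucn_category", "area_km2",
    "visits", "elephant_pop_mean", "elephant_pop_sd", "elephant_pop_lo",
    "elephant_pop_hi", "censused_area_km2", "forest", "lion",
    "natural_attractiveness", "nearby_population", "accessibility_minutes",
    "country_ppp", "poach_decline_rate", "current_spend_km2",
]


class DataValidationError(ValueError):
    """A table row violated a record invariant; carries pa_id and field."""


class FormatError(ValueError):
    """The input file could not be parsed as a delimited table."""


class PARecord(BaseModel):
    """One protected area: visits, elephant population and covariates.

    Elephant population uncertainty comes in exactly one of three forms:
    a standard deviation (``elephant_pop_sd``), a range interpreted as a
    95% interval (``elephant_pop_lo``/``elephant_pop_hi``), or nothing
    (the sd is imputed inside the model).
    """

    pa_id: str
    name: str
    country: str
    region: Region
    iucn_category: Literal["II", "III", "IV", "V", "VI"]
    area_km2: float
    visits: Optional[float] = None
    elephant_pop_mean: Optional[float] = None
    elephant_pop_sd: Optional[float] = None
    elephant_pop_lo: Optional[float] = None
    elephant_pop_hi: Optional[float] = None
    censused_area_km2: Optional[float] = None
    forest: bool
    lion: bool
    natural_attractiveness: int
    nearby_population: float
    accessibility_minutes: float
    country_ppp: float
    poach_decline_rate: float
    current_spend_km2: Optional[float] = None

    @model_validator(mode="after")
    def _invariants(self) -> "PARecord":
        if self.area_km2 <= 0:
            raise ValueError("area_km2 must be positive")
        if self.visits is not None and self.visits < 0:
            raise ValueError("visits must be nonnegative")
        has_sd = self.elephant_pop_sd is not None
        has_lo = self.elephant_pop_lo is not None
        has_hi = self.elephant_pop_hi is not None
        if has_lo != has_hi:
            raise ValueError("elephant_pop_lo and elephant_pop_hi must be given together")
        if has_sd and has_lo:
            raise ValueError("sd-form and range-form uncertainty are mutually exclusive")
        if has_lo and self.elephant_pop_lo > self.elephant_pop_hi:
            raise ValueError("elephant_pop_lo must not exceed elephant_pop_hi")
        if has_sd and self.elephant_pop_sd < 0:
            raise ValueError("elephant_pop_sd must be nonnegative")
        if self.elephant_pop_mean is not None:
            if self.elephant_pop_mean < 0:
                raise ValueError("elephant_pop_mean must be nonnegative")
            if self.censused_area_km2 is None or self.censused_area_km2 <= 0:
                raise ValueError("censused_area_km2 must be positive when a population is present")
        if not (1 <= self.natural_attractiveness <= 5):
            raise ValueError("natural_attractiveness must be in 1..5")
        for fld in ("nearby_population", "accessibility_minutes", "country_ppp"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        if not (0.0 <= self.poach_decline_rate < 1.0):
            raise ValueError("poach_decline_rate must be in [0, 1)")
        if self.current_spend_km2 is not None and self.current_spend_km2 < 0:
            raise ValueError("current_spend_km2 must be nonnegative")
        return self

    @property
    def uncertainty_form(self) -> Literal["sd", "range", "none"]:
        if self.elephant_pop_sd is not None:
            return "sd"
        if self.elephant_pop_lo is not None:
            return "range"
        return "none"

    @property
    def has_elephants(self) -> bool:
        return self.elephant_pop_mean is not None and self.elephant_pop_mean > 0

    @property
    def observed_density(self) -> float:
        """Census population mean divided by the censused area (km^-2)."""
        if not self.has_elephants:
            return 0.0
        return self.elephant_pop_mean / self.censused_area_km2


class SpendEstimateSet(BaseModel):
    """Literature estimates of per-visit direct spend and tourism multipliers."""

    direct_spend_usd: list[float]
    multipliers: list[float]

    @model_validator(mode="after")
    def _invariants(self) -> "SpendEstimateSet":
        if any(v <= 0 for v in self.direct_spend_usd):
            raise ValueError("direct spend estimates must be positive")
        if any(m < 1 for m in self.multipliers):
            # a total-impact multiplier below 1 would imply negative indirect spend
            raise ValueError("multipliers must be >= 1")
        return self


def _cell(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def read_pa_table(path) -> list[PARecord]:
    """Read and validate a PA table; drop category-I rows with a logged count.

    Raises :class:`FormatError` for unparseable files and
    :class:`DataValidationError` (naming pa_id and field) for rows violating
    a record invariant.
    """
    try:
        df = pd.read_csv(path, dtype={"pa_id": str, "name": str, "country": str},
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in PA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path} lacks required columns: {missing_cols}")

    n_cat1 = int((df["iucn_category"].astype(str).str.strip() == "I").sum())
    if n_cat1:
        logger.info("dropped %d category I", n_cat1)
        df = df[df["iucn_category"].astype(str).str.strip() != "I"]

    records: list[PARecord] = []
    for _, row in df.iterrows():
        payload = {k: _cell(row[k]) for k in PA_COLUMNS}
        try:
            records.append(PARecord(**payload))
        except ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(p) for p in first["loc"]) or "record"
            raise DataValidationError(
                f"pa_id={payload.get('pa_id')!r} field={field}: {first['msg']}"
            ) from exc
    logger.info("read %d PA records from %s", len(records), path)
    return records


def _fmt(value) -> object:
    # repr is the shortest exact decimal form of a float: bit-stable round trip
    if isinstance(value, float):
        return repr(value)
    if value is None:
        return ""
    return value


def write_pa_table(records: list[PARecord], path) -> None:
    """Write records as CSV; ``read_pa_table`` round-trips the result exactly."""
    rows = [{k: _fmt(getattr(r, k)) for k in PA_COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=PA_COLUMNS)
    df.to_csv(path, index=False)


def _read_one_column(path, column: str) -> list[float]:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if column not in df.columns:
        raise FormatError(f"{path} lacks required column {column!r}")
    return [float(v) for v in df[column].dropna()]


def read_spend_estimates(path_direct, path_mult) -> SpendEstimateSet:
    """Read direct-spend and multiplier estimate tables (one value column each)."""
    direct = _read_one_column(path_direct, "direct_spend_usd")
    mult = _read_one_column(path_mult, "multiplier")
    try:
        out = SpendEstimateSet(direct_spend_usd=direct, multipliers=mult)
    except ValidationError as exc:
        raise DataValidationError(str(exc.errors()[0]["msg"])) from exc
    logger.info("read %d direct-spend and %d multiplier estimates", len(direct), len(mult))
    return out


def write_spend_estimates(estimates: SpendEstimateSet, path_direct, path_mult) -> None:
    pd.DataFrame({"direct_spend_usd": estimates.direct_spend_usd}).to_csv(path_direct, index=False)
    pd.DataFrame({"multiplier": estimates.multipliers}).to_csv(path_mult, index=False)
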