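"""Reading, preprocessing and summarising livestock movement records.

Two input shapes are supported:

* the *raw survey* shape, one row per survey entry (origin market -> survey
  market -> destination market), which is split into up to two directed
  movements per entry; and
* the *edge list* shape, one row per directed movement, as distributed in
  processed supplementary tables (columns ``from, to, fromc, toc, dmonth,
  type, weight, transp, intl``).

Both converge on a :class:`MovementTable`: a pandas DataFrame of canonical
movement records plus provenance counters that account for every row read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIVESTOCK_TYPES = ("cattle", "goat", "sheep", "donkey")
TRANSPORT_MODES = ("vehicle", "foot", "train")

#: canonical column -> default column name in the processed edge-list dialect
EDGE_DIALECT: dict[str, str] = {
    "from_market": "from",
    "to_market": "to",
    "from_country": "fromc",
    "to_country": "toc",
    "month": "dmonth",
    "livestock_type": "type",
    "heads": "weight",
    "transport": "transp",
    "international": "intl",
}

#: canonical column -> default column name in the node-list dialect
NODE_DIALECT: dict[str, str] = {
    "code": "name",
    "country": "cid",
    "latitude": "lat",
    "longitude": "lon",
    # optional annotation columns
    "name": "label",
    "is_survey_point": "survey",
    "border_within_50km": "border50km",
    "is_urban": "urban",
}

#: canonical column -> default column name for raw three-point survey entries
RAW_DIALECT: dict[str, str] = {
    "origin_market": "from",
    "survey_market": "survey",
    "destination_market": "to",
    "month": "dmonth",
    "livestock_type": "type",
    "heads": "weight",
    "transport": "transp",
}

#: identity dialect for files written by :func:`write_movement_table`
CANONICAL_DIALECT: dict[str, str] = {k: k for k in EDGE_DIALECT}

NA_TOKENS = ("", "NA", "N/A", "NaN", "nan", "None", ".")

_LIVESTOCK_ALIASES = {
    "cattle": "cattle", "bovine": "cattle", "cow": "cattle", "bovin": "cattle",
    "goat": "goat", "caprine": "goat",
    "sheep": "sheep", "ovine": "sheep",
    "donkey": "donkey", "ass": "donkey", "asine": "donkey",
}
_TRANSPORT_ALIASES = {
    "vehicle": "vehicle", "truck": "vehicle", "car": "vehicle",
    "foot": "foot", "on foot": "foot", "hoof": "foot", "on the hoof": "foot",
    "train": "train", "rail": "train",
}

RECORD_COLUMNS = [
    "from_market", "to_market", "from_country", "to_country",
    "month", "livestock_type", "heads", "transport", "international",
]


class DialectError(KeyError):
    """A required input column could not be resolved through the dialect."""


class NodeListError(ValueError):
    """The node list violates a structural requirement (e.g. duplicate codes)."""


@dataclass
class ProvenanceCounters:
    """Row accounting for a movement table; every input row lands in exactly
    one of *retained* or a drop counter."""

    entries_read: int = 0
    records_created: int = 0      # movements emitted by entry splitting
    entries_unsplit: int = 0      # raw entries that produced no movement
    dropped_bad_month: int = 0
    dropped_bad_value: int = 0
    dropped_incomplete: int = 0
    dropped_unmapped: int = 0
    dropped_self_loop: int = 0
    intl_flag_overridden: int = 0  # informational, not a drop

    @property
    def total_dropped(self) -> int:
        return (self.dropped_bad_month + self.dropped_bad_value
                + self.dropped_incomplete + self.dropped_unmapped
                + self.dropped_self_loop)

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def merged(self, other: "ProvenanceCounters") -> "ProvenanceCounters":
        out = ProvenanceCounters()
        for k, v in asdict(self).items():
            setattr(out, k, v + getattr(other, k))
        return out


@dataclass
class MovementTable:
    """Canonical movement records plus provenance counters.

    ``records`` has columns :data:`RECORD_COLUMNS`; ``month`` is a pandas
    monthly Period, ``heads`` a positive float in scaled units.
    """

    records: pd.DataFrame
    counters: ProvenanceCounters = field(default_factory=ProvenanceCounters)

    def __len__(self) -> int:
        return len(self.records)

    def check_conservation(self) -> None:
        """Records read (or created by splitting) must equal retained + dropped."""
        c = self.counters
        source = c.records_created if c.records_created else c.entries_read
        if source and source != len(self.records) + c.total_dropped:
            raise AssertionError(
                f"provenance mismatch: {source} source rows vs "
                f"{len(self.records)} retained + {c.total_dropped} dropped")


def _resolve(df: pd.DataFrame, dialect: Mapping[str, str], canonical: str,
             required: bool = True) -> str | None:
    col = dialect.get(canonical, canonical)
    if col in df.columns:
        return col
    if canonical in df.columns:
        return canonical
    if required:
        raise DialectError(
            f"column for {canonical!r} (mapped to {col!r}) not found; "
            f"available: {list(df.columns)}")
    return None


def _normalize_category(series: pd.Series, aliases: Mapping[str, str]) -> pd.Series:
    cleaned = series.astype("string").str.strip().str.lower()
    return cleaned.map(aliases)


def _parse_month(series: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="mixed")
    return parsed.dt.to_period("M")


def _empty_records() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})
    df["heads"] = df["heads"].astype(float)
    df["month"] = pd.PeriodIndex([], freq="M")
    return df


def read_edge_list(path: str | Path, dialect: Mapping[str, str] | None = None,
                   na_tokens: Iterable[str] = NA_TOKENS) -> MovementTable:
    """Read a processed movement edge list into a :class:`MovementTable`.

    Rows with an unparseable month, a non-positive or missing head count, or
    an unrecognised livestock/transport category are dropped and counted.
    Rows with missing endpoints or self-loops are *kept* here so that
    :func:`filter_movements` can account for them explicitly.

    The international flag is always recomputed as ``from_country !=
    to_country``; a conflicting input flag is overridden and counted.
    """
    dialect = dict(EDGE_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=list(na_tokens))
    counters = ProvenanceCounters(entries_read=len(raw))
    if raw.empty:
        return MovementTable(_empty_records(), counters)

    cols = {c: _resolve(raw, dialect, c, required=c not in ("international",))
            for c in EDGE_DIALECT}

    df = pd.DataFrame({
        "from_market": raw[cols["from_market"]].astype("string").str.strip(),
        "to_market": raw[cols["to_market"]].astype("string").str.strip(),
        "from_country": raw[cols["from_country"]].astype("string").str.strip(),
        "to_country": raw[cols["to_country"]].astype("string").str.strip(),
        "month": _parse_month(raw[cols["month"]]),
        "livestock_type": _normalize_category(raw[cols["livestock_type"]],
                                              _LIVESTOCK_ALIASES),
        "heads": pd.to_numeric(raw[cols["heads"]], errors="coerce"),
        "transport": _normalize_category(raw[cols["transport"]],
                                         _TRANSPORT_ALIASES),
    })
    df["from_market"] = df["from_market"].replace("", pd.NA)
    df["to_market"] = df["to_market"].replace("", pd.NA)

    bad_month = df["month"].isna()
    counters.dropped_bad_month = int(bad_month.sum())
    df = df[~bad_month]

    bad_value = (df["heads"].isna() | (df["heads"] <= 0)
                 | df["livestock_type"].isna() | df["transport"].isna())
    counters.dropped_bad_value = int(bad_value.sum())
    df = df[~bad_value].copy()

    df["international"] = (df["from_country"] != df["to_country"]).astype("boolean")
    df.loc[df["from_country"].isna() | df["to_country"].isna(),
           "international"] = pd.NA

    if cols["international"] is not None:
        stated = raw.loc[df.index, cols["international"]].astype("string")
        stated_bool = stated.str.strip().str.lower().map(
            {"true": True, "1": True, "yes": True, "international": True,
             "false": False, "0": False, "no": False, "national": False})
        conflict = stated_bool.notna() & df["international"].notna() \
            & (stated_bool != df["international"])
        counters.intl_flag_overridden = int(conflict.sum())
        if counters.intl_flag_overridden:
            logger.warning("overrode %d stated international flags that "
                           "conflict with the country columns",
                           counters.intl_flag_overridden)

    table = MovementTable(df.reset_index(drop=True)[RECORD_COLUMNS], counters)
    table.check_conservation()
    return table


def read_node_list(path: str | Path, dialect: Mapping[str, str] | None = None,
                   na_tokens: Iterable[str] = NA_TOKENS) -> pd.DataFrame:
    """Read the market node list.

    Returns a DataFrame indexed by market code with columns ``name, country,
    latitude, longitude, is_survey_point, border_within_50km, is_urban``.
    Duplicate codes raise :class:`NodeListError`; rows with out-of-range or
    missing coordinates are rejected (logged, counted in ``.attrs``).
    """
    dialect = dict(NODE_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=list(na_tokens))
    code_col = _resolve(raw, dialect, "code")
    country_col = _resolve(raw, dialect, "country")
    lat_col = _resolve(raw, dialect, "latitude")
    lon_col = _resolve(raw, dialect, "longitude")

    df = pd.DataFrame({
        "code": raw[code_col].astype("string").str.strip(),
        "country": raw[country_col].astype("string").str.strip(),
        "latitude": pd.to_numeric(raw[lat_col], errors="coerce"),
        "longitude": pd.to_numeric(raw[lon_col], errors="coerce"),
    })
    name_col = _resolve(raw, dialect, "name", required=False)
    df["name"] = (raw[name_col].astype("string") if name_col else df["code"])
    for canonical in ("is_survey_point", "border_within_50km", "is_urban"):
        col = _resolve(raw, dialect, canonical, required=False)
        if col:
            df[canonical] = raw[col].astype("string").str.strip().str.lower() \
                .isin(("true", "1", "yes"))
        else:
            df[canonical] = False

    dupes = df["code"][df["code"].duplicated()].unique().tolist()
    if dupes:
        raise NodeListError(f"duplicate market codes in node list: {dupes}")

    ok = (df["latitude"].between(-90, 90) & df["longitude"].between(-180, 180)
          & np.isfinite(df["latitude"]) & np.isfinite(df["longitude"]))
    rejected = int((~ok).sum())
    if rejected:
        logger.warning("rejected %d node rows with invalid coordinates", rejected)
    df = df[ok].set_index("code")
    df.attrs["rejected_rows"] = rejected
    return df[["name", "country", "latitude", "longitude",
               "is_survey_point", "border_within_50km", "is_urban"]]


def read_raw_entries(path: str | Path, dialect: Mapping[str, str] | None = None,
                     na_tokens: Iterable[str] = NA_TOKENS) -> pd.DataFrame:
    """Read raw three-point survey entries (origin, survey, destination)."""
    dialect = dict(RAW_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=list(na_tokens))
    if raw.empty:
        return pd.DataFrame(columns=list(RAW_DIALECT))
    cols = {c: _resolve(raw, dialect, c) for c in RAW_DIALECT}
    df = pd.DataFrame({
        "origin_market": raw[cols["origin_market"]].astype("string").str.strip(),
        "survey_market": raw[cols["survey_market"]].astype("string").str.strip(),
        "destination_market": raw[cols["destination_market"]].astype("string").str.strip(),
        "month": _parse_month(raw[cols["month"]]),
        "livestock_type": _normalize_category(raw[cols["livestock_type"]],
                                              _LIVESTOCK_ALIASES),
        "heads": pd.to_numeric(raw[cols["heads"]], errors="coerce"),
        "transport": _normalize_category(raw[cols["transport"]],
                                         _TRANSPORT_ALIASES),
    })
    for c in ("origin_market", "destination_market"):
        df[c] = df[c].replace("", pd.NA)
    return df


def split_survey_entry(entry: Mapping) -> list[dict]:
    """Split one raw survey entry into 0..2 directed movement records.

    An entry records a shipment origin -> survey point -> destination. A leg
    is suppressed when its outer endpoint *equals* the survey point (that
    would be a self-loop), so the output never contains one. A leg whose
    outer endpoint is missing is still emitted (with the missing endpoint)
    and is dropped later by the incomplete-movement filter, so provenance
    counters account for it explicitly.
    """
    survey = entry["survey_market"]
    attrs = {k: entry[k] for k in ("month", "livestock_type", "heads", "transport")
             if k in entry}
    out = []
    origin = entry.get("origin_market")
    dest = entry.get("destination_market")
    origin_missing = origin is None or pd.isna(origin)
    dest_missing = dest is None or pd.isna(dest)
    if origin_missing or origin != survey:
        out.append({"from_market": None if origin_missing else origin,
                    "to_market": survey, **attrs})
    if dest_missing or dest != survey:
        out.append({"from_market": survey,
                    "to_market": None if dest_missing else dest, **attrs})
    return out


def split_survey_entries(entries: pd.DataFrame,
                         markets: pd.DataFrame | None = None) -> MovementTable:
    """Vectorised splitting of a raw-entry table into a MovementTable.

    If ``markets`` (node list, indexed by code) is given, country columns are
    attached by lookup and the international flag computed; otherwise both
    are left missing.
    """
    counters = ProvenanceCounters(entries_read=len(entries))
    attrs = ["month", "livestock_type", "heads", "transport"]
    if entries.empty:
        return MovementTable(_empty_records(), counters)

    first_ok = entries["origin_market"].isna() \
        | (entries["origin_market"] != entries["survey_market"])
    second_ok = entries["destination_market"].isna() \
        | (entries["destination_market"] != entries["survey_market"])

    first = entries.loc[first_ok, attrs].copy()
    first["from_market"] = entries.loc[first_ok, "origin_market"]
    first["to_market"] = entries.loc[first_ok, "survey_market"]
    second = entries.loc[second_ok, attrs].copy()
    second["from_market"] = entries.loc[second_ok, "survey_market"]
    second["to_market"] = entries.loc[second_ok, "destination_market"]

    df = pd.concat([first, second], ignore_index=True)
    counters.records_created = len(df)
    counters.entries_unsplit = int((~first_ok & ~second_ok).sum())

    if markets is not None:
        country = markets["country"]
        df["from_country"] = df["from_market"].map(country)
        df["to_country"] = df["to_market"].map(country)
        df["international"] = (df["from_country"]
                               != df["to_country"]).astype("boolean")
        df.loc[df["from_country"].isna() | df["to_country"].isna(),
               "international"] = pd.NA
    else:
        df["from_country"] = pd.NA
        df["to_country"] = pd.NA
        df["international"] = pd.NA
    return MovementTable(df[RECORD_COLUMNS], counters)


def filter_movements(table: MovementTable,
                     geolocatable: Iterable[str]) -> MovementTable:
    """Drop incomplete, unmapped and self-loop movements, updating counters.

    Retained records have both endpoints present, both endpoints in
    ``geolocatable`` (the set of markets with coordinates), and distinct
    endpoints. Checks are applied in that order, so each dropped row is
    counted exactly once.
    """
    geoset = set(geolocatable)
    df = table.records
    counters = ProvenanceCounters(**table.counters.as_dict())

    incomplete = df["from_market"].isna() | df["to_market"].isna()
    counters.dropped_incomplete += int(incomplete.sum())
    df = df[~incomplete]

    unmapped = ~(df["from_market"].isin(geoset) & df["to_market"].isin(geoset))
    counters.dropped_unmapped += int(unmapped.sum())
    df = df[~unmapped]

    self_loop = df["from_market"] == df["to_market"]
    counters.dropped_self_loop += int(self_loop.sum())
    df = df[~self_loop]

    out = MovementTable(df.reset_index(drop=True), counters)
    out.check_conservation()
    return out


_SUMMARY_DIMENSIONS = ("movement-type", "livestock", "transport",
                       "origin-country", "destination-country",
                       "month-livestock")


def summarize_movements(table: MovementTable, dimension: str) -> pd.DataFrame:
    """Descriptive summary of movement counts (and percentages) by category.

    ``month-livestock`` returns a month x livestock-type count matrix (a
    monthly time series); all other dimensions return a table with ``count``
    and ``percent`` columns whose percentages sum to 100 up to rounding.
    """
    if dimension not in _SUMMARY_DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; "
                         f"choose from {_SUMMARY_DIMENSIONS}")
    df = table.records
    if dimension == "month-livestock":
        if df.empty:
            return pd.DataFrame(columns=list(LIVESTOCK_TYPES))
        pivot = (df.groupby(["month", "livestock_type"], observed=True)
                   .size().unstack(fill_value=0))
        return pivot.reindex(columns=[c for c in LIVESTOCK_TYPES
                                      if c in pivot.columns])

    if df.empty:
        return pd.DataFrame(columns=["count", "percent"])

    if dimension == "movement-type":
        labels = df["international"].map({True: "international", False: "national"})
        counts = labels.value_counts(dropna=True)
    else:
        col = {"livestock": "livestock_type", "transport": "transport",
               "origin-country": "from_country",
               "destination-country": "to_country"}[dimension]
        counts = df[col].value_counts(dropna=True)
    out = counts.to_frame("count")
    out["percent"] = 100.0 * out["count"] / out["count"].sum()
    return out


def write_movement_table(table: MovementTable, path: str | Path) -> None:
    """Write the canonical CSV dialect (round-trips through read_edge_list)."""
    df = table.records.copy()
    df["month"] = df["month"].astype(str)
    df.to_csv(path, index=False)
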