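"""Capture-record data model and CSV input/output.

The tabular interchange format is one row per captured individual:

``dataset,site,night,species,family,guild,time``

with an optional ``count`` column (default 1).  Times are either clock
times ``HH:MM`` (column ``time``) or integer minutes since 18:00 (column
``time_min``); clock times are mapped onto the nocturnal window so that
18:30 becomes minute 30 and 05:30 becomes minute 690.  Times are snapped
down to the start of their 30-min net-check interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .schedules import DEFAULT_CHECK_INTERVAL, NIGHT_MINUTES, Schedule


class SchemaError(ValueError):
    """Input table does not have the expected columns."""


@dataclass(frozen=True)
class CaptureRecord:
    """One captured individual (or a count of identical captures)."""

    dataset_id: str
    site_id: str
    night_id: str
    species_id: str
    family: str
    time_min: int
    count: int = 1
    guild: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.time_min < NIGHT_MINUTES:
            raise ValueError(f"time_min {self.time_min} outside [0, {NIGHT_MINUTES})")
        if self.count < 1:
            raise ValueError("count must be >= 1")


REQUIRED_COLUMNS = ("dataset", "site", "night", "species", "family")


def _clock_to_minutes(value: str) -> int:
    """Map an HH:MM clock time to minutes since 18:00.

    Returns a value in [0, 1440); the caller rejects times outside the
    nocturnal window [0, 720).
    """
    parts = str(value).strip().split(":")
    if len(parts) < 2:
        raise ValueError(f"unparseable clock time {value!r}")
    hh, mm = int(parts[0]), int(parts[1])
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ValueError(f"unparseable clock time {value!r}")
    return (hh * 60 + mm - 18 * 60) % (24 * 60)


def read_captures(
    path: str | Path,
    check_interval: int = DEFAULT_CHECK_INTERVAL,
) -> list[CaptureRecord]:
    """Read capture records from CSV, binning times to check intervals.

    Rows whose time falls outside the [18:00, 06:00) window are dropped
    with a warning (e.g. a capture logged exactly at 06:00, minute 720,
    which lies outside the half-open night).
    """
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "time_min" in frame.columns:
        time_col, is_clock = "time_min", False
    elif "time" in frame.columns:
        time_col, is_clock = "time", True
    else:
        raise SchemaError("missing time column ('time' as HH:MM or 'time_min')")

    records: list[CaptureRecord] = []
    n_rejected = 0
    for idx, row in frame.iterrows():
        raw = row[time_col]
        try:
            minutes = _clock_to_minutes(raw) if is_clock else int(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        if not 0 <= minutes < NIGHT_MINUTES:
            n_rejected += 1
            continue
        minutes -= minutes % check_interval
        count = int(row["count"]) if "count" in frame.columns else 1
        guild = row.get("guild")
        records.append(
            CaptureRecord(
                dataset_id=str(row["dataset"]),
                site_id=str(row["site"]),
                night_id=str(row["night"]),
                species_id=str(row["species"]),
                family=str(row["family"]),
                time_min=minutes,
                count=count,
                guild=None if pd.isna(guild) else str(guild),
            )
        )
    if n_rejected:
        warnings.warn(
            f"{n_rejected} record(s) outside the nocturnal window were dropped",
            stacklevel=2,
        )
    return records


def records_to_frame(records: list[CaptureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset": [r.dataset_id for r in records],
            "site": [r.site_id for r in records],
            "night": [r.night_id for r in records],
            "species": [r.species_id for r in records],
            "family": [r.family for r in records],
            "guild": [r.guild for r in records],
            "time_min": [r.time_min for r in records],
            "count": [r.count for r in records],
        }
    )


def write_captures(records: list[CaptureRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read the site table (columns site, lon, lat[, dataset])."""
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("site", "lon", "lat"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    bad = frame[(frame["lon"].abs() > 180) | (frame["lat"].abs() > 90)]
    if len(bad):
        raise ValueError(f"coordinates out of range for sites {list(bad['site'])}")
    if frame["site"].duplicated().any():
        raise ValueError("duplicate site ids in site table")
    return frame.astype({"site": str})


def filter_families(
    records: list[CaptureRecord], allowed: set[str]
) -> tuple[list[CaptureRecord], float]:
    """Keep records of the allowed families; return (records, fraction kept).

    Mirrors the usual mist-net standardisation step of restricting the
    analysis to families the method samples consistently (phyllostomids
    and vespertilionids for understory nets).
    """
    if not allowed:
        raise ValueError("allowed family set must be non-empty")
    kept = [r for r in records if r.family in allowed]
    fraction = len(kept) / len(records) if records else 1.0
    return kept, fraction


def restrict_to_schedule(
    records: list[CaptureRecord], schedule: Schedule
) -> list[CaptureRecord]:
    """Keep records whose time falls inside the schedule's windows.

    The night universe is deliberately not touched here: nights left with
    zero captures must survive as all-zero matrix rows downstream, where
    each analysis decides how to treat them.
    """
    return [r for r in records if schedule.contains(r.time_min)]


def night_universe(records: list[CaptureRecord]) -> list[tuple[str, str]]:
    """Sorted distinct (site, night) pairs present in the records."""
    return sorted({(r.site_id, r.night_id) for r in records})


@dataclass
class AbundanceMatrix:
    """Night-replicate x species count matrix.

    Thin wrapper over a pandas DataFrame with a (site, night) MultiIndex;
    ``data`` is what every downstream stage consumes.
    """

    data: pd.DataFrame
    schedule_name: str | None = None

    @property
    def n_nights(self) -> int:
        return self.data.shape[0]

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index = [f"{s}:{n}" for s, n in out.index]
        out.index.name = "site:night"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        pairs = [tuple(key.split(":", 1)) for key in frame.index]
        frame.index = pd.MultiIndex.from_tuples(pairs, names=["site", "night"])
        return cls(frame.astype(int))


def build_matrix(
    records: list[CaptureRecord],
    all_species: list[str],
    all_nights: list[tuple[str, str]] | None = None,
    schedule_name: str | None = None,
) -> AbundanceMatrix:
    """Tally records into a (site, night) x species count matrix.

    ``all_species`` must cover every species in ``records`` so that
    schedule-restricted matrices share columns with the full-night one;
    ``all_nights`` fixes the row universe (schedule restriction must not
    silently drop empty nights).
    """
    present = {r.species_id for r in records}
    missing = present - set(all_species)
    if missing:
        raise ValueError(f"records contain species not in all_species: {sorted(missing)}")
    if all_nights is None:
        all_nights = night_universe(records)
    if len(set(all_nights)) != len(all_nights):
        raise ValueError("duplicate (site, night) labels in night universe")
    index = pd.MultiIndex.from_tuples(all_nights, names=["site", "night"])
    data = pd.DataFrame(0, index=index, columns=list(all_species), dtype=int)
    for r in records:
        data.loc[(r.site_id, r.night_id), r.species_id] += r.count
    return AbundanceMatrix(data, schedule_name=schedule_name)


def convert_xlsx(path: str | Path, out: str | Path, sheet: int | str = 0) -> Path:
    """Convert an XLSX capture table to the canonical CSV interchange format."""
    frame = pd.read_excel(path, sheet_name=sheet)
    out = Path(out)
    frame.to_csv(out, index=False)
    return out
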