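"""Decoy detection-trial records and stratified detection summaries.

Incidental-detection trials place feathered decoys (eagle-carcass
surrogates) at random distances and bearings from wind turbines and record
whether operations-and-maintenance staff find them during routine work
within a month-long trial window.  This module reads and validates those
trial tables, assigns derived strata (season from a site calendar, density
quartile from fall distance), and turns the records into the stratified
detection probabilities ``p_hat = found / available`` that feed the overall
detection probability g.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "VIEWSHED_CLASSES",
    "ACTIVITIES",
    "DENSITY_QUARTILES",
    "SEASONS",
    "DecoyTrialRecord",
    "TrialSummary",
    "SeasonCalendar",
    "TrialValidationError",
    "default_calendars",
    "read_trials",
    "assign_season",
    "assign_density_quartile",
    "filter_available",
    "summarize_detection",
    "summarize_activity",
    "summaries_to_frame",
]

VIEWSHED_CLASSES = ("low", "moderate", "high")
ACTIVITIES = ("routine_inspection", "driving", "maintenance", "other")
#: distance bins each expected to hold 25% of raptor carcasses
DENSITY_QUARTILES = ("near", "near_mid", "far_mid", "far")
SEASONS = ("spring", "summer", "fall", "winter")

#: inclusive upper bounds (m) of the near / near-mid / far-mid bins
QUARTILE_BOUNDS_M = (33.0, 45.0, 61.0)
MAX_DISTANCE_M = 100.0

STRATIFIERS = ("site", "season", "viewshed_class", "density_quartile")


class TrialValidationError(ValueError):
    """A trial table row violated a record invariant; names the row."""


@dataclass(frozen=True)
class DecoyTrialRecord:
    """One decoy placement and its detection outcome.

    ``found`` implies ``available`` and a detection date on or after the
    placement date.  Distances are metres from the turbine base, truncated
    at 100 m (the nominal search radius); bearings are degrees in [0, 360).
    """

    site_id: str
    turbine_id: str
    placement_date: _dt.date
    distance_m: float
    bearing_deg: float
    viewshed_class: str
    available: bool
    found: bool
    detection_date: Optional[_dt.date] = None
    activity: Optional[str] = None

    def validate(self) -> None:
        if not 0.0 <= self.distance_m <= MAX_DISTANCE_M:
            raise TrialValidationError(
                f"distance_m={self.distance_m} outside [0, {MAX_DISTANCE_M}]"
            )
        if not 0.0 <= self.bearing_deg < 360.0:
            raise TrialValidationError(
                f"bearing_deg={self.bearing_deg} outside [0, 360)"
            )
        if self.viewshed_class not in VIEWSHED_CLASSES:
            raise TrialValidationError(
                f"viewshed_class={self.viewshed_class!r} not one of {VIEWSHED_CLASSES}"
            )
        if self.found and not self.available:
            raise TrialValidationError("found decoy marked unavailable")
        if self.found:
            if self.detection_date is None:
                raise TrialValidationError("found decoy has no detection_date")
            if self.detection_date < self.placement_date:
                raise TrialValidationError(
                    "detection_date precedes placement_date"
                )
        if self.activity is not None and self.activity not in ACTIVITIES:
            raise TrialValidationError(
                f"activity={self.activity!r} not one of {ACTIVITIES}"
            )


@dataclass(frozen=True)
class TrialSummary:
    """Detection counts and proportion for one stratum."""

    stratum_key: Mapping[str, str]
    n_available: int
    n_found: int

    @property
    def p_hat(self) -> float:
        return self.n_found / self.n_available


def _parse_monthday(s: str) -> tuple[int, int]:
    m, d = s.split("-")
    return int(m), int(d)


@dataclass
class SeasonCalendar:
    """Season date ranges for one site, as (month, day) pairs.

    Ranges are inclusive at both ends.  A range whose start falls after its
    end (e.g. Dec 16 – Mar 15) wraps the calendar-year boundary and is
    handled by splitting into two sub-ranges internally.  Feb 29 is treated
    as Feb 28 so calendars written for a common year tile leap years too.
    """

    site_id: str
    seasons: Mapping[str, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=dict
    )

    @classmethod
    def from_strings(cls, site_id: str, seasons: Mapping[str, Sequence[str]]) -> "SeasonCalendar":
        """Build from ``{"spring": ["03-16", "06-15"], ...}``."""
        parsed = {
            name: (_parse_monthday(rng[0]), _parse_monthday(rng[1]))
            for name, rng in seasons.items()
        }
        cal = cls(site_id=site_id, seasons=parsed)
        cal.validate()
        return cal

    def _segments(self, season: str) -> list[tuple[int, int]]:
        """Inclusive day-of-year segments on a common (non-leap) year."""
        ref = 2021
        (m1, d1), (m2, d2) = self.seasons[season]
        a = _dt.date(ref, m1, d1).timetuple().tm_yday
        b = _dt.date(ref, m2, d2).timetuple().tm_yday
        if a <= b:
            return [(a, b)]
        return [(a, 365), (1, b)]  # winter wrap

    def validate(self) -> None:
        covered = [False] * 366
        for season in self.seasons:
            for a, b in self._segments(season):
                for doy in range(a, b + 1):
                    if covered[doy]:
                        raise ValueError(
                            f"calendar for {self.site_id}: day-of-year {doy} "
                            f"covered by more than one season"
                        )
                    covered[doy] = True
        gaps = [d for d in range(1, 366) if not covered[d]]
        if gaps:
            raise ValueError(
                f"calendar for {self.site_id}: uncovered days-of-year {gaps[:5]}..."
                if len(gaps) > 5
                else f"calendar for {self.site_id}: uncovered days-of-year {gaps}"
            )

    def season_of(self, date: _dt.date) -> str:
        # collapse Feb 29 onto Feb 28 before computing day-of-year
        if date.month == 2 and date.day == 29:
            date = date.replace(day=28)
        doy = _dt.date(2021, date.month, date.day).timetuple().tm_yday
        for season in self.seasons:
            for a, b in self._segments(season):
                if a <= doy <= b:
                    return season
        raise ValueError(
            f"calendar for {self.site_id} has a gap at {date.isoformat()}"
        )


def default_calendars() -> dict[str, SeasonCalendar]:
    """Season calendars for the six published study sites."""
    raw = {
        "Frontier I": {
            "spring": ["03-16", "06-15"], "summer": ["06-16", "08-31"],
            "fall": ["09-01", "12-15"], "winter": ["12-16", "03-15"],
        },
        "Marble River": {
            "spring": ["04-01", "06-25"], "summer": ["06-26", "08-30"],
            "fall": ["08-31", "11-30"], "winter": ["12-01", "03-31"],
        },
        "Mountain Wind I and II": {
            "spring": ["04-01", "06-30"], "summer": ["07-01", "09-20"],
            "fall": ["09-21", "11-30"], "winter": ["12-01", "03-31"],
        },
        "Pinyon Pines I and II": {
            "spring": ["03-01", "05-31"], "summer": ["06-01", "08-31"],
            "fall": ["09-01", "11-30"], "winter": ["12-01", "02-28"],
        },
        "Shiloh I": {
            "spring": ["04-01", "06-30"], "summer": ["07-01", "09-30"],
            "fall": ["10-01", "12-31"], "winter": ["01-01", "03-31"],
        },
        "Wild Horse": {
            "spring": ["03-01", "05-31"], "summer": ["06-01", "08-31"],
            "fall": ["09-01", "11-30"], "winter": ["12-01", "02-28"],
        },
    }
    return {site: SeasonCalendar.from_strings(site, s) for site, s in raw.items()}


_REQUIRED_COLUMNS = (
    "site_id", "turbine_id", "placement_date", "distance_m", "bearing_deg",
    "viewshed_class", "available", "found", "detection_date", "activity",
)

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise TrialValidationError(f"row {row}: cannot parse {column}={value!r} as boolean")


def _parse_date(value, row: int, column: str) -> Optional[_dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise TrialValidationError(f"row {row}: unparseable {column}={value!r}") from exc


def read_trials(path) -> list[DecoyTrialRecord]:
    """Read and validate a decoy-trial CSV.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing column(s): {', '.join(missing)}")
    records: list[DecoyTrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = DecoyTrialRecord(
                site_id=str(row.site_id),
                turbine_id=str(row.turbine_id),
                placement_date=_parse_date(row.placement_date, i, "placement_date"),
                distance_m=float(row.distance_m),
                bearing_deg=float(row.bearing_deg),
                viewshed_class=str(row.viewshed_class).strip(),
                available=_parse_bool(row.available, i, "available"),
                found=_parse_bool(row.found, i, "found"),
                detection_date=_parse_date(row.detection_date, i, "detection_date"),
                activity=(str(row.activity).strip() or None),
            )
            if rec.placement_date is None:
                raise TrialValidationError("placement_date is required")
            rec.validate()
        except (TrialValidationError, ValueError) as exc:
            raise TrialValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_trials(records: Iterable[DecoyTrialRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "site_id": r.site_id,
            "turbine_id": r.turbine_id,
            "placement_date": r.placement_date.isoformat(),
            "distance_m": f"{r.distance_m:.3f}",
            "bearing_deg": f"{r.bearing_deg:.3f}",
            "viewshed_class": r.viewshed_class,
            "available": str(r.available).lower(),
            "found": str(r.found).lower(),
            "detection_date": r.detection_date.isoformat() if r.detection_date else "",
            "activity": r.activity or "",
        })
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


def assign_season(record: DecoyTrialRecord, calendar: SeasonCalendar) -> str:
    """Season whose (inclusive) date range contains the placement date."""
    if calendar.site_id != record.site_id:
        raise ValueError(
            f"calendar is for {calendar.site_id!r}, record is from {record.site_id!r}"
        )
    return calendar.season_of(record.placement_date)


def assign_density_quartile(distance_m: float) -> str:
    """Distance bin holding 25% of expected carcasses.

    Boundaries at 33/45/61 m are inclusive upper bounds of their bins:
    near ≤ 33 < near_mid ≤ 45 < far_mid ≤ 61 < far ≤ 100.
    """
    if not 0.0 <= distance_m <= MAX_DISTANCE_M:
        raise ValueError(f"distance_m={distance_m} outside [0, {MAX_DISTANCE_M}]")
    for bound, label in zip(QUARTILE_BOUNDS_M, DENSITY_QUARTILES[:3]):
        if distance_m <= bound:
            return label
    return "far"


def filter_available(
    records: Sequence[DecoyTrialRecord],
) -> tuple[list[DecoyTrialRecord], int]:
    """Drop decoys that could not be confirmed available for detection."""
    kept = [r for r in records if r.available]
    return kept, len(records) - len(kept)


def _stratum_value(
    record: DecoyTrialRecord,
    name: str,
    calendars: Optional[Mapping[str, SeasonCalendar]],
) -> str:
    if name == "site":
        return record.site_id
    if name == "viewshed_class":
        return record.viewshed_class
    if name == "density_quartile":
        return assign_density_quartile(record.distance_m)
    if name == "season":
        if calendars is None:
            raise ValueError("stratifying by season requires site calendars")
        return assign_season(record, calendars[record.site_id])
    raise ValueError(f"unknown stratifier {name!r}; expected one of {STRATIFIERS}")


def summarize_detection(
    records: Sequence[DecoyTrialRecord],
    stratifiers: Sequence[str] = (),
    calendars: Optional[Mapping[str, SeasonCalendar]] = None,
) -> list[TrialSummary]:
    """Detection proportion ``found / available`` per observed stratum.

    With no stratifiers a single global summary is returned.  Only strata
    actually observed (n_available > 0) are emitted; proportions are exact
    ratios, rounded only at presentation time.
    """
    unavailable = [r for r in records if not r.available]
    if unavailable:
        raise ValueError(
            f"{len(unavailable)} unavailable record(s); apply filter_available first"
        )
    counts: dict[tuple[str, ...], list[int]] = {}
    for rec in records:
        key = tuple(_stratum_value(rec, s, calendars) for s in stratifiers)
        n = counts.setdefault(key, [0, 0])
        n[0] += 1
        n[1] += int(rec.found)
    summaries = [
        TrialSummary(
            stratum_key=dict(zip(stratifiers, key)),
            n_available=n_avail,
            n_found=n_found,
        )
        for key, (n_avail, n_found) in counts.items()
    ]
    summaries.sort(key=lambda s: tuple(s.stratum_key.values()))
    return summaries


def summarize_activity(records: Sequence[DecoyTrialRecord]) -> pd.DataFrame:
    """Counts and proportions of O&M activity among found decoys.

    Proportions are computed over found decoys with a recorded activity
    only (activity reporting was not consistent in the field).
    """
    found_with_activity = [
        r for r in records if r.found and r.activity is not None
    ]
    if not found_with_activity:
        return pd.DataFrame(columns=["activity", "n", "proportion"])
    counts = {a: 0 for a in ACTIVITIES}
    for r in found_with_activity:
        counts[r.activity] += 1
    total = len(found_with_activity)
    df = pd.DataFrame(
        [
            {"activity": a, "n": n, "proportion": n / total}
            for a, n in counts.items()
            if n > 0
        ]
    )
    return df.sort_values("n", ascending=False, ignore_index=True)


def summaries_to_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Tidy table, one row per stratum."""
    rows = []
    for s in summaries:
        row = dict(s.stratum_key)
        row.update(n_available=s.n_available, n_found=s.n_found, p_hat=s.p_hat)
        rows.append(row)
    return pd.DataFrame(rows)
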