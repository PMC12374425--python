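"""Data model and I/O for body-worn activity-sensor exports.

Epoch-level records (5-second activity-category + intensity-count samples)
are aggregated into clock-aligned 15-minute windows carrying per-category
time fractions, summed intensity counts, derived event counts
(sit-to-stand transitions, estimated steps) and a wear-time fraction.
Windows are then sliced into the three analysis periods used throughout
the package: the full 24-hour period anchored at 22:00, the night period
(00:00-06:00) and the day period (09:00-21:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Activity-category vocabulary
# ---------------------------------------------------------------------------

#: Closed vocabulary of epoch-level activity categories (thigh-sensor output).
CATEGORIES: tuple[str, ...] = (
    "upright_standing",
    "sporadic_walking",
    "walking",
    "running",
    "moderate_intensity",
    "lying_rest",
    "lying_movement",
    "sitting",
    "cycling",
)

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}

#: Categories counted as "upright" for sit-to-stand transition detection.
_UPRIGHT = {"upright_standing", "sporadic_walking", "walking", "running",
            "moderate_intensity"}

#: Nominal cadence (steps per second) used to derive step counts from
#: ambulatory epoch categories.  These are package constants, not sensor
#: outputs; real systems report steps directly.
_STEP_RATE = {
    "sporadic_walking": 0.8,
    "walking": 1.7,
    "moderate_intensity": 2.0,
    "running": 2.8,
}

SENSOR_SITES = ("thigh", "chest")

#: Diagnosis labels accepted in a subject manifest.
DIAGNOSES = ("AD", "DLB", "MixedAD", "VCD", "HC")

MANIFEST_COLUMNS = [
    "subject_id", "diagnosis", "age", "sex",
    "antidepressant", "antipsychotic", "hypnotic", "sedative_analgesic",
    "mmse",
]


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


class IntegrityError(ValueError):
    """Record contents violate an ordering or consistency requirement."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class EpochSeries:
    """A per-subject, per-sensor sequence of fixed-length epochs.

    ``offsets`` holds each observed epoch's start in seconds after
    ``start_time``; epochs absent from the grid are non-wear.  Categories
    are stored as integer codes into :data:`CATEGORIES`.
    """

    subject_id: str
    sensor_site: str
    start_time: pd.Timestamp
    categories: np.ndarray          # int codes into CATEGORIES
    intensity: np.ndarray           # nonnegative counts
    epoch_length: float = 5.0       # seconds
    offsets: np.ndarray = field(default=None)  # seconds from start_time

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=np.int64)
        self.intensity = np.asarray(self.intensity)
        if self.offsets is None:
            self.offsets = np.arange(len(self.categories)) * self.epoch_length
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        if len(self.categories) != len(self.intensity):
            raise IntegrityError("categories and intensity differ in length")
        if len(self.offsets) != len(self.categories):
            raise IntegrityError("offsets and categories differ in length")
        if np.any(np.diff(self.offsets) <= 0):
            raise IntegrityError("epoch timestamps are not strictly increasing")
        if np.any(self.intensity < 0):
            raise IntegrityError("negative intensity counts")
        if self.sensor_site not in SENSOR_SITES:
            raise ValueError(f"unknown sensor site {self.sensor_site!r}")
        if self.categories.size and (self.categories.min() < 0
                                     or self.categories.max() >= len(CATEGORIES)):
            raise ValueError("category code out of range")

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(self.offsets, unit="s")

    def category_names(self) -> np.ndarray:
        return np.asarray(CATEGORIES, dtype=object)[self.categories]


@dataclass
class WindowSeries:
    """Clock-aligned fixed-length windows for one subject.

    Wraps a DataFrame with columns ``window_start, wear_frac, count_sum,
    sit_to_stand, step_count`` and one ``frac_<category>`` column per
    activity category.
    """

    subject_id: str
    window_length: int              # minutes
    data: pd.DataFrame

    def __post_init__(self) -> None:
        frac_cols = [f"frac_{c}" for c in CATEGORIES]
        needed = ["window_start", "wear_frac", "count_sum",
                  "sit_to_stand", "step_count"] + frac_cols
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise SchemaError(f"window data missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def frac_columns(self) -> list[str]:
        return [f"frac_{c}" for c in CATEGORIES]

    def fracs(self, category: str) -> np.ndarray:
        return self.data[f"frac_{category}"].to_numpy(dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return self.data["count_sum"].to_numpy(dtype=float)

    def modal_categories(self) -> np.ndarray:
        """Modal category name per window; '' where no wear at all."""
        f = self.data[self.frac_columns].to_numpy(dtype=float)
        modal = np.asarray(CATEGORIES, dtype=object)[np.argmax(f, axis=1)]
        modal[f.sum(axis=1) == 0] = ""
        return modal


@dataclass(frozen=True)
class PeriodDefinition:
    """Named clock-time analysis period.

    The full period runs 22:00 to 22:00 the next day; the night and day
    periods are sub-intervals of the morning/daytime that follows the
    22:00 anchor.
    """

    name: str
    start_clock: str
    end_clock: str

    @property
    def duration_minutes(self) -> int:
        s = _clock_minutes(self.start_clock)
        e = _clock_minutes(self.end_clock)
        return e - s if e > s else e - s + 24 * 60


def _clock_minutes(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


FULL_PERIOD = PeriodDefinition("full", "22:00", "22:00")
NIGHT_PERIOD = PeriodDefinition("night", "00:00", "06:00")
DAY_PERIOD = PeriodDefinition("day", "09:00", "21:00")
PERIODS = {"full": FULL_PERIOD, "night": NIGHT_PERIOD, "day": DAY_PERIOD}


# ---------------------------------------------------------------------------
# Epoch CSV I/O
# ---------------------------------------------------------------------------

EPOCH_COLUMNS = ["subject_id", "sensor_site", "timestamp_iso8601",
                 "category", "intensity"]


def read_epoch_csv(path, schema_version: str = "1") -> EpochSeries:
    """Read one subject/sensor epoch export.

    Rows out of time order are rejected (integrity error), never silently
    sorted; an unknown category string raises a ValueError naming the
    offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"epoch CSV missing columns: {missing}")
    if df.empty:
        raise IntegrityError("epoch CSV contains no rows")
    bad = ~df["category"].isin(CATEGORIES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown activity category {df['category'].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    ts = pd.to_datetime(df["timestamp_iso8601"])
    if (ts.diff().dropna() <= pd.Timedelta(0)).any():
        raise IntegrityError("timestamps not strictly increasing")
    subject_id = str(df["subject_id"].iloc[0])
    sensor_site = str(df["sensor_site"].iloc[0])
    start = ts.iloc[0]
    offsets = (ts - start).dt.total_seconds().to_numpy()
    # infer epoch length from the most common spacing
    if len(ts) > 1:
        diffs = np.diff(offsets)
        epoch_length = float(np.median(diffs))
    else:
        epoch_length = 5.0
    codes = df["category"].map(_CAT_INDEX).to_numpy(dtype=np.int64)
    return EpochSeries(
        subject_id=subject_id,
        sensor_site=sensor_site,
        start_time=start,
        categories=codes,
        intensity=df["intensity"].to_numpy(),
        epoch_length=epoch_length,
        offsets=offsets.astype(np.int64),
    )


def write_epoch_csv(epochs: EpochSeries, path) -> None:
    df = pd.DataFrame({
        "subject_id": epochs.subject_id,
        "sensor_site": epochs.sensor_site,
        "timestamp_iso8601": epochs.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "category": epochs.category_names(),
        "intensity": epochs.intensity,
    })
    df.to_csv(path, index=False)


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing columns: {missing}")
    bad = ~df["diagnosis"].isin(DIAGNOSES)
    if bad.any():
        raise ValueError(f"unknown diagnosis labels: "
                         f"{sorted(df.loc[bad, 'diagnosis'].unique())}")
    if (df["age"] <= 0).any():
        raise ValueError("manifest ages must be positive")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_window_csv(ws: WindowSeries, path) -> None:
    out = ws.data.copy()
    out.insert(0, "subject_id", ws.subject_id)
    out.to_csv(path, index=False)


def read_window_csv(path) -> list[WindowSeries]:
    """Read one or more subjects' window series from a combined CSV."""
    df = pd.read_csv(path, parse_dates=["window_start"])
    if "subject_id" not in df.columns:
        raise SchemaError("window CSV missing subject_id")
    result = []
    for sid, grp in df.groupby("subject_id", sort=False):
        starts = grp["window_start"]
        wl = 15
        if len(starts) > 1:
            wl = int(starts.diff().dropna().min().total_seconds() // 60)
        result.append(WindowSeries(str(sid), wl,
                                   grp.drop(columns=["subject_id"])))
    return result


# ---------------------------------------------------------------------------
# Window aggregation
# ---------------------------------------------------------------------------

def aggregate_to_windows(epochs: EpochSeries,
                         window_length: int = 15) -> WindowSeries:
    """Aggregate epoch records into clock-aligned fixed-length windows.

    Windows start on clock times that are multiples of ``window_length``
    past midnight; a trailing partial window is dropped.  Per window:
    ``frac_<c>`` is the observed time fraction in category c relative to
    the full window (so the fractions plus the non-wear fraction sum to
    one exactly), ``count_sum`` sums intensity, ``wear_frac`` is the
    observed share of epoch slots.  Sit-to-stand events are counted as
    sitting-to-upright transitions between grid-consecutive epochs and
    step counts are derived from ambulatory epochs via nominal cadences.
    """
    if len(epochs) == 0:
        raise IntegrityError("cannot aggregate an empty epoch series")
    win_s = window_length * 60
    slots = win_s / epochs.epoch_length
    if slots != int(slots) or slots <= 0:
        raise ValueError("window length not commensurate with epoch length")
    slots = int(slots)

    start = epochs.start_time
    midnight = start.normalize()
    first_off = (np.ceil((start - midnight).total_seconds() / win_s) * win_s
                 - (start - midnight).total_seconds())
    first_start = start + pd.Timedelta(seconds=first_off)

    # absolute epoch seconds relative to the first aligned window start
    rel = epochs.offsets - int(first_off)
    keep = rel >= 0
    rel = rel[keep]
    cats = epochs.categories[keep]
    inten = np.asarray(epochs.intensity, dtype=float)[keep]
    if rel.size == 0:
        raise IntegrityError("no epochs after the first aligned window start")

    widx = rel // win_s
    end_sec = rel[-1] + epochs.epoch_length  # recording end (observed)
    n_win = int(end_sec // win_s)            # complete windows only
    inside = widx < n_win
    widx = widx[inside].astype(np.int64)
    cats = cats[inside]
    inten = inten[inside]
    rel = rel[inside]
    if n_win < 1:
        raise IntegrityError("recording shorter than one window")

    n_cat = len(CATEGORIES)
    occ = np.zeros((n_win, n_cat))
    np.add.at(occ, (widx, cats), 1.0)
    frac = occ / slots
    count_sum = np.bincount(widx, weights=inten, minlength=n_win)
    wear = np.bincount(widx, minlength=n_win) / slots

    # sit-to-stand: sitting followed by an upright category on the next slot
    upright = np.isin(cats, [_CAT_INDEX[c] for c in _UPRIGHT])
    sitting = cats == _CAT_INDEX["sitting"]
    step_len = int(epochs.epoch_length)
    consec = np.diff(rel) == step_len
    s2s_ev = sitting[:-1] & upright[1:] & consec
    s2s = np.bincount(widx[:-1][s2s_ev], minlength=n_win).astype(float)

    rates = np.zeros(n_cat)
    for c, r in _STEP_RATE.items():
        rates[_CAT_INDEX[c]] = r
    steps = np.bincount(widx, weights=rates[cats] * epochs.epoch_length,
                        minlength=n_win)

    data = pd.DataFrame({
        "window_start": first_start + pd.to_timedelta(
            np.arange(n_win) * win_s, unit="s"),
        "wear_frac": wear,
        "count_sum": count_sum,
        "sit_to_stand": s2s,
        "step_count": np.round(steps),
    })
    for i, c in enumerate(CATEGORIES):
        data[f"frac_{c}"] = frac[:, i]
    return WindowSeries(epochs.subject_id, window_length, data)


# ---------------------------------------------------------------------------
# Period slicing
# ---------------------------------------------------------------------------

def full_period_anchors(ws: WindowSeries) -> pd.DatetimeIndex:
    """All 22:00 anchors within the recording span (window starts)."""
    if len(ws) == 0:
        return pd.DatetimeIndex([])
    t0 = ws.data["window_start"].iloc[0]
    t1 = (ws.data["window_start"].iloc[-1]
          + pd.Timedelta(minutes=ws.window_length))
    first = t0.normalize() + pd.Timedelta(hours=22)
    if first < t0:
        first += pd.Timedelta(days=1)
    anchors = pd.date_range(first, t1, freq="1D")
    return anchors


def n_full_periods(ws: WindowSeries) -> int:
    """Number of complete 22:00-to-22:00 periods in the recording."""
    return max(0, len(full_period_anchors(ws)) - 1)


def slice_period(ws: WindowSeries, period: PeriodDefinition,
                 civil_day_index: int) -> WindowSeries:
    """Select windows of one named period of one recording day.

    Day ``d``'s full period spans 22:00 of anchor day d to 22:00 of the
    next day; the night and day sub-periods fall inside that span on the
    following morning/daytime.  Membership is decided by window start
    time in the half-open interval.  A day outside the recording yields
    an empty (not erroring) result.
    """
    anchors = full_period_anchors(ws)
    if civil_day_index < 0 or civil_day_index >= len(anchors) - 1:
        empty = ws.data.iloc[0:0]
        return WindowSeries(ws.subject_id, ws.window_length, empty)
    anchor = anchors[civil_day_index]
    if period.name == "full":
        lo, hi = anchor, anchor + pd.Timedelta(days=1)
    else:
        day_after = anchor.normalize() + pd.Timedelta(days=1)
        lo = day_after + pd.Timedelta(minutes=_clock_minutes(period.start_clock))
        hi = day_after + pd.Timedelta(minutes=_clock_minutes(period.end_clock))
    starts = ws.data["window_start"]
    sel = (starts >= lo) & (starts < hi)
    return WindowSeries(ws.subject_id, ws.window_length, ws.data.loc[sel])


def validate_day(ws: WindowSeries, min_wear: float = 0.8) -> bool:
    """True iff the full-period slice has mean wear fraction >= min_wear.

    Windows absent from the slice (e.g. a truncated recording) count as
    zero wear against the expected window count of the period.
    """
    expected = (24 * 60) // ws.window_length
    if expected <= 0:
        return False
    total_wear = float(ws.data["wear_frac"].sum())
    return total_wear / expected >= min_wear
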