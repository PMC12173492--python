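"""RFID box-stay processing: ingest, validation, seasons, meetings, occupancy.

A *box stay* is one continuous interval a tagged mouse spends inside one nest
box, recorded by the antennas at the box entrance.  All intervals are half-open
``[entry, exit)`` in UTC epoch seconds; touching intervals share no time, which
makes zero-measure boundary cases unambiguous.  A *meeting* is a maximal
interval during which two mice co-occupy the same box — the atom from which
the co-occupancy association index and all pairwise analyses are built.

Calendar operations (seasons, ISO weeks, hour of day) use a configurable fixed
UTC offset (default +1 h, central European standard time) so that no daylight-
saving ambiguity enters the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

#: default fixed offset from UTC, seconds (central European standard time)
DEFAULT_UTC_OFFSET = 3600

STAY_COLUMNS = ["mouse_id", "sex", "box_id", "entry", "exit"]
SEASON_ORDER = ["spring", "summer", "autumn", "winter"]

_SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# seasons and calendar helpers
# ---------------------------------------------------------------------------

def assign_season(t: float, utc_offset: int = DEFAULT_UTC_OFFSET
                  ) -> tuple[str, int]:
    """Map an epoch timestamp to its (season label, season year).

    Spring is March–May, summer June–August, autumn September–November, and
    the winter of a given year is December of that year plus January and
    February of the next — so a January timestamp belongs to the *previous*
    year's winter.
    """
    dt = datetime.fromtimestamp(float(t), tz=timezone(timedelta(
        seconds=utc_offset)))
    label = _SEASON_OF_MONTH[dt.month]
    year = dt.year
    if label == "winter" and dt.month in (1, 2):
        year -= 1
    return label, year


def season_window(label: str, year: int,
                  utc_offset: int = DEFAULT_UTC_OFFSET) -> tuple[float, float]:
    """Return the half-open ``[start, end)`` epoch span of a season."""
    tz = timezone(timedelta(seconds=utc_offset))
    starts = {"spring": (year, 3), "summer": (year, 6),
              "autumn": (year, 9), "winter": (year, 12)}
    if label not in starts:
        raise ValueError(f"unknown season {label!r}")
    y, m = starts[label]
    start = datetime(y, m, 1, tzinfo=tz)
    m_end = m + 3
    y_end = y + (m_end - 1) // 12
    m_end = (m_end - 1) % 12 + 1
    end = datetime(y_end, m_end, 1, tzinfo=tz)
    return start.timestamp(), end.timestamp()


def seasons_in_range(start: float, end: float,
                     utc_offset: int = DEFAULT_UTC_OFFSET
                     ) -> list[tuple[str, int]]:
    """Chronological (label, year) list of seasons overlapping [start, end)."""
    out: list[tuple[str, int]] = []
    t = float(start)
    while t < end:
        key = assign_season(t, utc_offset)
        if not out or out[-1] != key:
            out.append(key)
        t = season_window(*key, utc_offset=utc_offset)[1]
    return out


def hour_of_day(t: np.ndarray | float,
                utc_offset: int = DEFAULT_UTC_OFFSET) -> np.ndarray:
    """Fractional local hour of day in [0, 24) for epoch timestamps."""
    return (np.asarray(t, dtype=float) + utc_offset) % 86400.0 / 3600.0


# ---------------------------------------------------------------------------
# ingest and validation
# ---------------------------------------------------------------------------

def read_stays(path, utc_offset: int = DEFAULT_UTC_OFFSET
               ) -> tuple[pd.DataFrame, dict]:
    """Read a box-stay CSV into a validated stays table.

    Expected columns: ``mouse_id,sex,box_id,entry_iso8601,exit_iso8601``.
    Zero- or negative-duration stays (RFID glitches; near-zero stays occur in
    real logs) are dropped and counted in the returned QC report.  Overlapping
    stays for a single mouse violate the physical model and raise.

    Returns ``(stays, qc)`` with stays sorted by entry time.
    """
    raw = pd.read_csv(path, dtype={"mouse_id": str, "box_id": str})
    required = {"mouse_id", "sex", "box_id", "entry_iso8601", "exit_iso8601"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"stays file missing columns: {sorted(missing)}")
    try:
        entry = pd.to_datetime(raw["entry_iso8601"], utc=True, format="ISO8601")
        exit_ = pd.to_datetime(raw["exit_iso8601"], utc=True, format="ISO8601")
    except (ValueError, pd.errors.ParserError) as e:
        raise ValidationError(f"malformed timestamp in stays file: {e}") from e
    stays = pd.DataFrame({
        "mouse_id": raw["mouse_id"],
        "sex": raw["sex"].fillna("unknown"),
        "box_id": raw["box_id"],
        "entry": entry.astype("int64") / 1e9,
        "exit": exit_.astype("int64") / 1e9,
    })
    return validate_stays(stays)


def validate_stays(stays: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop degenerate stays, verify per-mouse disjointness, sort by entry."""
    stays = stays[STAY_COLUMNS].copy()
    bad = stays["exit"] <= stays["entry"]
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero/negative-duration stays",
                      stacklevel=2)
        stays = stays[~bad]
    stays = stays.sort_values(["entry", "exit", "mouse_id"],
                              kind="mergesort").reset_index(drop=True)
    offenders = []
    for mouse, sub in stays.groupby("mouse_id", sort=False):
        e = sub["entry"].to_numpy()
        x = sub["exit"].to_numpy()
        if np.any(e[1:] < x[:-1]):
            offenders.append(str(mouse))
    if offenders:
        raise ValidationError(
            f"overlapping stays for mice: {sorted(offenders)}")
    qc = {"n_stays": int(len(stays)), "n_dropped_degenerate": n_dropped,
          "n_mice": int(stays["mouse_id"].nunique()),
          "n_boxes": int(stays["box_id"].nunique())}
    return stays, qc


def write_stays(stays: pd.DataFrame, path) -> None:
    """Write a stays table in the ingest CSV schema (ISO-8601 UTC times)."""
    out = pd.DataFrame({
        "mouse_id": stays["mouse_id"],
        "sex": stays["sex"],
        "box_id": stays["box_id"],
        "entry_iso8601": pd.to_datetime(stays["entry"], unit="s", utc=True)
            .dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
        "exit_iso8601": pd.to_datetime(stays["exit"], unit="s", utc=True)
            .dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-mouse summaries
# ---------------------------------------------------------------------------

@dataclass
class MouseSummary:
    mouse_id: str
    total_box_time: float      # seconds
    n_stays: int
    median_stay: float         # seconds
    unique_boxes: int
    favourite_box: str
    favourite_box_fraction: float
    tenure_days: float         # first entrance to last exit


def summarize_mouse(stays: pd.DataFrame) -> MouseSummary:
    """Summarise one mouse's box use.

    The favourite box is the box with maximal cumulative time; ties break by
    box id order.  Requires at least one stay.
    """
    if len(stays) == 0:
        raise ValueError("summarize_mouse requires at least one stay")
    if stays["mouse_id"].nunique() != 1:
        raise ValueError("summarize_mouse expects stays of a single mouse")
    dur = (stays["exit"] - stays["entry"]).to_numpy()
    by_box = (stays.assign(dur=dur).groupby("box_id")["dur"].sum()
              .sort_index())
    fav = by_box.index[int(np.argmax(by_box.to_numpy()))]
    total = float(dur.sum())
    return MouseSummary(
        mouse_id=str(stays["mouse_id"].iloc[0]),
        total_box_time=total,
        n_stays=int(len(stays)),
        median_stay=float(np.median(dur)),
        unique_boxes=int(by_box.size),
        favourite_box=str(fav),
        favourite_box_fraction=float(by_box.loc[fav] / total),
        tenure_days=float((stays["exit"].max() - stays["entry"].min())
                          / 86400.0),
    )


def summarize_all(stays: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse summary table over a validated stays table."""
    rows = [summarize_mouse(sub) for _, sub in
            stays.groupby("mouse_id", sort=True)]
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# meetings
# ---------------------------------------------------------------------------

def detect_meetings(stays: pd.DataFrame) -> pd.DataFrame:
    """Detect all pairwise meetings from a validated stays table.

    A meeting is a maximal half-open interval during which two mice are in the
    same box; touching stays (one exits exactly as the other enters) do not
    meet.  Pair ids are canonically ordered ``mouse_a < mouse_b``; back-to-back
    fragments caused by a mouse exiting and instantaneously re-entering are
    merged to keep meetings maximal.  Output columns:
    ``mouse_a, mouse_b, box_id, start, end`` sorted by start.
    """
    records: list[tuple[str, str, str, float, float]] = []
    for box, sub in stays.groupby("box_id", sort=True):
        sub = sub.sort_values(["entry", "exit"], kind="mergesort")
        mice = sub["mouse_id"].to_numpy()
        entries = sub["entry"].to_numpy()
        exits = sub["exit"].to_numpy()
        active: list[int] = []  # indices of stays possibly still open
        for i in range(len(sub)):
            e_i = entries[i]
            active = [j for j in active if exits[j] > e_i]
            for j in active:
                if mice[j] == mice[i]:
                    continue
                start = e_i  # entries sorted, so e_i >= entries[j]
                end = min(exits[j], exits[i])
                if end > start:
                    a, b = sorted((str(mice[i]), str(mice[j])))
                    records.append((a, b, str(box), float(start), float(end)))
            active.append(i)
    meetings = pd.DataFrame(records,
                            columns=["mouse_a", "mouse_b", "box_id",
                                     "start", "end"])
    if len(meetings) == 0:
        return meetings
    # merge touching fragments per (pair, box) to restore maximality
    meetings = meetings.sort_values(
        ["mouse_a", "mouse_b", "box_id", "start"],
        kind="mergesort").reset_index(drop=True)
    merged: list[dict] = []
    for _, row in meetings.iterrows():
        if (merged
                and merged[-1]["mouse_a"] == row["mouse_a"]
                and merged[-1]["mouse_b"] == row["mouse_b"]
                and merged[-1]["box_id"] == row["box_id"]
                and row["start"] <= merged[-1]["end"]):
            merged[-1]["end"] = max(merged[-1]["end"], row["end"])
        else:
            merged.append(row.to_dict())
    out = pd.DataFrame(merged)
    return out.sort_values(["start", "end", "mouse_a"],
                           kind="mergesort").reset_index(drop=True)


def meeting_durations(meetings: pd.DataFrame) -> pd.Series:
    """Total meeting seconds per canonical pair."""
    if len(meetings) == 0:
        return pd.Series(dtype=float)
    d = meetings["end"] - meetings["start"]
    return d.groupby([meetings["mouse_a"], meetings["mouse_b"]]).sum()


# ---------------------------------------------------------------------------
# occupancy and turnover
# ---------------------------------------------------------------------------

def occupancy_series(stays: pd.DataFrame, box_id: str, resolution: float,
                     span: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Instantaneous occupant count of one box on a regular grid.

    Returns ``(times, counts, occupied_mean)`` where counts[t] is the number
    of stays containing sample time t, and occupied_mean is the exact
    time-weighted mean occupant count conditional on the box being occupied
    (computed by an event sweep, not from the sampled grid).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    sub = stays[stays["box_id"] == box_id]
    entries = sub["entry"].to_numpy()
    exits = sub["exit"].to_numpy()
    if span is None:
        if len(sub) == 0:
            return np.array([]), np.array([]), float("nan")
        span = (float(entries.min()), float(exits.max()))
    times = np.arange(span[0], span[1], resolution)
    counts = np.zeros(len(times), dtype=int)
    if len(sub):
        # count = #entries <= t minus #exits <= t (half-open intervals)
        counts = (np.searchsorted(np.sort(entries), times, side="right")
                  - np.searchsorted(np.sort(exits), times, side="right"))
    occupied_mean = _occupied_mean_sweep(entries, exits)
    return times, counts, occupied_mean


def _occupied_mean_sweep(entries: np.ndarray, exits: np.ndarray) -> float:
    """Time-weighted mean occupant count over occupied time, by event sweep."""
    if len(entries) == 0:
        return float("nan")
    pts = np.concatenate([entries, exits])
    deltas = np.concatenate([np.ones_like(entries), -np.ones_like(exits)])
    order = np.argsort(pts, kind="mergesort")
    pts, deltas = pts[order], deltas[order]
    # collapse simultaneous events so the running count is well defined
    uniq, idx = np.unique(pts, return_index=True)
    net = np.add.reduceat(deltas, idx)
    counts = np.cumsum(net)[:-1]
    widths = np.diff(uniq)
    occ = counts > 0
    if not occ.any():
        return float("nan")
    return float(np.sum(counts[occ] * widths[occ]) / np.sum(widths[occ]))


def weekly_turnover(stays: pd.DataFrame, box_id: str,
                    window: tuple[float, float],
                    utc_offset: int = DEFAULT_UTC_OFFSET) -> float | None:
    """Mean week-to-week turnover of one box's occupant set within a window.

    The occupant set of an ISO calendar week is the set of mice with at least
    one stay touching the box that week; turnover between consecutive weeks is
    the Jaccard distance ``1 - |A ∩ B| / |A ∪ B|``.  Week pairs with both sets
    empty are skipped.  Returns None (undefined) with fewer than two
    non-empty weeks.
    """
    lo, hi = window
    sub = stays[(stays["box_id"] == box_id)
                & (stays["entry"] < hi) & (stays["exit"] > lo)]
    tz = timezone(timedelta(seconds=utc_offset))

    def iso_week(t: float) -> tuple[int, int]:
        return datetime.fromtimestamp(t, tz=tz).isocalendar()[:2]

    week_sets: dict[tuple[int, int], set] = {}
    for _, row in sub.iterrows():
        week_sets.setdefault(iso_week(max(row["entry"], lo)), set()).add(
            row["mouse_id"])
    if len(week_sets) < 2:
        return None
    # enumerate the consecutive ISO weeks spanning the observed range
    weeks = sorted(week_sets)
    ordered: list[set] = []
    y, w = weeks[0]
    while (y, w) <= weeks[-1]:
        ordered.append(week_sets.get((y, w), set()))
        w += 1
        if w > datetime(y, 12, 28).isocalendar()[1]:
            y, w = y + 1, 1
    vals = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        union = a | b
        if not union:
            continue
        vals.append(1.0 - len(a & b) / len(union))
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# diel profiles
# ---------------------------------------------------------------------------

#: named hour-of-day intervals used for time-of-day comparisons
HOUR_INTERVALS = {
    "early morning": (0, 6),
    "morning": (6, 12),
    "afternoon": (12, 16),
    "evening": (16, 24),
}


def diel_profile(timestamps, normalize: bool = False,
                 utc_offset: int = DEFAULT_UTC_OFFSET
                 ) -> tuple[np.ndarray, dict[str, float]]:
    """24-bin hour-of-day histogram plus the four named interval totals.

    With ``normalize=True`` the histogram is scaled so the modal hour equals
    1.0 (the convention used for per-individual activity heat maps).
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size == 0:
        raise ValueError("diel_profile requires at least one timestamp")
    hours = hour_of_day(ts, utc_offset)
    hist, _ = np.histogram(hours, bins=24, range=(0, 24))
    hist = hist.astype(float)
    intervals = {name: float(hist[lo:hi].sum())
                 for name, (lo, hi) in HOUR_INTERVALS.items()}
    if normalize:
        peak = hist.max()
        if peak > 0:
            hist = hist / peak
    return hist, intervals
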