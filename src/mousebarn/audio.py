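"""Vocalization detection tables, clock alignment, duty-cycle binning.

Autonomous recorders (AudioMoths) run a 55 s record / 5 s pause duty cycle, so
one analysis "minute" is a 55 s segment; segment i of a recording occupies
``[start + 60·i, start + 60·i + 55)`` in RFID time.  The recorder's onboard
clock drifts relative to the barn RFID clock; a chime generated at a known
RFID timestamp at the start and end of every recording gives two anchor pairs
through which a single affine (linear-drift) map per recording converts
detection times into the RFID frame.

Events are treated as points at their onset for all binning and alignment
(durations are kept but unused), so an event spanning a segment boundary is
never double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SEGMENT_PERIOD = 60.0   # seconds between segment starts
SEGMENT_LEN = 55.0      # recorded seconds per segment
LABELS = ("squeak", "usv")

DETECTION_COLUMNS = ["recording_id", "box_id", "onset", "offset", "label"]


@dataclass(frozen=True)
class ClockAnchors:
    """Two (audiomoth, rfid) timestamp pairs bracketing one recording."""

    start_pair: tuple[float, float]
    end_pair: tuple[float, float]

    def __post_init__(self):
        if not (self.end_pair[0] > self.start_pair[0]
                and self.end_pair[1] > self.start_pair[1]):
            raise ValueError("end anchor must be strictly later than start "
                             "anchor on both clocks")


@dataclass(frozen=True)
class Recording:
    """One duty-cycled recording session at one box."""

    recording_id: str
    box_id: str
    start: float          # RFID-frame epoch seconds
    n_segments: int
    anchors: ClockAnchors | None = None

    @property
    def end(self) -> float:
        """End of the last segment's 60 s slot (RFID frame)."""
        return self.start + SEGMENT_PERIOD * self.n_segments

    @property
    def recorded_seconds(self) -> float:
        return SEGMENT_LEN * self.n_segments

    def segment_starts(self) -> np.ndarray:
        return self.start + SEGMENT_PERIOD * np.arange(self.n_segments)

    def segment_of(self, t: np.ndarray | float) -> np.ndarray:
        """Segment index for each onset; -1 for gaps or out-of-span times."""
        t = np.asarray(t, dtype=float)
        rel = t - self.start
        idx = np.floor(rel / SEGMENT_PERIOD).astype(int)
        within = rel - idx * SEGMENT_PERIOD
        ok = (idx >= 0) & (idx < self.n_segments) & (within < SEGMENT_LEN)
        return np.where(ok, idx, -1)


def read_detections(path) -> tuple[pd.DataFrame, dict]:
    """Read a detection CSV (audiomoth frame) into a validated event table.

    Columns: ``recording_id,box_id,onset_s,offset_s,label``.  Events with
    offset <= onset are dropped with a warning; unknown labels are an error.
    Output is sorted by onset.
    """
    raw = pd.read_csv(path, dtype={"recording_id": str, "box_id": str})
    required = {"recording_id", "box_id", "onset_s", "offset_s", "label"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"detections file missing columns: {sorted(missing)}")
    unknown = set(raw["label"].unique()) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown vocalization labels: {sorted(unknown)}")
    events = pd.DataFrame({
        "recording_id": raw["recording_id"],
        "box_id": raw["box_id"],
        "onset": raw["onset_s"].astype(float),
        "offset": raw["offset_s"].astype(float),
        "label": raw["label"],
    })
    bad = events["offset"] <= events["onset"]
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} detections with offset <= onset",
                      stacklevel=2)
        events = events[~bad]
    events = events.sort_values(["onset", "offset"],
                                kind="mergesort").reset_index(drop=True)
    return events, {"n_events": int(len(events)),
                    "n_dropped_degenerate": n_dropped}


def read_anchors(path) -> dict[str, ClockAnchors]:
    """Read an anchor CSV ``recording_id,clock,event,timestamp`` into
    per-recording ClockAnchors (clock in {audiomoth, rfid}, event in
    {start, end})."""
    raw = pd.read_csv(path, dtype={"recording_id": str})
    out = {}
    for rec, sub in raw.groupby("recording_id"):
        vals = {(r["clock"], r["event"]): float(r["timestamp"])
                for _, r in sub.iterrows()}
        try:
            out[str(rec)] = ClockAnchors(
                start_pair=(vals[("audiomoth", "start")],
                            vals[("rfid", "start")]),
                end_pair=(vals[("audiomoth", "end")], vals[("rfid", "end")]))
        except KeyError as e:
            raise ValueError(
                f"recording {rec}: missing anchor row {e}") from e
    return out


def correct_clock(events: pd.DataFrame, anchors: ClockAnchors
                  ) -> pd.DataFrame:
    """Convert event times from the recorder frame to the RFID frame.

    The map is the unique affine function through the two anchor pairs
    (linear drift between the clocks).  Times outside the anchor span are
    converted by extrapolation and flagged with a warning.
    """
    (a0, r0), (a1, r1) = anchors.start_pair, anchors.end_pair
    if a1 == a0:
        raise ValueError("degenerate anchors: identical audiomoth timestamps")
    slope = (r1 - r0) / (a1 - a0)

    def to_rfid(t):
        return r0 + (np.asarray(t, dtype=float) - a0) * slope

    out = events.copy()
    onsets = events["onset"].to_numpy(dtype=float)
    n_extrap = int(np.sum((onsets < min(a0, a1)) | (onsets > max(a0, a1))))
    if n_extrap:
        warnings.warn(f"{n_extrap} events outside the anchor span were "
                      "extrapolated", stacklevel=2)
    out["onset"] = to_rfid(events["onset"])
    out["offset"] = to_rfid(events["offset"])
    return out


def bin_segments(events: pd.DataFrame, recording: Recording
                 ) -> tuple[pd.DataFrame, dict]:
    """Per-segment counts by label for one recording (RFID-frame events).

    An event belongs to the segment containing its onset.  Onsets falling in
    a 5 s duty-cycle gap cannot be genuine detections and are dropped with a
    warning, as are onsets outside the recording span.  Returns
    ``(counts, qc)`` where counts has one row per segment and one column per
    label, and retained + dropped = input.
    """
    sub = events[events["recording_id"] == recording.recording_id] \
        if "recording_id" in events.columns else events
    seg = recording.segment_of(sub["onset"].to_numpy(dtype=float)) \
        if len(sub) else np.array([], dtype=int)
    n_dropped = int(np.sum(seg < 0))
    if n_dropped:
        warnings.warn(
            f"{recording.recording_id}: dropped {n_dropped} events in "
            "duty-cycle gaps or outside the recording span", stacklevel=2)
    counts = pd.DataFrame(0, index=pd.RangeIndex(recording.n_segments,
                                                 name="segment"),
                          columns=list(LABELS))
    keep = seg >= 0
    for label in LABELS:
        mask = keep & (sub["label"].to_numpy() == label)
        counts[label] = np.bincount(seg[mask],
                                    minlength=recording.n_segments)
    qc = {"n_input": int(len(sub)), "n_retained": int(keep.sum()),
          "n_dropped": n_dropped}
    return counts, qc


def presence_fraction(counts: pd.DataFrame, label: str) -> float:
    """Percentage of recorded segments ('minutes') with >= 1 event of label."""
    if len(counts) == 0:
        raise ValueError("presence_fraction requires >= 1 segment")
    return float(100.0 * (counts[label] > 0).mean())


def write_detections(events: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "recording_id": events["recording_id"],
        "box_id": events["box_id"],
        "onset_s": events["onset"],
        "offset_s": events["offset"],
        "label": events["label"],
    })
    out.to_csv(path, index=False)


def write_anchors(anchors: dict[str, ClockAnchors], path) -> None:
    rows = []
    for rec, a in anchors.items():
        rows += [
            (rec, "audiomoth", "start", a.start_pair[0]),
            (rec, "rfid", "start", a.start_pair[1]),
            (rec, "audiomoth", "end", a.end_pair[0]),
            (rec, "rfid", "end", a.end_pair[1]),
        ]
    pd.DataFrame(rows, columns=["recording_id", "clock", "event",
                                "timestamp"]).to_csv(path, index=False)


def write_recordings(recordings: list[Recording], path) -> None:
    pd.DataFrame([
        {"recording_id": r.recording_id, "box_id": r.box_id,
         "start_epoch_s": r.start, "n_segments": r.n_segments}
        for r in recordings
    ]).to_csv(path, index=False)


def read_recordings(path, anchors: dict[str, ClockAnchors] | None = None
                    ) -> list[Recording]:
    raw = pd.read_csv(path, dtype={"recording_id": str, "box_id": str})
    return [Recording(recording_id=str(r["recording_id"]),
                      box_id=str(r["box_id"]),
                      start=float(r["start_epoch_s"]),
                      n_segments=int(r["n_segments"]),
                      anchors=(anchors or {}).get(str(r["recording_id"])))
            for _, r in raw.iterrows()]
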