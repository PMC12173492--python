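"""Synthetic barn generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a resident
population with near-balanced sexes; nest boxes on a regular grid; seasonal
social groups whose members preferentially share a set of home boxes;
crepuscular (dawn/dusk) activity rhythms; log-normal stay durations; vocal
event streams whose rate rises near box entrances/exits and with the number
of pups present; occasional joint squeak+USV bouts inside the same recorded
segment; and a recorder clock that drifts linearly against the RFID clock.

Every stochastic draw flows from one root seed through named substreams
(population, stays, vocals, drift, pups) so components can be regenerated
independently and all outputs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mousebarn.audio import ClockAnchors, Recording, SEGMENT_LEN, SEGMENT_PERIOD
from mousebarn.config import (ConfigurationError, SyntheticConfig, VocalParams,
                              substream)
from mousebarn.rfid import assign_season, season_window, seasons_in_range


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests."""

    group_assignment: dict[str, dict[str, int]] = field(default_factory=dict)
    #: (season_label, year) -> group -> home boxes, serialized by label
    group_boxes: dict[str, dict[int, list[str]]] = field(default_factory=dict)
    pup_counts: dict[str, int] = field(default_factory=dict)
    drift: dict[str, dict[str, float]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj
        with open(path, "w") as fh:
            json.dump(_clean(self.__dict__), fh, indent=1)


# ---------------------------------------------------------------------------
# population and layout
# ---------------------------------------------------------------------------

def simulate_population(config: SyntheticConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roster of mice with near-balanced sexes and a grid box layout.

    Boxes are placed row-major on a square grid with the configured spacing.
    Sexes are assigned by randomly permuting an exactly half-male/half-female
    vector (the odd mouse, if any, gets a random sex), so male and female
    counts never differ by more than one.
    """
    config.validate()
    rng = substream(config.seed, "population")
    n = config.n_mice
    sexes = ["male"] * (n // 2) + ["female"] * (n // 2)
    if n % 2:
        sexes.append("male" if rng.random() < 0.5 else "female")
    sexes = list(rng.permutation(sexes))
    roster = pd.DataFrame({
        "mouse_id": [f"M{i:04d}" for i in range(n)],
        "sex": sexes,
    })
    side = int(np.ceil(np.sqrt(config.n_boxes)))
    coords = [(col * config.box_grid_spacing, row * config.box_grid_spacing)
              for row in range(side) for col in range(side)]
    coords = coords[:config.n_boxes]
    layout = pd.DataFrame({
        "box_id": [f"B{i:02d}" for i in range(config.n_boxes)],
        "x": [c[0] for c in coords],
        "y": [c[1] for c in coords],
    })
    return roster, layout


def _plant_groups(config: SyntheticConfig, roster: pd.DataFrame,
                  layout: pd.DataFrame, season: tuple[str, int]
                  ) -> tuple[dict[str, int], dict[int, list[str]]]:
    """Deterministic per-season planted partition of mice and boxes."""
    label, year = season
    rng = substream(config.seed, f"groups/{label}/{year}")
    k = config.season_params[label].group_count
    mice = roster["mouse_id"].tolist()
    perm = rng.permutation(len(mice))
    assignment = {mice[j]: int(i % k) for i, j in enumerate(perm)}
    boxes = layout["box_id"].tolist()
    bperm = rng.permutation(len(boxes))
    group_boxes: dict[int, list[str]] = {g: [] for g in range(k)}
    for i, j in enumerate(bperm):
        group_boxes[int(i % k)].append(boxes[j])
    return assignment, group_boxes


# ---------------------------------------------------------------------------
# stays
# ---------------------------------------------------------------------------

def _diel_density(config: SyntheticConfig, grid_h: np.ndarray) -> np.ndarray:
    """Unnormalized activity density over hour-of-day (wrapped gaussians
    over a uniform floor)."""
    dens = np.full_like(grid_h, config.diel_floor)
    for center, width in config.diel_peaks:
        for wrap in (-24.0, 0.0, 24.0):
            dens += np.exp(-0.5 * ((grid_h - center + wrap) / width) ** 2)
    return dens


def _sample_times_of_day(config: SyntheticConfig, rng: np.random.Generator,
                         size: int) -> np.ndarray:
    grid = np.linspace(0.0, 24.0, 1441)
    mid = 0.5 * (grid[:-1] + grid[1:])
    dens = _diel_density(config, mid)
    cdf = np.concatenate([[0.0], np.cumsum(dens)])
    cdf /= cdf[-1]
    u = rng.random(size)
    idx = np.searchsorted(cdf, u, side="right") - 1
    idx = np.clip(idx, 0, len(mid) - 1)
    frac = (u - cdf[idx]) / np.maximum(cdf[idx + 1] - cdf[idx], 1e-300)
    return (grid[idx] + frac * (grid[idx + 1] - grid[idx])) * 3600.0


def simulate_stays(roster: pd.DataFrame, layout: pd.DataFrame,
                   config: SyntheticConfig, start: float, end: float
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate box stays for every mouse over ``[start, end)``.

    Stay start times follow an inhomogeneous process modulated by the diel
    profile; durations are log-normal with the season's configured median;
    stays that would overlap a mouse's previous stay are discarded so each
    mouse occupies at most one box at a time.  Box choice is the planted
    group structure: with probability ``box_affinity`` a stay happens in one
    of the mouse's group's home boxes, otherwise in a uniformly random other
    box; on "defection days" (drawn with the per-day switch rate) a mouse
    temporarily adopts another group's home boxes.
    """
    config.validate()
    if end - start < 86400.0:
        raise ConfigurationError("date range must cover at least one day")
    truth = GroundTruth(config=config.to_dict())
    rows: list[tuple] = []
    all_boxes = layout["box_id"].tolist()
    sex_of = dict(zip(roster["mouse_id"], roster["sex"]))
    for season in seasons_in_range(start, end):
        label, year = season
        params = config.season_params[label]
        win = season_window(label, year)
        lo, hi = max(win[0], start), min(win[1], end)
        if hi <= lo:
            continue
        assignment, group_boxes = _plant_groups(config, roster, layout,
                                                season)
        skey = f"{label}/{year}"
        truth.group_assignment[skey] = assignment
        truth.group_boxes[skey] = group_boxes
        k = params.group_count
        n_days = int(np.ceil((hi - lo) / 86400.0))
        rng = substream(config.seed, f"stays/{label}/{year}")
        mu_log = np.log(params.stay_duration_median)
        for mouse in roster["mouse_id"]:
            g = assignment[mouse]
            # transient defections: on these days the mouse uses another
            # group's home boxes
            defect_days = rng.random(n_days) < params.switch_rate
            defect_group = rng.integers(k, size=n_days)
            n_stays = rng.poisson(params.stay_rate * (hi - lo) / 3600.0)
            if n_stays == 0:
                continue
            day_idx = rng.integers(n_days, size=n_stays)
            tod = _sample_times_of_day(config, rng, n_stays)
            entries = lo + day_idx * 86400.0 + tod
            entries = np.sort(entries[entries < hi])
            durations = np.exp(mu_log + params.stay_duration_sigma
                               * rng.standard_normal(len(entries)))
            prev_exit = -np.inf
            for t0, d in zip(entries, durations):
                if t0 < prev_exit:
                    continue
                day = min(int((t0 - lo) // 86400.0), n_days - 1)
                g_today = g
                if defect_days[day] and k > 1:
                    g_today = int(defect_group[day])
                    if g_today == g:
                        g_today = (g + 1) % k
                home = group_boxes[g_today]
                if rng.random() < params.box_affinity and home:
                    box = home[rng.integers(len(home))]
                else:
                    others = [b for b in all_boxes if b not in home] or home
                    box = others[rng.integers(len(others))]
                t1 = min(t0 + d, hi)
                if t1 <= t0:
                    continue
                rows.append((mouse, sex_of[mouse], box, t0, t1))
                prev_exit = t1
    stays = pd.DataFrame(rows, columns=["mouse_id", "sex", "box_id",
                                        "entry", "exit"])
    stays = stays.sort_values(["entry", "exit", "mouse_id"],
                              kind="mergesort").reset_index(drop=True)
    return stays, truth


# ---------------------------------------------------------------------------
# recordings, pups, vocal events
# ---------------------------------------------------------------------------

def make_recordings(layout: pd.DataFrame, start_times: list[float],
                    config: SyntheticConfig, n_segments: int = 2880,
                    boxes_per_deployment: int = 4) -> list[Recording]:
    """Duty-cycled recordings: at each deployment start time, recorders are
    placed on ``boxes_per_deployment`` randomly chosen boxes (two-day
    sessions at the default 2880 segments)."""
    rng = substream(config.seed, "recordings")
    boxes = layout["box_id"].tolist()
    out = []
    i = 0
    for t0 in start_times:
        chosen = rng.choice(len(boxes), size=min(boxes_per_deployment,
                                                 len(boxes)), replace=False)
        for b in chosen:
            out.append(Recording(recording_id=f"R{i:03d}",
                                 box_id=boxes[int(b)], start=float(t0),
                                 n_segments=n_segments))
            i += 1
    return out


def make_pup_schedule(recordings: list[Recording], config: SyntheticConfig,
                      wave_means: dict[str, float] | None = None
                      ) -> dict[str, int]:
    """Per-recording pup counts in two seasonal waves.

    Pups appear in a spring wave and a late-summer wave; recordings outside
    the waves get zero pups.  Counts are Poisson with the wave's mean.
    """
    if wave_means is None:
        wave_means = {"spring": 4.0, "summer": 3.0}
    rng = substream(config.seed, "pups")
    out = {}
    for rec in recordings:
        label, _ = assign_season(rec.start)
        mean = wave_means.get(label, 0.0)
        out[rec.recording_id] = int(rng.poisson(mean)) if mean > 0 else 0
    return out


def _laplace_kernel_sum(t: np.ndarray, centers: np.ndarray, tau: float
                        ) -> np.ndarray:
    """Sum over sorted centres of exp(-|t - c|/tau), truncating each kernel
    at 40 tau so memory stays linear in the number of query points."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    half = 40.0 * tau
    lo = np.searchsorted(centers, t - half, side="left")
    hi = np.searchsorted(centers, t + half, side="right")
    for i in range(len(t)):
        if hi[i] > lo[i]:
            out[i] = np.exp(-np.abs(t[i] - centers[lo[i]:hi[i]])
                            / tau).sum()
    return out


def _box_events(stays: pd.DataFrame, box_id: str, lo: float, hi: float
                ) -> np.ndarray:
    sub = stays[stays["box_id"] == box_id]
    ev = np.concatenate([sub["entry"].to_numpy(), sub["exit"].to_numpy()])
    return np.sort(ev[(ev >= lo) & (ev < hi)])


def simulate_vocal_events(stays: pd.DataFrame, recordings: list[Recording],
                          pup_counts: dict[str, int],
                          config: SyntheticConfig) -> pd.DataFrame:
    """Simulate vocal events (RFID frame) for each recording.

    The per-second event rate is

        r(t) = [lambda0/55 + lambda_event · K(t)] · exp(beta_pup · pups)

    where K(t) sums two-sided exponential kernels (timescale ``tau_event``)
    centred ``lag_event`` seconds after each box entrance/exit.  Bouts are
    drawn by thinning and kept only if they fall inside a recorded 55 s
    segment.  With probability ``q_joint`` a bout emits a squeak *and* a USV
    in the same segment; otherwise a single call is a squeak with probability
    ratio/(1+ratio).
    """
    vp = config.vocal_params
    vp.validate()
    rng = substream(config.seed, "vocals")
    rows: list[tuple] = []
    for rec in recordings:
        pups = pup_counts.get(rec.recording_id, 0)
        pup_factor = float(np.exp(vp.beta_pup * pups))
        centers = _box_events(stays, rec.box_id, rec.start, rec.end) \
            + vp.lag_event
        base = vp.lambda0 / SEGMENT_LEN

        def kernel(t: np.ndarray) -> np.ndarray:
            if len(centers) == 0 or vp.lambda_event == 0:
                return np.zeros_like(t)
            return _laplace_kernel_sum(t, centers, vp.tau_event)

        # a sum of two-sided exponential kernels is convex between adjacent
        # centres, so its maximum is attained at a centre
        k_max = float(kernel(centers).max()) if len(centers) else 0.0
        rate_max = (base + vp.lambda_event * k_max) * pup_factor
        duration = rec.end - rec.start
        n_cand = rng.poisson(rate_max * duration)
        if n_cand == 0:
            continue
        t_cand = np.sort(rec.start + rng.uniform(0.0, duration, n_cand))
        rate = (base + vp.lambda_event * kernel(t_cand)) * pup_factor
        keep = rng.random(n_cand) < rate / rate_max
        t_keep = t_cand[keep]
        seg = rec.segment_of(t_keep)
        t_keep = t_keep[seg >= 0]
        p_squeak = vp.squeak_usv_ratio / (1.0 + vp.squeak_usv_ratio)
        for t in t_keep:
            if rng.random() < vp.q_joint:
                # joint bout: both call types inside the same segment
                seg_i = int(rec.segment_of(t))
                seg_end = rec.start + SEGMENT_PERIOD * seg_i + SEGMENT_LEN
                t2 = t + 0.05 if t + 0.1 < seg_end else t - 0.05
                rows.append((rec.recording_id, rec.box_id, t, t + 0.08,
                             "squeak"))
                rows.append((rec.recording_id, rec.box_id, t2, t2 + 0.04,
                             "usv"))
            else:
                label = "squeak" if rng.random() < p_squeak else "usv"
                dur = 0.08 if label == "squeak" else 0.04
                rows.append((rec.recording_id, rec.box_id, t, t + dur, label))
    events = pd.DataFrame(rows, columns=["recording_id", "box_id", "onset",
                                         "offset", "label"])
    return events.sort_values(["onset", "label"],
                              kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# clock drift
# ---------------------------------------------------------------------------

def inject_clock_drift(events: pd.DataFrame, recording: Recording,
                       drift_rate: float, offset: float = 0.0
                       ) -> tuple[pd.DataFrame, ClockAnchors]:
    """Convert RFID-frame detections to a drifting recorder clock.

    The recorder clock reads ``rfid + offset + drift_rate · elapsed_days``
    (elapsed from the recording start), and chime anchors are emitted at the
    recording's start and end.  The affine clock correction recovers the
    RFID frame exactly up to floating-point error.
    """
    if recording.n_segments <= 0:
        raise ValueError("recording duration must be > 0")

    def to_am(t):
        t = np.asarray(t, dtype=float)
        return t + offset + drift_rate * (t - recording.start) / 86400.0

    sub = events[events["recording_id"] == recording.recording_id].copy()
    sub["onset"] = to_am(sub["onset"])
    sub["offset"] = to_am(sub["offset"])
    anchors = ClockAnchors(
        start_pair=(float(to_am(recording.start)), float(recording.start)),
        end_pair=(float(to_am(recording.end)), float(recording.end)))
    return sub, anchors


# ---------------------------------------------------------------------------
# planted pair coupling
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig, outdir,
                     year: int = 2023, days_per_season: int = 7,
                     recordings_per_season: int = 1,
                     n_segments: int = 2880,
                     boxes_per_deployment: int = 4) -> dict:
    """Generate and write a complete synthetic dataset.

    Simulates ``days_per_season`` days at the start of each season of the
    given year (winter belongs to that year's December), places recorder
    deployments inside each simulated window, and writes the CSV schemas the
    ingest stages consume plus the ground truth as JSON.  Returns the file
    map.
    """
    import os

    from mousebarn import rfid as _rfid
    from mousebarn.audio import (write_anchors, write_detections,
                                 write_recordings)

    config.validate()
    os.makedirs(outdir, exist_ok=True)
    roster, layout = simulate_population(config)
    all_stays, all_recs = [], []
    truth = GroundTruth(config=config.to_dict())
    for label in ("spring", "summer", "autumn", "winter"):
        lo, _ = season_window(label, year)
        hi = lo + days_per_season * 86400.0
        stays, t = simulate_stays(roster, layout, config, lo, hi)
        all_stays.append(stays)
        truth.group_assignment.update(t.group_assignment)
        truth.group_boxes.update(t.group_boxes)
        rec_len_days = n_segments * SEGMENT_PERIOD / 86400.0
        usable = max(days_per_season - rec_len_days, 0.0)
        starts = [lo + (i + 0.5) / recordings_per_season * usable * 86400.0
                  for i in range(recordings_per_season)]
        all_recs.extend(make_recordings(layout, starts, config,
                                        n_segments=n_segments,
                                        boxes_per_deployment=boxes_per_deployment))
    # recording ids must be unique across seasons
    recs = [Recording(recording_id=f"R{i:03d}", box_id=r.box_id,
                      start=r.start, n_segments=r.n_segments)
            for i, r in enumerate(all_recs)]
    stays = pd.concat(all_stays, ignore_index=True).sort_values(
        ["entry", "exit", "mouse_id"], kind="mergesort").reset_index(
        drop=True)
    pups = make_pup_schedule(recs, config)
    truth.pup_counts = dict(pups)
    events = simulate_vocal_events(stays, recs, pups, config)
    drift_rng = substream(config.seed, "drift")
    det_parts, anchors = [], {}
    for rec in recs:
        offset = float(drift_rng.uniform(-60.0, 60.0))
        det, anc = inject_clock_drift(events, rec, config.drift_rate,
                                      offset=offset)
        det_parts.append(det)
        anchors[rec.recording_id] = anc
        truth.drift[rec.recording_id] = {"drift_rate": config.drift_rate,
                                         "offset": offset}
    detections = pd.concat(det_parts, ignore_index=True) if det_parts \
        else events.iloc[0:0]
    paths = {
        "stays": os.path.join(outdir, "stays.csv"),
        "detections": os.path.join(outdir, "detections.csv"),
        "anchors": os.path.join(outdir, "anchors.csv"),
        "recordings": os.path.join(outdir, "recordings.csv"),
        "layout": os.path.join(outdir, "layout.csv"),
        "pups": os.path.join(outdir, "pups.csv"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    _rfid.write_stays(stays, paths["stays"])
    write_detections(detections, paths["detections"])
    write_anchors(anchors, paths["anchors"])
    write_recordings(recs, paths["recordings"])
    layout.to_csv(paths["layout"], index=False)
    pd.DataFrame(sorted(pups.items()),
                 columns=["recording_id", "n_pups"]).to_csv(paths["pups"],
                                                            index=False)
    truth.to_json(paths["ground_truth"])
    return paths


def _recorded_subintervals(rec: Recording, lo: float, hi: float
                           ) -> list[tuple[float, float]]:
    """Intersections of [lo, hi) with the recording's 55 s segments."""
    out = []
    first = max(int(np.floor((lo - rec.start) / SEGMENT_PERIOD)), 0)
    last = min(int(np.floor((hi - rec.start) / SEGMENT_PERIOD)),
               rec.n_segments - 1)
    for i in range(first, last + 1):
        s = rec.start + SEGMENT_PERIOD * i
        a, b = max(lo, s), min(hi, s + SEGMENT_LEN)
        if b > a:
            out.append((a, b))
    return out


def _uniform_in_intervals(rng: np.random.Generator,
                          intervals: list[tuple[float, float]],
                          size: int) -> np.ndarray:
    """Uniform samples over a union of disjoint intervals."""
    if size == 0 or not intervals:
        return np.array([])
    lens = np.array([b - a for a, b in intervals])
    starts = np.array([a for a, _ in intervals])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    u = rng.uniform(0.0, cum[-1], size)
    idx = np.searchsorted(cum, u, side="right") - 1
    idx = np.clip(idx, 0, len(lens) - 1)
    return starts[idx] + (u - cum[idx])


def simulate_pair_coupling(n_pairs: int = 100, n_meetings: int = 12,
                           gamma_pair: float = 0.0, seed: int = 0,
                           mu_squeak: float = 6.0, mu_usv: float = 1.0,
                           base_duration: float = 120.0,
                           duration_sigma: float = 0.4,
                           latent_step: float = 0.6,
                           solo_duration: float = 400.0,
                           gap: float = 1200.0
                           ) -> tuple[pd.DataFrame, pd.DataFrame,
                                      list[Recording], dict]:
    """Plant a coupling between meeting vocal counts and future co-occupancy.

    Each pair carries a shared latent state z (a random walk over meeting
    index).  The latent multiplies both the pair's meeting durations
    (``base_duration · exp(duration_sigma·ε + gamma_pair·z)``) and its vocal
    rate during meetings (counts Poisson with mean ``mu · exp(gamma_pair·z)``),
    so with gamma_pair > 0 vocal counts and the subsequently accumulated
    co-occupancy index rise and fall together, while with gamma_pair = 0
    counts are independent of the COI trajectory.  Pairs live in disjoint
    boxes, each covered by its own recording, and each mouse takes a fixed
    solo stay between meetings so the COI stays below 1 and varies.

    Returns ``(stays, vocal events, recordings, truth)`` ready for
    :func:`mousebarn.rfid.detect_meetings` and
    :func:`mousebarn.vocal.build_pair_series`.
    """
    rng = np.random.default_rng(seed)
    stay_rows, event_rows, recordings = [], [], []
    truth: dict = {"gamma_pair": gamma_pair, "z": {}}
    t_origin = 1_700_000_000.0  # arbitrary epoch anchor
    for p in range(n_pairs):
        a, b = f"P{p:03d}a", f"P{p:03d}b"
        box = f"BX{p:03d}"
        sex_a = "male" if p % 2 == 0 else "female"
        sex_b = "female"
        z = np.cumsum(latent_step * rng.standard_normal(n_meetings))
        durations = base_duration * np.exp(
            duration_sigma * rng.standard_normal(n_meetings)
            + gamma_pair * z)
        t = t_origin
        rec_id = f"RP{p:03d}"
        starts, ends = [], []
        for k in range(n_meetings):
            starts.append(t)
            ends.append(t + durations[k])
            t = t + durations[k] + gap
        span = ends[-1] + 60.0 - t_origin
        n_seg = int(np.ceil(span / SEGMENT_PERIOD)) + 1
        rec = Recording(recording_id=rec_id, box_id=box,
                        start=t_origin - 30.0, n_segments=n_seg)
        recordings.append(rec)
        for k in range(n_meetings):
            s, e = starts[k], ends[k]
            stay_rows.append((a, sex_a, box, s, e))
            stay_rows.append((b, sex_b, box, s, e))
            # solo stays between meetings, in pair-private side boxes
            if k < n_meetings - 1:
                s0 = e + 10.0
                stay_rows.append((a, sex_a, f"SA{p:03d}", s0,
                                  s0 + solo_duration))
                stay_rows.append((b, sex_b, f"SB{p:03d}", s0,
                                  s0 + solo_duration))
            # vocal counts during the recorded portion of the meeting
            recorded = _recorded_subintervals(rec, s, e)
            mean_scale = float(np.exp(gamma_pair * z[k]))
            for label, mu in (("squeak", mu_squeak), ("usv", mu_usv)):
                n_ev = rng.poisson(mu * mean_scale)
                for cand in _uniform_in_intervals(rng, recorded, n_ev):
                    event_rows.append((rec_id, box, cand, cand + 0.08,
                                       label))
        truth["z"][f"{a}|{b}"] = z.tolist()
    stays = pd.DataFrame(stay_rows, columns=["mouse_id", "sex", "box_id",
                                             "entry", "exit"])
    stays = stays.sort_values(["entry", "exit", "mouse_id"],
                              kind="mergesort").reset_index(drop=True)
    events = pd.DataFrame(event_rows, columns=["recording_id", "box_id",
                                               "onset", "offset", "label"])
    events = events.sort_values("onset",
                                kind="mergesort").reset_index(drop=True)
    return stays, events, recordings, truth
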