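"""Statistics linking vocal events to social events.

Implements the bespoke procedures of the analysis: the per-minute squeak/USV
co-production permutation test, peri-event alignment of vocalizations to box
entrances and exits with randomized nulls, 60 s window fractions by season and
sex, negative-binomial count-model comparison by AIC, and per-pair Spearman
correlations between meeting vocal counts and subsequent co-occupancy, with
shuffled controls.

All permutation p-values use the add-one estimator
``p = (1 + #{null >= observed}) / (1 + n_perm)`` for a one-sided "greater"
alternative, which is valid (super-uniform under the null) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from mousebarn.audio import Recording, SEGMENT_LEN, SEGMENT_PERIOD


# ---------------------------------------------------------------------------
# co-minute permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    #: t-analog of the comparison: (observed - null mean) / null sd
    t_vs_null: float = float("nan")


def cominute_test(squeak_counts: np.ndarray, usv_counts: np.ndarray,
                  n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Test for excess co-occurrence of squeaks and USVs in the same minute.

    The observed statistic is the number of segments containing at least one
    squeak *and* at least one USV.  Each null replicate permutes the
    recording's per-segment squeak counts uniformly at random across its
    segments (squeak timestamps shifted relative to USV timestamps; the
    per-segment count multiset is preserved, USVs fixed) and recounts the
    co-occupied segments.  Under such a permutation the statistic is exactly
    hypergeometric — the overlap between a uniformly random set of
    squeak-occupied segments and the fixed USV-occupied set — which is how
    the null replicates are drawn.  One-sided (greater) add-one p-value.
    """
    s = np.asarray(squeak_counts, dtype=int)
    u = np.asarray(usv_counts, dtype=int)
    if s.shape != u.shape:
        raise ValueError("count vectors must have equal length")
    n_seg = len(s)
    if n_seg == 0:
        raise ValueError("cominute_test requires >= 1 segment")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = int(np.sum((s > 0) & (u > 0)))
    k_squeak = int(np.sum(s > 0))
    k_usv = int(np.sum(u > 0))
    rng = np.random.default_rng(seed)
    if k_squeak == 0 or k_usv == 0:
        null = np.zeros(n_perm, dtype=int)
    else:
        null = rng.hypergeometric(k_usv, n_seg - k_usv, k_squeak,
                                  size=n_perm)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    sd = null.std(ddof=1) if n_perm > 1 else 0.0
    t = (observed - null.mean()) / sd if sd > 0 else float("nan")
    return PermutationResult(observed=float(observed),
                             null_values=null.astype(float),
                             p_value=float(p), t_vs_null=float(t))


# ---------------------------------------------------------------------------
# peri-event alignment
# ---------------------------------------------------------------------------

@dataclass
class PeriEventHistogram:
    """Distribution of vocal onsets relative to box events within ±window."""

    edges: np.ndarray            # bin edges, seconds relative to event
    counts: np.ndarray           # aligned vocalizations per bin
    pct: np.ndarray              # counts as % of total aligned vocalizations
    n_events: int
    n_vocalizations: int         # total aligned contributions
    per_event: np.ndarray        # (n_events, n_bins) per-event rows

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def modal_lag(self) -> float:
        """Center of the bin with the most aligned vocalizations."""
        return float(self.centers[int(np.argmax(self.counts))])


def align_to_events(vocal_onsets, event_times, window: float = 60.0,
                    bin_width: float = 5.0) -> PeriEventHistogram:
    """Histogram of vocal onsets at signed lags around box events.

    Every vocal onset within ``[-window, +window)`` of a box event (entrance
    or exit) contributes one count at its lag; an onset near several events
    contributes to each.  Percentages are relative to the total number of
    aligned contributions.
    """
    onsets = np.sort(np.asarray(vocal_onsets, dtype=float))
    events = np.asarray(event_times, dtype=float)
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    per_event = np.zeros((len(events), n_bins), dtype=int)
    for i, t in enumerate(events):
        lo = np.searchsorted(onsets, t - window, side="left")
        hi = np.searchsorted(onsets, t + window, side="left")
        lags = onsets[lo:hi] - t
        per_event[i], _ = np.histogram(lags, bins=edges)
    counts = per_event.sum(axis=0)
    total = int(counts.sum())
    pct = 100.0 * counts / total if total > 0 else np.zeros(n_bins)
    return PeriEventHistogram(edges=edges, counts=counts, pct=pct,
                              n_events=len(events),
                              n_vocalizations=total, per_event=per_event)


@dataclass
class AlignmentNull:
    """Null peri-event histograms from time-randomized vocal onsets."""

    edges: np.ndarray
    null_counts: np.ndarray      # (n_rand, n_bins)

    def envelope(self, lower: float = 0.0, upper: float = 100.0
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin percentile envelope over the null replicates."""
        return (np.percentile(self.null_counts, lower, axis=0),
                np.percentile(self.null_counts, upper, axis=0))


def alignment_null(n_vocal: int, recording: Recording, event_times,
                   n_rand: int = 100, seed: int = 0, window: float = 60.0,
                   bin_width: float = 5.0) -> AlignmentNull:
    """Null distribution for a peri-event histogram.

    Each replicate redraws ``n_vocal`` onsets uniformly over the recording's
    *recorded* 55 s segments (count preserved; duty-cycle gaps never receive
    events) and recomputes the alignment histogram against the fixed box
    events.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    null_counts = np.zeros((n_rand, len(edges) - 1), dtype=int)
    for r in range(n_rand):
        if n_vocal > 0:
            seg = rng.integers(recording.n_segments, size=n_vocal)
            off = rng.uniform(0.0, SEGMENT_LEN, size=n_vocal)
            onsets = recording.start + SEGMENT_PERIOD * seg + off
            h = align_to_events(onsets, event_times, window=window,
                                bin_width=bin_width)
            null_counts[r] = h.counts
    return AlignmentNull(edges=edges, null_counts=null_counts)


# ---------------------------------------------------------------------------
# 60 s window fractions
# ---------------------------------------------------------------------------

def window_fractions(box_events: pd.DataFrame, vocal_onsets,
                     direction: str, window: float = 60.0,
                     group_by: tuple[str, ...] = ("season", "sex")
                     ) -> pd.DataFrame:
    """Percentage of box events with >= 1 vocalization in a 60 s window.

    ``box_events`` carries one row per entrance or exit with a ``time``
    column plus the grouping columns (typically the actor's sex and the
    season).  For entrances, "followed" means an onset in the half-open
    window ``(t, t + 60]``; for exits, "preceded" means ``[t - 60, t)`` —
    the event instant itself is excluded on the closed side so a
    simultaneous onset is never double-counted as both preceded and
    followed.  Groups with zero events are omitted.
    """
    if direction not in ("followed", "preceded"):
        raise ValueError("direction must be 'followed' or 'preceded'")
    onsets = np.sort(np.asarray(vocal_onsets, dtype=float))
    t = box_events["time"].to_numpy(dtype=float)
    if direction == "followed":
        lo = np.searchsorted(onsets, t, side="right")
        hi = np.searchsorted(onsets, t + window, side="right")
    else:
        lo = np.searchsorted(onsets, t - window, side="left")
        hi = np.searchsorted(onsets, t, side="left")
    has_vocal = hi > lo
    df = box_events.copy()
    df["has_vocal"] = has_vocal
    grouped = (df.groupby(list(group_by), observed=True)["has_vocal"]
               .agg(["mean", "size"]).reset_index())
    grouped["pct"] = 100.0 * grouped["mean"]
    grouped = grouped.rename(columns={"size": "n_events"})
    return grouped[[*group_by, "n_events", "pct"]]


# ---------------------------------------------------------------------------
# negative-binomial GLM comparison
# ---------------------------------------------------------------------------

#: the four candidate hypotheses: vocalization is seasonal, plus optionally
#: driven by adult count, sex ratio, or pup count in the recorded box
MODEL_COVARIATES = {
    "season": [],
    "season+adults": ["n_adults"],
    "season+sexratio": ["sex_ratio"],
    "season+pups": ["n_pups"],
}

ALPHA_GRID = np.logspace(np.log10(0.01), np.log10(10.0), 50)


@dataclass
class ModelFit:
    name: str
    aic: float
    llf: float
    alpha: float
    params: pd.Series
    pseudo_r2: float


@dataclass
class ModelComparison:
    models: dict[str, ModelFit]
    best: str

    def aic_table(self) -> pd.DataFrame:
        rows = [{"model": m.name, "aic": m.aic, "llf": m.llf,
                 "alpha": m.alpha, "pseudo_r2": m.pseudo_r2}
                for m in self.models.values()]
        return (pd.DataFrame(rows).sort_values("aic")
                .reset_index(drop=True))


def _design(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    seasons = sorted(table["season"].unique())
    if len(seasons) < 2:
        raise ValueError(
            "singular design: only one season present; the seasonal models "
            "require at least two seasons")
    X = pd.DataFrame({"const": 1.0}, index=table.index)
    for s in seasons[1:]:
        X[f"season[{s}]"] = (table["season"] == s).astype(float)
    for c in covariates:
        X[c] = table[c].astype(float)
    return X


def _fit_nb(y, X, offset, alpha_grid=ALPHA_GRID):
    """Profile the NB dispersion over a log-spaced grid by minimal NLL."""
    best = None
    start = None
    for alpha in alpha_grid:
        model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                       offset=offset)
        try:
            res = model.fit(start_params=start, maxiter=200)
        except (ValueError, np.linalg.LinAlgError):
            continue
        start = res.params
        if not np.isfinite(res.llf):
            continue
        if best is None or res.llf > best[0]:
            best = (res.llf, alpha, res)
    if best is None:
        raise RuntimeError("negative binomial fit failed at every alpha")
    return best


def fit_vocal_glms(table: pd.DataFrame, count_col: str = "count"
                   ) -> ModelComparison:
    """Compare the four seasonal count models for one vocalization type.

    ``table`` has one row per recording with columns ``count`` (vocalization
    count), ``season``, ``n_adults``, ``sex_ratio``, ``n_pups`` and
    ``exposure`` (number of recorded segments).  Each model is a negative
    binomial GLM with a log link and a log-exposure offset; the dispersion
    alpha is chosen per model on a 50-point log grid over [0.01, 10] by
    minimal negative log-likelihood.  AIC counts every estimated parameter,
    including alpha; the pseudo-R² is deviance based
    (1 - residual deviance / null deviance).
    """
    if len(table) < 10:
        raise ValueError("need >= 10 recordings to compare models")
    y = table[count_col].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.all(y == 0):
        raise ValueError("degenerate fit: all counts are zero")
    offset = np.log(table["exposure"].to_numpy(dtype=float))
    fits = {}
    for name, covs in MODEL_COVARIATES.items():
        X = _design(table, covs)
        llf, alpha, res = _fit_nb(y, X, offset)
        k = len(res.params) + 1  # regression coefficients + dispersion alpha
        pseudo_r2 = 1.0 - res.deviance / res.null_deviance \
            if res.null_deviance > 0 else float("nan")
        fits[name] = ModelFit(name=name, aic=2 * k - 2 * llf, llf=float(llf),
                              alpha=float(alpha),
                              params=res.params.copy(),
                              pseudo_r2=float(pseudo_r2))
    best = min(fits.values(), key=lambda m: m.aic).name
    return ModelComparison(models=fits, best=best)


# ---------------------------------------------------------------------------
# pair series: meeting vocal counts vs subsequent co-occupancy
# ---------------------------------------------------------------------------

@dataclass
class PairSeries:
    """Per-meeting vocal counts and the pair's co-occupancy index (COI)
    evaluated at the start of each *next* meeting in the focal box."""

    mouse_a: str
    mouse_b: str
    box_id: str
    recording_id: str
    counts: pd.DataFrame         # columns squeak, usv; one row per meeting k
    coi_next: np.ndarray         # COI at start of meeting k+1
    pair_type: str = "unknown"   # male-male / male-female / female-female

    def __len__(self) -> int:
        return len(self.coi_next)


def _cum_time(entries: np.ndarray, exits: np.ndarray, t: float) -> float:
    """Total interval time accumulated strictly before t."""
    return float(np.clip(np.minimum(exits, t) - np.minimum(entries, t),
                         0.0, None).sum())


def _count_in_segments(onsets: np.ndarray, start: float, end: float,
                       recording: Recording) -> int:
    """Onsets inside [start, end) that also fall in a recorded segment."""
    sel = onsets[(onsets >= start) & (onsets < end)]
    if len(sel) == 0:
        return 0
    return int(np.sum(recording.segment_of(sel) >= 0))


def build_pair_series(meetings: pd.DataFrame, events: pd.DataFrame,
                      stays: pd.DataFrame, recordings: list[Recording],
                      min_meetings: int = 4) -> list[PairSeries]:
    """Build the per-pair series underlying the Spearman analysis.

    For each recorded (focal) box, each pair's meetings inside the recording
    span are ordered; the vocal count of meeting k is the number of onsets of
    each label inside the meeting interval that fall within a recorded 55 s
    segment, and the paired response is the pair's cumulative all-box COI at
    the start of meeting k+1 (the last meeting has no "next" and contributes
    no point).  Pairs with fewer than ``min_meetings`` usable points are
    excluded.
    """
    sex_of = {str(m): str(sub["sex"].iloc[0])
              for m, sub in stays.groupby("mouse_id")}
    by_mouse = {str(m): (sub["entry"].to_numpy(), sub["exit"].to_numpy())
                for m, sub in stays.groupby("mouse_id")}
    out: list[PairSeries] = []
    for rec in recordings:
        span_lo, span_hi = rec.start, rec.end
        focal = meetings[(meetings["box_id"] == rec.box_id)
                         & (meetings["start"] < span_hi)
                         & (meetings["end"] > span_lo)]
        ev = events[events["box_id"] == rec.box_id] \
            if "box_id" in events.columns else events
        onsets = {label: np.sort(ev.loc[ev["label"] == label,
                                        "onset"].to_numpy(dtype=float))
                  for label in ("squeak", "usv")}
        for (a, b), pm in focal.groupby(["mouse_a", "mouse_b"]):
            pm = pm.sort_values("start")
            if len(pm) < 2:
                continue
            all_pair = meetings[(meetings["mouse_a"] == a)
                                & (meetings["mouse_b"] == b)]
            pm_start = pm["start"].to_numpy()
            pm_end = pm["end"].to_numpy()
            counts = {"squeak": [], "usv": []}
            coi_next = []
            ae, ax = by_mouse[str(a)]
            be, bx = by_mouse[str(b)]
            ov_s = all_pair["start"].to_numpy()
            ov_e = all_pair["end"].to_numpy()
            for k in range(len(pm) - 1):
                for label in ("squeak", "usv"):
                    counts[label].append(_count_in_segments(
                        onsets[label], pm_start[k], pm_end[k], rec))
                t_next = pm_start[k + 1]
                ov = _cum_time(ov_s, ov_e, t_next)
                ta = _cum_time(ae, ax, t_next)
                tb = _cum_time(be, bx, t_next)
                denom = ta + tb - ov
                coi_next.append(ov / denom if denom > 0 else 0.0)
            if len(coi_next) < min_meetings:
                continue
            sa = sex_of.get(str(a), "unknown")
            sb = sex_of.get(str(b), "unknown")
            pair_type = "-".join(sorted((sa, sb)))
            out.append(PairSeries(
                mouse_a=str(a), mouse_b=str(b), box_id=rec.box_id,
                recording_id=rec.recording_id,
                counts=pd.DataFrame(counts),
                coi_next=np.asarray(coi_next, dtype=float),
                pair_type=pair_type))
    return out


def pair_spearman(series: PairSeries, label: str = "squeak") -> float:
    """Spearman rho (average ranks for ties) between a pair's meeting vocal
    counts and its COI at the next meeting.  NaN when either member of the
    series is constant (undefined rank correlation)."""
    x = series.counts[label].to_numpy(dtype=float)
    y = series.coi_next
    if len(x) < 2:
        raise ValueError("Spearman requires >= 2 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def all_pair_spearman(series_list: list[PairSeries], label: str = "squeak"
                      ) -> pd.DataFrame:
    """Per-pair rho table; constant (undefined) pairs are excluded."""
    rows = []
    for s in series_list:
        rho = pair_spearman(s, label=label)
        if np.isfinite(rho):
            rows.append({"mouse_a": s.mouse_a, "mouse_b": s.mouse_b,
                         "box_id": s.box_id, "pair_type": s.pair_type,
                         "n_points": len(s), "rho": rho})
    return pd.DataFrame(rows,
                        columns=["mouse_a", "mouse_b", "box_id", "pair_type",
                                 "n_points", "rho"])


@dataclass
class PairControlResult:
    actual: np.ndarray           # one rho per eligible pair
    null: np.ndarray             # pooled shuffled rhos
    #: one-sided Mann-Whitney p for actual right-shifted vs null
    p_greater: float


def shuffled_pair_controls(series_list: list[PairSeries],
                           n_shuffles: int = 100, seed: int = 0,
                           label: str = "squeak") -> PairControlResult:
    """Shuffled-control null for the pair-level Spearman distribution.

    Per pair and replicate, the vocal counts are permuted uniformly across
    that pair's meetings while the COI sequence stays fixed, and rho is
    recomputed.  Returns the actual rho distribution, the pooled null, and a
    one-sided Mann-Whitney p-value for the actual distribution being
    right-shifted.
    """
    if not series_list:
        raise ValueError("no eligible pairs")
    rng = np.random.default_rng(seed)
    actual, null = [], []
    for s in series_list:
        x = s.counts[label].to_numpy(dtype=float)
        y = s.coi_next
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        actual.append(float(stats.spearmanr(x, y).statistic))
        ry = stats.rankdata(y)
        for _ in range(n_shuffles):
            xs = rng.permutation(x)
            if np.all(xs == xs[0]):
                continue
            rx = stats.rankdata(xs)
            null.append(float(np.corrcoef(rx, ry)[0, 1]))
    actual_arr = np.asarray(actual)
    null_arr = np.asarray(null)
    if len(actual_arr) and len(null_arr):
        p = float(stats.mannwhitneyu(actual_arr, null_arr,
                                     alternative="greater").pvalue)
    else:
        p = float("nan")
    return PairControlResult(actual=actual_arr, null=null_arr, p_greater=p)
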