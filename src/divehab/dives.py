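"""Dive detection, metrics, U/V classification and phenology.

A time-depth-recorder trace is a 1-Hz depth series logged while the bird
is submerged.  A dive is a maximal run of samples deeper than a surface
threshold.  Per-dive metrics are maximum depth, duration and bottom time
(time spent at >= 80% of maximum depth, a configurable convention).
Dives are classified into prolonged U-shaped dives (distinct bottom
phase, deep) versus brief V-shaped plunges, shallower dives (< 1 m) are
discarded as likely bathing, and V dives are split into early/late
chick-rearing phases at the date of the marked drop in the daily
proportion of U dives.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CutoffRule",
    "detect_dives",
    "compute_metrics",
    "classify_dive",
    "filter_dives",
    "process_traces",
    "assign_foraging_locations",
    "detect_cutoff",
    "phase_labels",
    "daily_summary",
]

#: classifier thresholds: bottom time (s), duration (s), depth (m)
U_BOTTOM_S = 3.0
U_DURATION_S = 10.0
U_DEPTH_M = 8.0
MIN_DEPTH_M = 1.0


@dataclass
class CutoffRule:
    """How to place the early/late phase boundary.

    ``fixed_date`` echoes configured per-year dates; ``auto`` locates, per
    year, the day maximising the drop in mean daily U-dive proportion
    between the days before and from that day on.
    """

    mode: str = "auto"
    fixed_dates: dict[int, dt.date] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("fixed_date", "auto"):
            raise ValueError(f"unknown cutoff mode {self.mode!r}")
        if self.mode == "fixed_date" and not self.fixed_dates:
            raise ValueError("fixed_date mode needs fixed_dates")


def _trace_arrays(trace: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = trace["timestamp"]
    if pd.api.types.is_datetime64_any_dtype(t):
        t = (t - t.iloc[0]).dt.total_seconds() if len(t) else pd.Series(dtype=float)
        t0 = trace["timestamp"].iloc[0] if len(trace) else None
        sec = t.to_numpy(dtype=float)
        return sec, t0
    return t.to_numpy(dtype=float), None


def detect_dives(trace: pd.DataFrame, surface_threshold: float = 0.5,
                 max_gap_s: float = 5.0) -> list[pd.DataFrame]:
    """Split one bird's depth trace into raw dive segments.

    A segment is a maximal run of consecutive samples with
    ``depth > surface_threshold``; any surface sample, or a sampling gap
    longer than ``max_gap_s`` (the logger only records while submerged),
    separates segments.  Returns the per-segment sample slices.
    """
    if trace.empty:
        return []
    t = trace["timestamp"].to_numpy()
    if len(t) > 1 and not (t[1:] > t[:-1]).all():
        bad = trace["bird_id"].iloc[0] if "bird_id" in trace else "<trace>"
        raise ValueError(f"non-monotone timestamps in trace for {bad}")
    depth = trace["depth_m"].to_numpy(dtype=float)
    sec, _ = _trace_arrays(trace)
    wet = depth > surface_threshold
    if not wet.any():
        return []
    gap = np.concatenate([[False], np.diff(sec) > max_gap_s])
    # run starts: wet sample that follows a dry sample or a long gap
    prev_wet = np.concatenate([[False], wet[:-1]])
    starts = np.flatnonzero(wet & (~prev_wet | gap))
    segments = []
    for s in starts:
        e = s
        while e + 1 < len(wet) and wet[e + 1] and sec[e + 1] - sec[e] <= max_gap_s:
            e += 1
        segments.append(trace.iloc[s:e + 1])
    return segments


def compute_metrics(segment: pd.DataFrame, sample_interval: float = 1.0,
                    bottom_frac: float = 0.8) -> tuple[float, float, float]:
    """(max_depth m, duration s, bottom_time s) for one dive segment.

    Duration counts the terminal sample interval, so an n-sample 1-Hz dive
    lasts n seconds.  Bottom time is the summed sample time at depth
    >= ``bottom_frac`` x max depth.
    """
    if segment.empty:
        raise ValueError("empty dive segment")
    depth = segment["depth_m"].to_numpy(dtype=float)
    sec, _ = _trace_arrays(segment)
    max_depth = float(depth.max())
    duration = float(sec[-1] - sec[0] + sample_interval)
    bottom_time = float((depth >= bottom_frac * max_depth).sum() * sample_interval)
    return max_depth, duration, bottom_time


def classify_dive(max_depth: float, duration: float, bottom_time: float,
                  rule: str = "or") -> str:
    """Label a dive U or V.

    Default rule: U iff bottom_time >= 3 s, or (duration > 10 s and
    max_depth > 8 m); V is the exact complement.  The U and V clause
    sets as verbally stated in field use are not logical complements;
    this precedence (with V as complement of U) is the package's
    documented reading.  ``rule="strict_and"`` requires both clauses for U.
    """
    deep_long = duration > U_DURATION_S and max_depth > U_DEPTH_M
    has_bottom = bottom_time >= U_BOTTOM_S
    if rule == "or":
        return "U" if (has_bottom or deep_long) else "V"
    if rule == "strict_and":
        return "U" if (has_bottom and deep_long) else "V"
    raise ValueError(f"unknown classification rule {rule!r}")


def filter_dives(events: pd.DataFrame) -> pd.DataFrame:
    """Drop dives shallower than 1 m (likely bathing, not foraging)."""
    return events[events["max_depth"] >= MIN_DEPTH_M].reset_index(drop=True)


def process_traces(traces: pd.DataFrame, surface_threshold: float = 0.5,
                   bottom_frac: float = 0.8, rule: str = "or",
                   apply_filter: bool = True) -> pd.DataFrame:
    """Detect, measure and classify every dive in a multi-bird trace table.

    Returns one row per dive: bird_id, start_time, end_time, max_depth,
    duration, bottom_time, shape.  Output is independent of input row
    order within each bird (rows are time-sorted per bird first).
    """
    rows = []
    for bird, g in traces.groupby("bird_id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        for seg in detect_dives(g, surface_threshold):
            md, du, bt = compute_metrics(seg, bottom_frac=bottom_frac)
            rows.append((bird, seg["timestamp"].iloc[0], seg["timestamp"].iloc[-1],
                         md, du, bt, classify_dive(md, du, bt, rule)))
    events = pd.DataFrame(rows, columns=["bird_id", "start_time", "end_time",
                                         "max_depth", "duration", "bottom_time", "shape"])
    return filter_dives(events) if apply_filter else events


def assign_foraging_locations(events: pd.DataFrame, fixes: pd.DataFrame,
                              window_s: float = 1800.0) -> pd.DataFrame:
    """Attach to each dive the latest same-bird GPS fix in the 30 min
    (``window_s``) before the dive start; dives with no qualifying fix get
    NaN coordinates (and are excluded from presence generation downstream).
    """
    if events.empty:
        out = events.copy()
        out[["lon", "lat"]] = np.nan
        return out
    ev = events.sort_values("start_time", kind="stable").reset_index(drop=True)
    fx = fixes.sort_values("timestamp", kind="stable")[["bird_id", "timestamp", "lon", "lat"]]
    merged = pd.merge_asof(
        ev, fx.rename(columns={"timestamp": "fix_time"}),
        left_on="start_time", right_on="fix_time", by="bird_id",
        direction="backward", tolerance=pd.Timedelta(seconds=window_s),
    )
    return merged.drop(columns=["fix_time"])


def _best_split(days: np.ndarray, props: np.ndarray) -> tuple[int, float]:
    """Exhaustive scan of split points maximising mean(before) - mean(from)."""
    best_day, best_gap = None, -np.inf
    for k in range(1, len(days)):
        gap = props[:k].mean() - props[k:].mean()
        if gap > best_gap + 1e-12:
            best_gap, best_day = gap, days[k]
    return best_day, best_gap


def detect_cutoff(events: pd.DataFrame, rule: CutoffRule) -> dict[int, dt.date]:
    """Per-year early/late cutoff date from the drop in daily U proportion."""
    dates = pd.to_datetime(events["start_time"]).dt.date
    years = pd.Index(dates).map(lambda d: d.year)
    if rule.mode == "fixed_date":
        return dict(rule.fixed_dates)
    out = {}
    df = pd.DataFrame({"date": dates, "year": years, "is_u": (events["shape"] == "U").to_numpy()})
    for year, g in df.groupby("year"):
        daily = g.groupby("date")["is_u"].mean()
        if len(daily) < 7:
            raise ValueError(f"auto cutoff needs >= 7 days of data in {year}")
        props = daily.to_numpy(dtype=float)
        days = daily.index.to_numpy()
        if np.allclose(props, props[0]):
            warnings.warn(f"constant U proportion in {year}; using midpoint cutoff")
            out[int(year)] = days[len(days) // 2]
            continue
        day, _ = _best_split(days, props)
        out[int(year)] = day
    return out


def phase_labels(events: pd.DataFrame, cutoffs: dict[int, dt.date]) -> pd.DataFrame:
    """Add a phase column: 'early' before the year's cutoff date, 'late' from
    it on.  U dives are labelled too (bookkeeping only; tabulation ignores
    U phase)."""
    out = events.copy()
    dates = pd.to_datetime(out["start_time"]).dt.date
    years = pd.Index(dates).map(lambda d: d.year)
    phase = []
    for d, y in zip(dates, years):
        cut = cutoffs.get(int(y))
        if cut is None:
            raise KeyError(f"no cutoff configured for year {y}")
        phase.append("early" if d < cut else "late")
    out["phase"] = phase
    out["year"] = [int(y) for y in years]
    return out


def daily_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Per-day dive counts and U/V proportions (days with no dives absent)."""
    dates = pd.to_datetime(events["start_time"]).dt.date
    g = pd.DataFrame({"date": dates, "is_u": (events["shape"] == "U").to_numpy()}).groupby("date")
    out = g.agg(n_dives=("is_u", "size"), prop_U=("is_u", "mean")).reset_index()
    out["prop_V"] = 1.0 - out["prop_U"]
    return out
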