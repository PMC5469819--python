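"""Automated radio-telemetry processing: burst filtering, departure
detection, and apparent stopover duration.

A coded tag transmits at a fixed burst interval. True detections are
distinguished from noise by requiring at least three consecutive bursts at
the tag's designated interval (missed bursts are tolerated as integer
multiples of the interval). A migratory departure shows as a run whose
signal strength rises to a peak and then falls away as the bird flies
towards, over, and past the station, ending in the evening departure
window. Apparent stopover is the number of days from first capture (tag
deployment) to departure; records without a clean evening departure are
classed as unreliable:

  A — bird moved beyond the reach of the local stations within 48 h,
  B — disappearance at a time of day suggesting a landscape movement
      rather than a migratory departure,
  C — bird still present when the local stations were dismantled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRun",
    "StopoverRecord",
    "filter_bursts",
    "detect_departure",
    "build_stopover_records",
    "apparent_stopover",
    "runs_to_frame",
    "records_to_frame",
]

RELIABLE = "reliable"
CLASS_A = "A"  # left local detection range within 48 h of tagging
CLASS_B = "B"  # non-migratory disappearance (wrong time of day / no peak)
CLASS_C = "C"  # still present at station dismantling


@dataclass
class DetectionRun:
    """A validated run of consecutive bursts at one station/antenna."""

    tag_id: str
    station_id: str
    antenna_id: int
    times: np.ndarray  # epoch seconds, sorted
    strengths: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.times)

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.times[0], unit="s")

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.times[-1], unit="s")

    @property
    def median_interval(self) -> float:
        return float(np.median(np.diff(self.times))) if self.n_bursts > 1 else 0.0


@dataclass
class StopoverRecord:
    """Departure status and apparent stopover for one radio-tagged bird."""

    tag_id: str
    bird_id: str
    first_capture_date: pd.Timestamp
    departure_datetime: pd.Timestamp | None
    apparent_stopover_days: int | None
    reliability: str
    last_detection: pd.Timestamp | None = None


def _as_epoch(ts: pd.Series) -> np.ndarray:
    return pd.to_datetime(ts).astype("int64").to_numpy() / 1e9


def filter_bursts(
    raw_log: pd.DataFrame,
    tag_registry: dict[str, float] | pd.DataFrame,
    tolerance: float = 0.1,
    max_missed: int = 2,
) -> list[DetectionRun]:
    """Keep only maximal runs of >= 3 bursts at each tag's designated interval.

    Successive gaps must lie within ``tolerance`` (a fraction) of an integer
    multiple m of the interval, m <= ``max_missed`` + 1 (missed bursts).
    Bursts for unknown tag ids are discarded as noise.
    """
    if isinstance(tag_registry, pd.DataFrame):
        tag_registry = dict(
            zip(tag_registry["tag_id"], tag_registry["burst_interval_s"].astype(float))
        )
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    runs: list[DetectionRun] = []
    df = raw_log.copy()
    time_col = "timestamp_iso" if "timestamp_iso" in df.columns else "timestamp"
    df["_t"] = _as_epoch(df[time_col])
    for (tag, station, antenna), grp in df.groupby(
        ["tag_id", "station_id", "antenna_id"], sort=True
    ):
        interval = tag_registry.get(tag)
        if interval is None:
            continue  # unknown tag: noise
        grp = grp.sort_values("_t")
        t = grp["_t"].to_numpy()
        s = grp["signal_strength"].to_numpy(dtype=float)
        gaps = np.diff(t)
        mult = np.round(gaps / interval)
        ok = (
            (mult >= 1)
            & (mult <= max_missed + 1)
            & (np.abs(gaps - mult * interval) <= tolerance * interval * np.maximum(mult, 1))
        )
        # split into maximal runs of consecutive ok gaps
        start = 0
        for i in range(len(gaps) + 1):
            if i == len(gaps) or not ok[i]:
                if i - start + 1 >= 3:
                    runs.append(
                        DetectionRun(
                            tag_id=str(tag),
                            station_id=str(station),
                            antenna_id=int(antenna),
                            times=t[start : i + 1],
                            strengths=s[start : i + 1],
                        )
                    )
                start = i + 1
    return runs


def _smoothed_rise_fall(strengths: np.ndarray, window: int = 5) -> bool:
    """True if the moving-median-smoothed series rises to an interior maximum
    and then falls monotonically (strict, after collapsing plateaus)."""
    s = (
        pd.Series(strengths)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    # collapse consecutive equal values
    keep = np.concatenate([[True], np.diff(s) != 0])
    s = s[keep]
    if len(s) < 3:
        return False
    k = int(np.argmax(s))
    if k == 0 or k == len(s) - 1:
        return False
    # net rise to the peak, then a strictly monotone fall to the final burst
    return bool(s[k] > s[0] and np.all(np.diff(s[k:]) < 0))


def _parse_clock(hhmm: str) -> float:
    h, m = hhmm.split(":")
    return int(h) * 3600.0 + int(m) * 60.0


def detect_departure(
    runs: list[DetectionRun],
    window: tuple[str, str] = ("18:00", "21:00"),
) -> pd.Timestamp | None:
    """Find an evening departure signature among a bird's local-station runs.

    Only the final calendar day with any run is examined. A departure is
    declared iff some run that day shows the rise-then-fall smoothed
    signal-strength signature and its final burst falls inside the clock
    window; the departure time is that final burst (the latest qualifying
    run wins if several do).
    """
    if not runs:
        return None
    runs = sorted(runs, key=lambda r: r.times[-1])
    last_day = runs[-1].end.date()
    lo, hi = _parse_clock(window[0]), _parse_clock(window[1])
    best: pd.Timestamp | None = None
    for run in runs:
        if run.end.date() != last_day:
            continue
        tod = (
            run.end - pd.Timestamp(run.end.date())
        ).total_seconds()
        if not lo <= tod <= hi:
            continue
        if not _smoothed_rise_fall(run.strengths):
            continue
        if best is None or run.end > best:
            best = run.end
    return best


def build_stopover_records(
    runs: list[DetectionRun],
    tags: pd.DataFrame,
    local_station_ids: set[str],
    window: tuple[str, str] = ("18:00", "21:00"),
    dismantle_dates: dict[int, str] | None = None,
) -> list[StopoverRecord]:
    """Classify every tagged bird and compute apparent stopover.

    Classification is exhaustive and exclusive: C if detections continue to
    the station dismantle date, A if local coverage spans 48 h or less from
    tagging, reliable if a clean evening departure was found, otherwise B.
    """
    dismantle_dates = dismantle_dates or {}
    by_tag: dict[str, list[DetectionRun]] = {}
    for run in runs:
        if run.station_id in local_station_ids:
            by_tag.setdefault(run.tag_id, []).append(run)
    records: list[StopoverRecord] = []
    for _, row in tags.iterrows():
        tag = str(row["tag_id"])
        deploy = pd.Timestamp(row["deploy_date"])
        tag_runs = by_tag.get(tag, [])
        last = max((r.end for r in tag_runs), default=None)
        departure = detect_departure(tag_runs, window=window)
        year = int(row["year"]) if "year" in row else deploy.year
        dismantle = dismantle_dates.get(year)
        if (
            dismantle is not None
            and last is not None
            and last.date() >= pd.Timestamp(dismantle).date()
        ):
            cls, departure = CLASS_C, None
        elif last is None or (last - deploy).total_seconds() <= 48 * 3600:
            cls = CLASS_A
        elif departure is not None:
            cls = RELIABLE
        else:
            cls = CLASS_B
        apparent = (
            (departure.normalize() - deploy.normalize()).days
            if departure is not None and cls == RELIABLE
            else None
        )
        records.append(
            StopoverRecord(
                tag_id=tag,
                bird_id=str(row.get("bird_id", "")),
                first_capture_date=deploy,
                departure_datetime=departure if cls == RELIABLE else None,
                apparent_stopover_days=apparent,
                reliability=cls,
                last_detection=last,
            )
        )
    return records


def apparent_stopover(records: list[StopoverRecord]) -> pd.DataFrame:
    """Per-year mean/SD/n of apparent stopover over reliable records."""
    rows = [
        {
            "year": r.departure_datetime.year,
            "apparent_stopover_days": r.apparent_stopover_days,
        }
        for r in records
        if r.reliability == RELIABLE
    ]
    if not rows:
        raise ValueError("no reliable stopover records")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("year")["apparent_stopover_days"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    overall = pd.DataFrame(
        {
            "year": ["all"],
            "mean": [df["apparent_stopover_days"].mean()],
            "sd": [df["apparent_stopover_days"].std()],
            "n": [len(df)],
        }
    )
    return pd.concat([out.astype({"year": object}), overall], ignore_index=True)


def runs_to_frame(runs: list[DetectionRun]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [r.tag_id for r in runs],
            "station_id": [r.station_id for r in runs],
            "antenna_id": [r.antenna_id for r in runs],
            "start": [r.start.isoformat() for r in runs],
            "end": [r.end.isoformat() for r in runs],
            "n_bursts": [r.n_bursts for r in runs],
            "median_interval_s": [r.median_interval for r in runs],
            "max_strength": [float(np.max(r.strengths)) for r in runs],
        }
    )


def records_to_frame(records: list[StopoverRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [r.tag_id for r in records],
            "bird_id": [r.bird_id for r in records],
            "first_capture_date": [
                r.first_capture_date.date().isoformat() for r in records
            ],
            "departure_datetime": [
                r.departure_datetime.isoformat() if r.departure_datetime else ""
                for r in records
            ],
            "apparent_stopover_days": [
                r.apparent_stopover_days if r.apparent_stopover_days is not None else ""
                for r in records
            ],
            "reliability": [r.reliability for r in records],
            "last_detection": [
                r.last_detection.isoformat() if r.last_detection is not None else ""
                for r in records
            ],
        }
    )
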