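"""Synthetic stopover-season generator with known ground truth.

Emulates the statistical structure of a two-year spring stopover study of a
trans-Caribbean migrant songbird: bell-shaped arrival phenology, roughly
two-week stopovers, year-specific linear mass gain, daily mist-net capture,
evening departures announced by a rise-then-fall radio signal envelope,
sparse re-detections by a continental receiver array whose timing follows a
known linear pace-of-migration structure, and Poisson false-positive bursts.

Every emitted record traces back to a :class:`SimulatedBird`, so downstream
estimators (capture-recapture stopover duration, departure detection, fuel
energetics, pace regressions) can be scored against exact truth.

Conventions: day-of-season is an integer with day 1 = the season start
(April 1 by default); timestamps are site-local, second resolution;
coordinates are WGS-84 decimal degrees, longitude negative west.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "SimulatedBird",
    "SimulatedDataset",
    "simulate_population",
    "emit_banding_table",
    "emit_tag_registry",
    "emit_detection_log",
    "emit_truth",
    "default_stations",
    "simulate_dataset",
    "day_to_date",
]

LOCAL_REGION = "Local"
CONTINENTAL_REGIONS = ("GulfCoast", "Midwest", "Ontario")


def day_to_date(year: int, day: int, season_start: str = "04-01") -> pd.Timestamp:
    """Map integer day-of-season (day 1 = season start) to a calendar date."""
    start = pd.Timestamp(f"{year}-{season_start}")
    return start + pd.Timedelta(days=int(day) - 1)


def _parse_clock(hhmm: str) -> float:
    h, m = hhmm.split(":")
    return int(h) * 3600.0 + int(m) * 60.0


@dataclass
class SimulatedBird:
    """Ground-truth trajectory of one simulated migrant."""

    bird_id: str
    year: int
    arrival_day: int  # day-of-season
    stopover_days: float  # continuous residence draw
    stay_days: int  # catchable occasions: arrival_day .. arrival_day+stay-1
    wing_mm: float
    lbm_g: float
    fuel_arrival: float  # LBM fraction on arrival
    fdr: float  # LBM fraction gained per day
    tagged: bool
    tag_id: str | None
    departure_datetime: pd.Timestamp
    flight_speed_kmh: float
    pace_intercept_b: float  # bird-level random effect, days
    elapsed_by_region: dict[str, float] = field(default_factory=dict)

    @property
    def departure_day(self) -> int:
        return self.arrival_day + self.stay_days

    @property
    def mass_arrival_g(self) -> float:
        return self.lbm_g * (1.0 + self.fuel_arrival)

    def mass_on(self, day: int) -> float:
        """True (noise-free) mass on a given day-of-season."""
        dt = day - self.arrival_day
        return self.lbm_g * (1.0 + self.fuel_arrival + self.fdr * dt)

    @property
    def true_dfl(self) -> float:
        """Fuel load at departure as a fraction of LBM."""
        return (self.mass_on(self.departure_day) - self.lbm_g) / self.lbm_g


def _season_length(config: SimulationConfig, year: int) -> int:
    start = pd.Timestamp(f"{year}-{config.season_start}")
    end = pd.Timestamp(f"{year}-{config.season_end}")
    return int((end - start).days) + 1


def simulate_population(config: SimulationConfig) -> list[SimulatedBird]:
    """Draw the ground-truth population for all simulated years.

    Arrival days are normal around the phenology peak (truncated to the
    season), residence times normal truncated at one day, and the fuel
    trajectory is linear at the year's fuel deposition rate. A fixed
    fraction of birds carries a coded radio tag, deployed on arrival day.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    years = config.years
    birds: list[SimulatedBird] = []
    w0, w1 = config.departure_window
    win_lo, win_hi = _parse_clock(w0), _parse_clock(w1)
    smin, smax = config.flight_speed_range
    for i in range(config.n_birds):
        year = years[i % len(years)]
        season_len = _season_length(config, year)
        arrival = int(
            np.clip(
                round(rng.normal(config.arrival_peak_day, config.arrival_sd)),
                1,
                season_len - 2,
            )
        )
        stopover = max(1.0, rng.normal(config.stopover_mean, config.stopover_sd))
        stay = max(1, int(round(stopover)))
        wing = rng.normal(config.wing_mean, config.wing_sd)
        lbm = config.lbm_slope * wing + config.lbm_intercept
        if lbm <= 0:
            raise ValueError("LBM parameters produce non-positive lean mass")
        fuel0 = max(-0.03, rng.normal(config.initial_fuel_mean, config.initial_fuel_sd))
        tagged = rng.random() < config.tag_fraction
        dep_date = day_to_date(year, arrival + stay, config.season_start)
        dep_sec = rng.uniform(win_lo, win_hi)
        departure = dep_date + pd.Timedelta(seconds=round(dep_sec))
        bird = SimulatedBird(
            bird_id=f"B{i:04d}",
            year=year,
            arrival_day=arrival,
            stopover_days=stopover,
            stay_days=stay,
            wing_mm=wing,
            lbm_g=lbm,
            fuel_arrival=fuel0,
            fdr=config.fdr_by_year[year],
            tagged=tagged,
            tag_id=f"T{i:04d}" if tagged else None,
            departure_datetime=departure,
            flight_speed_kmh=rng.uniform(smin, smax),
            pace_intercept_b=rng.normal(0.0, config.pace_bird_sd),
        )
        birds.append(bird)
    return birds


def emit_banding_table(
    birds: list[SimulatedBird], config: SimulationConfig
) -> pd.DataFrame:
    """Capture-event table from daily mist netting.

    Untagged birds are captured each catchable day with ``capture_prob``;
    tagged birds are captured (and tagged) on their arrival day — netting
    at this site targets newly arrived, lean individuals — then recaptured
    at the same daily probability. Measured mass carries Gaussian noise;
    fat score is 0 when measured mass does not exceed lean body mass.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    rows = []
    for bird in birds:
        ages = "SY" if rng.random() < 0.5 else "ASY"
        season_len = _season_length(config, bird.year)
        for k in range(bird.stay_days):
            day = bird.arrival_day + k
            if day > season_len:  # netting stops at season end
                break
            if k == 0 and bird.tagged:
                caught = True
            else:
                caught = rng.random() < config.capture_prob
            if not caught:
                continue
            mass = bird.mass_on(day) + rng.normal(0.0, config.mass_noise_sd)
            fuel = (mass - bird.lbm_g) / bird.lbm_g
            fat = 0 if fuel <= 0 else int(min(5, 1 + fuel // 0.16))
            rows.append(
                {
                    "bird_id": bird.bird_id,
                    "date": day_to_date(bird.year, day, config.season_start).date().isoformat(),
                    "mass_g": round(mass, 2),
                    "wing_mm": round(bird.wing_mm, 1),
                    "fat_score": fat,
                    "age": ages,
                    "tag_id": bird.tag_id if bird.tagged else "",
                    "year": bird.year,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "bird_id", "date", "mass_g", "wing_mm",
            "fat_score", "age", "tag_id", "year",
        ],
    )
    if len(table):
        table = table.sort_values(["date", "bird_id"], kind="stable").reset_index(
            drop=True
        )
    return table


def emit_tag_registry(
    birds: list[SimulatedBird], config: SimulationConfig
) -> pd.DataFrame:
    """Tag deployment table: one row per radio-tagged bird."""
    rows = [
        {
            "tag_id": b.tag_id,
            "burst_interval_s": config.burst_interval,
            "deploy_date": day_to_date(b.year, b.arrival_day, config.season_start)
            .date()
            .isoformat(),
            "bird_id": b.bird_id,
            "year": b.year,
        }
        for b in birds
        if b.tagged
    ]
    return pd.DataFrame(
        rows, columns=["tag_id", "burst_interval_s", "deploy_date", "bird_id", "year"]
    )


def default_stations() -> pd.DataFrame:
    """Station registry: two local towers plus one station per continental
    region on the great-circle route north out of Colombia."""
    rows = [
        ("LOCAL-1", 11.123, -74.089, LOCAL_REGION),
        ("LOCAL-2", 11.123, -74.093, LOCAL_REGION),
        ("GULF-1", 29.10, -90.20, "GulfCoast"),
        ("MIDW-1", 40.05, -86.10, "Midwest"),
        ("ONTA-1", 42.60, -80.40, "Ontario"),
    ]
    return pd.DataFrame(rows, columns=["station_id", "lat_dd", "lon_dd", "region"])


def _departure_trace(
    bird: SimulatedBird, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Burst times (epoch seconds) and strengths for the departure flyover.

    The envelope is a Gaussian bump — signal rises as the bird approaches
    the tower, peaks overhead, and falls away — spanning 10-30 minutes and
    ending at the departure timestamp.
    """
    lo, hi = config.envelope_minutes
    span = rng.uniform(lo * 60.0, hi * 60.0)
    interval = config.burst_interval
    n = max(5, int(span // interval))
    t_end = bird.departure_datetime.value / 1e9
    times = t_end - interval * np.arange(n - 1, -1, -1)
    # peak sits late in the trace: the bird lifts off, passes over the tower,
    # and the signal dies quickly as it recedes northward
    t_peak = times[0] + 0.65 * (times[-1] - times[0])
    sigma = span / 4.0
    strengths = -85.0 + 35.0 * np.exp(-0.5 * ((times - t_peak) / sigma) ** 2)
    strengths = strengths + rng.normal(0.0, config.envelope_noise_sd, size=n)
    return times, strengths


def emit_detection_log(
    birds: list[SimulatedBird],
    stations: pd.DataFrame,
    config: SimulationConfig,
    with_provenance: bool = False,
) -> pd.DataFrame:
    """Raw automated-telemetry log for all tagged birds plus noise.

    Local stations detect a present bird in a few short bouts per day (an
    on/off presence model: birds forage in cover and are only intermittently
    within line of sight), record the rise-then-fall departure trace on the
    departure evening, and continental stations record short burst runs at
    times set by the ground-truth pace model. Poisson false positives with
    arbitrary tag ids and exponential spacing are superimposed.
    """
    if stations is None or len(stations) == 0:
        raise ValueError("station registry is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    local_ids = stations.loc[stations["region"] == LOCAL_REGION, "station_id"].tolist()
    region_station = {
        reg: sid
        for sid, reg in zip(stations["station_id"], stations["region"])
        if reg in CONTINENTAL_REGIONS
    }
    origin = (11.122, -74.087)  # tagging site
    st_idx = stations.set_index("station_id")
    region_dist = {
        reg: float(
            _haversine_km(
                origin[0], origin[1],
                st_idx.loc[sid, "lat_dd"], st_idx.loc[sid, "lon_dd"],
            )
        )
        for reg, sid in region_station.items()
    }
    interval = config.burst_interval
    rows_t: list[float] = []
    rows_tag: list[str] = []
    rows_station: list[str] = []
    rows_ant: list[int] = []
    rows_sig: list[float] = []
    rows_src: list[str] = []

    def _push(
        times: np.ndarray, sig: np.ndarray, tag: str, sid: str, ant: int, src: str
    ) -> None:
        rows_t.extend(times.tolist())
        rows_sig.extend(sig.tolist())
        rows_tag.extend([tag] * len(times))
        rows_station.extend([sid] * len(times))
        rows_ant.extend([ant] * len(times))
        rows_src.extend([src] * len(times))

    for bird in birds:
        if not bird.tagged:
            continue
        assert bird.tag_id is not None
        # daily local bouts while at the site (final day included: the bird
        # departs that evening)
        for day in range(bird.arrival_day, bird.departure_day + 1):
            date0 = day_to_date(bird.year, day, config.season_start).value / 1e9
            for _ in range(config.bouts_per_day):
                t0 = date0 + rng.uniform(6 * 3600.0, 17 * 3600.0)
                t0 = round(t0)
                n = config.bout_n_bursts
                times = t0 + interval * np.arange(n)
                sig = rng.normal(-62.0, 4.0, size=n)
                sid = local_ids[int(rng.integers(len(local_ids)))] if local_ids else None
                if sid is None:
                    continue
                _push(times, sig, bird.tag_id, sid, int(rng.integers(1, 4)), "bout")
        # departure flyover
        if local_ids:
            times, sig = _departure_trace(bird, config, rng)
            sid = local_ids[int(rng.integers(len(local_ids)))]
            _push(times, sig, bird.tag_id, sid, int(rng.integers(1, 4)), "departure")
        # continental re-detections at pace-model times
        dep_t = bird.departure_datetime.value / 1e9
        for region in CONTINENTAL_REGIONS:
            if region not in region_station:
                continue
            if rng.random() >= config.detect_prob_continental:
                continue
            elapsed = (
                config.pace_intercept
                + config.pace_beta_dfl * bird.true_dfl
                + config.pace_beta_depart * (bird.departure_day - config.pace_depart_ref)
                + config.pace_region_offsets.get(region, 0.0)
                + bird.pace_intercept_b
                + rng.normal(0.0, config.pace_resid_sd)
            )
            # elapsed time cannot undercut the non-stop flight time; birds at
            # this floor are the direct flights
            min_days = region_dist[region] / (bird.flight_speed_kmh * 24.0)
            elapsed = max(elapsed, min_days)
            bird.elapsed_by_region[region] = elapsed
            t0 = round(dep_t + elapsed * 86400.0)
            times = t0 + interval * np.arange(5)
            sig = rng.normal(-70.0, 3.0, size=5)
            _push(times, sig, bird.tag_id, region_station[region], int(rng.integers(1, 4)), "continental")

    # Poisson false positives per station over the operational window
    real_tags = [b.tag_id for b in birds if b.tagged]
    for year in config.years:
        t_start = pd.Timestamp(f"{year}-{config.season_start}").value / 1e9
        t_stop = t_start + 75 * 86400.0
        hours = (t_stop - t_start) / 3600.0
        for sid in stations["station_id"]:
            n_fp = rng.poisson(config.false_positive_rate * hours)
            if n_fp == 0:
                continue
            times = np.sort(np.round(rng.uniform(t_start, t_stop, size=n_fp)))
            sig = rng.uniform(-100.0, -40.0, size=n_fp)
            for t, s in zip(times, sig):
                if real_tags and rng.random() < 0.5:
                    tag = real_tags[int(rng.integers(len(real_tags)))]
                else:
                    tag = f"X{int(rng.integers(1000, 9999))}"
                rows_t.append(float(t))
                rows_sig.append(float(s))
                rows_tag.append(tag)
                rows_station.append(sid)
                rows_ant.append(int(rng.integers(1, 4)))
                rows_src.append("noise")

    log = pd.DataFrame(
        {
            "tag_id": rows_tag,
            "station_id": rows_station,
            "antenna_id": rows_ant,
            "timestamp": pd.to_datetime(np.asarray(rows_t), unit="s"),
            "signal_strength": np.round(np.asarray(rows_sig), 2),
            "source": rows_src,
        }
    )
    log = log.sort_values(
        ["tag_id", "station_id", "antenna_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)
    log["timestamp_iso"] = log["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    cols = ["tag_id", "station_id", "antenna_id", "timestamp_iso", "signal_strength"]
    if with_provenance:
        cols.append("source")
    return log[cols]


def emit_truth(birds: list[SimulatedBird], config: SimulationConfig) -> pd.DataFrame:
    """Per-bird ground truth for recovery scoring."""
    rows = []
    for b in birds:
        row = {
            "bird_id": b.bird_id,
            "year": b.year,
            "tagged": b.tagged,
            "tag_id": b.tag_id or "",
            "arrival_day": b.arrival_day,
            "stopover_days": b.stopover_days,
            "stay_days": b.stay_days,
            "departure_datetime": b.departure_datetime.isoformat(),
            "wing_mm": b.wing_mm,
            "lbm_g": b.lbm_g,
            "mass_arrival_g": b.mass_arrival_g,
            "fdr": b.fdr,
            "true_dfl": b.true_dfl,
            "flight_speed_kmh": b.flight_speed_kmh,
        }
        for region in CONTINENTAL_REGIONS:
            row[f"elapsed_{region}"] = b.elapsed_by_region.get(region, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """All synthetic tables for one run, plus the generating config."""

    config: SimulationConfig
    birds: list[SimulatedBird]
    banding: pd.DataFrame
    tags: pd.DataFrame
    stations: pd.DataFrame
    detections: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.banding.to_csv(os.path.join(out_dir, "banding.csv"), index=False)
        self.tags.to_csv(os.path.join(out_dir, "tags.csv"), index=False)
        self.stations.to_csv(os.path.join(out_dir, "stations.csv"), index=False)
        self.detections.to_csv(os.path.join(out_dir, "detections.csv"), index=False)
        self.truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)


def simulate_dataset(
    config: SimulationConfig | None = None,
    stations: pd.DataFrame | None = None,
    with_detections: bool = True,
) -> SimulatedDataset:
    """Run the full generator: population, banding, tags, detections, truth.

    ``with_detections=False`` skips the (comparatively bulky) telemetry log
    for workflows that only need the banding table.
    """
    config = config or SimulationConfig()
    stations = stations if stations is not None else default_stations()
    birds = simulate_population(config)
    banding = emit_banding_table(birds, config)
    tags = emit_tag_registry(birds, config)
    if with_detections:
        detections = emit_detection_log(birds, stations, config)
    else:
        detections = pd.DataFrame(
            columns=["tag_id", "station_id", "antenna_id", "timestamp_iso", "signal_strength"]
        )
    truth = emit_truth(birds, config)
    return SimulatedDataset(config, birds, banding, tags, stations, detections, truth)


def simulate_pace_observations(
    config: SimulationConfig | None = None,
    n_birds: int = 43,
    detect_prob: float = 0.35,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Draw pace observations directly from the ground-truth linear model.

    One row per (bird, region) detection: elapsed days follow
    intercept + beta_dfl * DFL + beta_depart * (departure day - reference)
    + region offset + bird intercept + noise. Used to score the pace
    regression against known coefficients without running the telemetry
    chain; ``detect_prob`` is per region, so most birds yield one row and
    some several (identifying the bird random intercept). Departure fuel
    loads are drawn N(0.52, 0.19): the midpoint of the two year means, with
    the spread implied by the reported 1000-4000 km flight-range span.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 7]))
    stations = default_stations().set_index("region")
    origin = (11.122, -74.087)
    rows = []
    for i in range(n_birds):
        dfl = float(np.clip(rng.normal(0.52, 0.19), 0.05, 0.95))
        depart_day = float(
            np.clip(rng.normal(config.pace_depart_ref, 5.0), 18.0, 55.0)
        )
        b_i = rng.normal(0.0, config.pace_bird_sd)
        detected = [
            r for r in CONTINENTAL_REGIONS if rng.random() < detect_prob
        ] or [CONTINENTAL_REGIONS[int(rng.integers(3))]]
        for region in detected:
            elapsed = (
                config.pace_intercept
                + config.pace_beta_dfl * dfl
                + config.pace_beta_depart * (depart_day - config.pace_depart_ref)
                + config.pace_region_offsets.get(region, 0.0)
                + b_i
                + rng.normal(0.0, config.pace_resid_sd)
            )
            st = stations.loc[region]
            dist = float(
                _haversine_km(origin[0], origin[1], st["lat_dd"], st["lon_dd"])
            )
            # pure linear draw (no flight-time censoring): this sampler
            # exists to score the regression against known coefficients
            elapsed = max(elapsed, 0.1)
            rows.append(
                {
                    "bird_id": f"P{i:03d}",
                    "region": region,
                    "elapsed_days": elapsed,
                    "elapsed_hours": elapsed * 24.0,
                    "distance_km": float(
                        _haversine_km(origin[0], origin[1], st["lat_dd"], st["lon_dd"])
                    ),
                    "dfl": dfl,
                    "departure_day_of_season": depart_day,
                }
            )
    return pd.DataFrame(rows)


def _haversine_km(lat1, lon1, lat2, lon2):
    from .pace import great_arc_km

    return great_arc_km(lat1, lon1, lat2, lon2)
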