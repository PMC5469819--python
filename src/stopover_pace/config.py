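"""Configuration objects for the simulator and the end-to-end pipeline.

The defaults encode the study conditions: a two-season (2015/2016) spring
stopover of a trans-Caribbean migrant songbird at a single Colombian site,
monitored by constant-effort mist netting and two local automated telemetry
stations, with sparse re-detections by a continental receiver network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["SimulationConfig", "PipelineConfig", "load_yaml", "dump_yaml"]


def _default_fdr() -> dict[int, float]:
    # fuel deposition rate, LBM fraction per day; slower fuelling in 2015
    return {2015: 0.035, 2016: 0.048}


def _default_region_offsets() -> dict[str, float]:
    # extra elapsed days by detection region, increasing with distance
    return {"GulfCoast": 0.0, "Midwest": 4.0, "Ontario": 8.0}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic stopover/migration season.

    Day-of-season is an integer with day 1 = April 1; calendar dates are
    ISO-8601. Probabilities are daily unless noted. Fuel quantities are
    fractions of lean body mass (LBM); LBM itself is linear in wing length.
    """

    n_birds: int = 888
    season_start: str = "04-01"  # month-day, applied to every simulated year
    season_end: str = "05-31"
    arrival_peak_day: float = 23.0  # day-of-season of peak arrival
    arrival_sd: float = 8.0
    stopover_mean: float = 12.7  # days
    stopover_sd: float = 3.1
    fdr_by_year: dict[int, float] = field(default_factory=_default_fdr)
    initial_fuel_mean: float = 0.0  # fuel load on arrival, LBM fraction
    initial_fuel_sd: float = 0.03
    wing_mean: float = 93.0  # mm; gives LBM near 26 g
    wing_sd: float = 3.0
    lbm_slope: float = 0.33  # g per mm
    lbm_intercept: float = -4.63  # g
    mass_noise_sd: float = 0.4  # g, measurement noise on each weighing
    capture_prob: float = 0.08  # daily probability while at the site
    tag_fraction: float = 0.15  # of the population, tagged on arrival day
    burst_interval: float = 10.0  # s between a tag's coded bursts
    bouts_per_day: int = 3  # local-station detection bouts per bird-day
    bout_n_bursts: int = 6
    departure_window: tuple[str, str] = ("18:00", "21:00")
    envelope_minutes: tuple[float, float] = (10.0, 30.0)  # departure trace span
    envelope_noise_sd: float = 0.3  # unitless signal-strength noise
    airspeed_U: float = 60.0  # km/h, mean airspeed for flight-range formula
    flight_speed_range: tuple[float, float] = (40.0, 76.0)  # km/h, realised
    pace_intercept: float = 25.0  # days, baseline elapsed time to Gulf Coast
    pace_beta_dfl: float = -27.57  # days per unit DFL
    pace_beta_depart: float = -0.76  # days per day of departure date
    pace_depart_ref: float = 36.0  # day-of-season at which the date term is 0
    pace_region_offsets: dict[str, float] = field(
        default_factory=_default_region_offsets
    )
    pace_bird_sd: float = 2.0  # days, random bird intercept SD
    pace_resid_sd: float = 3.0  # days, residual SD
    detect_prob_continental: float = 0.12  # per bird per continental region
    false_positive_rate: float = 1.0  # spurious bursts per station-hour
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "capture_prob": self.capture_prob,
            "tag_fraction": self.tag_fraction,
            "detect_prob_continental": self.detect_prob_continental,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_birds <= 0:
            raise ValueError("n_birds must be positive")
        if self.stopover_mean <= 0:
            raise ValueError("stopover_mean must be positive")
        if self.arrival_sd <= 0:
            raise ValueError("arrival_sd must be positive")
        if self.stopover_sd < 0:
            raise ValueError("stopover_sd must be non-negative")
        if self.burst_interval <= 0:
            raise ValueError("burst_interval must be positive")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be non-negative")
        for year, fdr in self.fdr_by_year.items():
            if fdr < 0:
                raise ValueError(f"fdr_by_year[{year}] must be non-negative")

    @property
    def years(self) -> list[int]:
        return sorted(self.fdr_by_year)

    def replace(self, **kw: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "fdr_by_year" in d:
            d["fdr_by_year"] = {int(k): float(v) for k, v in d["fdr_by_year"].items()}
        for key in ("departure_window", "envelope_minutes", "flight_speed_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineConfig:
    """One config for the simulate -> cjs -> telemetry -> fuel -> pace chain."""

    out_dir: str = "stopover_pace_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # capture-recapture
    delta_max: float = 6.0  # AICc window for model averaging
    # telemetry
    gap_tolerance: float = 0.1  # fraction of the burst interval
    max_missed_bursts: int = 2
    dismantle_dates: dict[int, str] = field(default_factory=lambda: {2015: "2015-05-15"})
    # fuel energetics
    airspeed_U: float = 60.0
    # pace
    speed_band: tuple[float, float] = (40.0, 76.0)  # km/h direct-flight band
    run_cjs: bool = True
    run_telemetry: bool = True
    run_fuel: bool = True
    run_pace: bool = True

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "dismantle_dates" in d:
            d["dismantle_dates"] = {
                int(k): str(v) for k, v in d["dismantle_dates"].items()
            }
        if "speed_band" in d and isinstance(d["speed_band"], list):
            d["speed_band"] = tuple(d["speed_band"])
        return cls(**d)


def load_yaml(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def dump_yaml(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
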