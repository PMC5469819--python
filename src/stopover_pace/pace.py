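"""Pace of intercontinental migration from continental re-detections.

Each re-detection of a departed bird by the continental receiver array
yields one pace observation: great-arc distance from the tagging site,
elapsed time since the evening departure, the implied minimum speed (as if
the bird flew continuously), and the detection region. Pace is modelled as
elapsed days against departure fuel load (DFL) and departure date, with a
region covariate and a random intercept per bird for multiply-detected
individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "great_arc_km",
    "min_speed",
    "build_pace_observations",
    "classify_direct_flights",
    "PaceModel",
    "PaceResults",
]

EARTH_RADIUS_KM = 6371.0


def great_arc_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle distance in km (haversine, spherical Earth R = 6371 km).

    Inputs in decimal degrees; numerically stable near zero separation.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lon2))):
        raise ValueError("non-finite longitude")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def min_speed(distance_km: float, elapsed_hours: float) -> float:
    """Minimum migration speed (km/h) assuming continuous flight."""
    if elapsed_hours <= 0:
        raise ValueError("elapsed time must be positive")
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    return distance_km / elapsed_hours


def build_pace_observations(
    runs: pd.DataFrame,
    stations: pd.DataFrame,
    stopover_records: pd.DataFrame,
    fuel: pd.DataFrame | None = None,
    tags: pd.DataFrame | None = None,
    origin: tuple[float, float] = (11.122, -74.087),
    season_start: str = "04-01",
) -> pd.DataFrame:
    """One row per (bird, continental station): distance, elapsed time,
    minimum speed, region, and departure covariates.

    ``runs`` is the validated-run table; only runs at non-local stations
    count. The earliest run per (tag, station) is the detection. Birds
    without a reliable departure are excluded (no elapsed time is defined).
    """
    st = stations.set_index("station_id")
    rec = stopover_records.copy()
    rec = rec[rec["reliability"] == "reliable"]
    rec["departure_datetime"] = pd.to_datetime(rec["departure_datetime"])
    dep = rec.set_index("tag_id")
    tag_to_bird = dict(zip(rec["tag_id"], rec["bird_id"]))
    if tags is not None:
        tag_to_bird.update(dict(zip(tags["tag_id"].astype(str), tags["bird_id"].astype(str))))
    rows = []
    df = runs.copy()
    df["start"] = pd.to_datetime(df["start"])
    for (tag, station), grp in df.groupby(["tag_id", "station_id"]):
        if station not in st.index:
            continue
        region = st.loc[station, "region"]
        if region == "Local":
            continue
        if tag not in dep.index:
            continue
        t_detect = grp["start"].min()
        t_depart = dep.loc[tag, "departure_datetime"]
        elapsed_h = (t_detect - t_depart).total_seconds() / 3600.0
        if elapsed_h <= 0:
            continue
        dist = great_arc_km(origin[0], origin[1], st.loc[station, "lat_dd"], st.loc[station, "lon_dd"])
        depart_day = (
            t_depart.normalize()
            - pd.Timestamp(f"{t_depart.year}-{season_start}")
        ).days + 1
        rows.append(
            {
                "bird_id": tag_to_bird.get(tag, tag),
                "tag_id": tag,
                "station_id": station,
                "region": region,
                "detection_datetime": t_detect.isoformat(),
                "departure_datetime": t_depart.isoformat(),
                "elapsed_hours": elapsed_h,
                "elapsed_days": elapsed_h / 24.0,
                "distance_km": dist,
                "min_speed_kmh": min_speed(dist, elapsed_h),
                "departure_day_of_season": depart_day,
                "year": t_depart.year,
            }
        )
    obs = pd.DataFrame(rows)
    if fuel is not None and len(obs):
        obs = obs.merge(fuel[["bird_id", "dfl", "flight_range_km"]], on="bird_id", how="left")
    return obs


def classify_direct_flights(
    observations: pd.DataFrame,
    speed_band: tuple[float, float] = (40.0, 76.0),
) -> pd.DataFrame:
    """Flag detections consistent with a single non-stop flight.

    Direct iff the minimum speed lies in the plausible continuous-flight
    band AND the distance does not exceed the bird's estimated flight
    range. Missing flight range -> 'unknown'.
    """
    out = observations.copy()
    lo, hi = speed_band
    flags = []
    for _, r in out.iterrows():
        rng = r.get("flight_range_km", np.nan)
        if pd.isna(rng):
            flags.append("unknown")
        elif lo <= r["min_speed_kmh"] <= hi and r["distance_km"] <= rng:
            flags.append("direct")
        else:
            flags.append("not_direct")
    out["direct_flight"] = flags
    return out


class PaceModel:
    """Pace-of-migration regression suite.

    Simple regressions of elapsed days on DFL and on departure date, plus
    linear mixed models with a bird random intercept and a candidate set of
    fixed effects compared by (ML) AICc.
    """

    def __init__(self, observations: pd.DataFrame):
        required = {"bird_id", "elapsed_days", "dfl", "departure_day_of_season", "region"}
        missing = required - set(observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        obs = observations.dropna(subset=["dfl", "elapsed_days"]).copy()
        if obs["bird_id"].nunique() < 2:
            raise ValueError("need at least two birds")
        if obs["bird_id"].value_counts().max() < 2:
            warnings.warn("no multiply-detected birds; random intercept unidentifiable")
        if np.std(obs["dfl"]) == 0:
            raise ValueError("departure fuel load constant across birds: dfl term dropped")
        obs["depart"] = obs["departure_day_of_season"].astype(float)
        self.obs = obs

    def fit(self, reml: bool = True) -> "PaceResults":
        obs = self.obs
        simple = {}
        for name, col in (("dfl", "dfl"), ("depart", "depart")):
            X = sm.add_constant(obs[col].to_numpy(dtype=float))
            f = sm.OLS(obs["elapsed_days"].to_numpy(dtype=float), X).fit()
            simple[name] = {
                "slope": float(f.params[1]),
                "se": float(f.bse[1]),
                "r_squared": float(f.rsquared),
                "p_value": float(f.pvalues[1]),
            }
        candidates = [
            "1",
            "dfl",
            "depart",
            "dfl + depart",
            "dfl + depart + C(region)",
        ]
        rows, fits = [], {}
        for formula in candidates:
            res, singular = self._fit_mixed(f"elapsed_days ~ {formula}", reml=False)
            k = res.df_modelwc + 2 if hasattr(res, "df_modelwc") else len(res.params) + 1
            n = len(obs)
            aic = -2 * res.llf + 2 * k
            aicc = aic + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf)
            rows.append(
                {"model": formula, "K": int(k), "logL": float(res.llf), "AICc": float(aicc),
                 "singular": singular}
            )
            fits[formula] = res
        table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
        table["delta_AICc"] = table["AICc"] - table["AICc"].min()
        w = np.exp(-table["delta_AICc"] / 2)
        table["weight"] = w / w.sum()
        best_formula = str(table.iloc[0]["model"])
        full = "dfl + depart + C(region)"
        best_fit, _ = self._fit_mixed(f"elapsed_days ~ {best_formula}", reml=reml)
        full_fit, full_singular = self._fit_mixed(f"elapsed_days ~ {full}", reml=reml)
        return PaceResults(
            observations=obs,
            simple=simple,
            table=table,
            best_formula=best_formula,
            best=best_fit,
            full=full_fit,
            full_singular=full_singular,
        )

    def _fit_mixed(self, formula: str, reml: bool):
        obs = self.obs
        singular = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(formula, obs, groups=obs["bird_id"])
                res = md.fit(reml=reml, method="lbfgs")
                if not np.isfinite(res.llf) or np.any(~np.isfinite(res.params)):
                    raise np.linalg.LinAlgError
                if float(np.asarray(res.cov_re).ravel()[0]) < 1e-10:
                    singular = True
            except (np.linalg.LinAlgError, ValueError):
                res = smf.ols(formula, obs).fit()
                singular = True
        return res, singular


@dataclass
class PaceResults:
    """Fitted pace models: simple slopes, mixed-model table, best fit."""

    observations: pd.DataFrame = field(repr=False)
    simple: dict
    table: pd.DataFrame = field(repr=False)
    best_formula: str
    best: object = field(repr=False)
    full: object = field(repr=False)
    full_singular: bool = False

    @property
    def beta_dfl(self) -> float:
        return self.simple["dfl"]["slope"]

    @property
    def beta_depart(self) -> float:
        return self.simple["depart"]["slope"]

    def fixed_effects(self) -> pd.DataFrame:
        """Fixed-effect estimates from the full mixed model."""
        params = self.full.params
        bse = self.full.bse
        names = [n for n in params.index if n != "Group Var"]
        return pd.DataFrame(
            {"term": names,
             "estimate": [float(params[n]) for n in names],
             "se": [float(bse[n]) for n in names]}
        )

    def region_offsets(self) -> dict[str, float]:
        """Region fixed effects relative to the baseline region."""
        out = {}
        for n, v in self.full.params.items():
            if n.startswith("C(region)"):
                out[n.split("[T.")[1].rstrip("]")] = float(v)
        return out

    def plot_effects(self, path: str | None = None):
        """Scatter of elapsed days against DFL and departure date with the
        simple-regression fits; returns the matplotlib figure."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        obs = self.observations
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, col, label in (
            (axes[0], "dfl", "departure fuel load (LBM fraction)"),
            (axes[1], "depart", "departure day of season"),
        ):
            ax.scatter(obs[col], obs["elapsed_days"], s=18, alpha=0.7,
                       c=obs["region"].astype("category").cat.codes, cmap="viridis")
            fit = self.simple["dfl" if col == "dfl" else "depart"]
            x = np.linspace(obs[col].min(), obs[col].max(), 50)
            x_mean = obs[col].mean()
            y_mean = obs["elapsed_days"].mean()
            ax.plot(x, y_mean + fit["slope"] * (x - x_mean), "k-")
            ax.set_xlabel(label)
        axes[0].set_ylabel("elapsed days since departure")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        lines = [
            "Pace of migration",
            f"  elapsed ~ DFL:    beta = {self.beta_dfl:8.2f} d per unit DFL   "
            f"R2 = {self.simple['dfl']['r_squared']:.2f}  p = {self.simple['dfl']['p_value']:.2g}",
            f"  elapsed ~ depart: beta = {self.beta_depart:8.2f} d per day      "
            f"R2 = {self.simple['depart']['r_squared']:.2f}  p = {self.simple['depart']['p_value']:.2g}",
            f"  best mixed model by AICc: elapsed ~ {self.best_formula}"
            + ("   [random intercept singular -> OLS fallback]" if self.full_singular else ""),
            "",
            self.table.to_string(index=False),
        ]
        return "\n".join(lines)
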