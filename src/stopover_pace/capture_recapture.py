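"""Stopover duration from mark-recapture: CJS survival plus seniority.

Every netting day is a capture occasion. A forward Cormack-Jolly-Seber model
estimates the daily probability phi that a bird already caught remains at the
site, and a recapture probability p; the identical likelihood applied to
time-reversed histories estimates the seniority probability gamma that a
bird was already present before the occasion on which it was caught. The
life-expectancy transform

    TS = -1/ln(phi) - 1/ln(gamma)

turns the two daily probabilities into a total stopover duration in days:
expected time remaining after capture plus expected time already spent.

Covariates (day-of-season, year, mass at first capture) act on phi and gamma
through a logit link; p is constant. Candidate models are compared by AICc
and estimates are model-averaged over the set within ``delta_max`` AICc units
of the best model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "CaptureHistory",
    "build_capture_histories",
    "CJSModel",
    "CJSResults",
    "cjs_loglik",
    "fit_cjs",
    "total_stopover",
    "candidate_specs",
    "fit_candidate_set",
    "select_and_average",
    "ModelAverage",
]

_ETA_CLIP = 15.0  # logit-scale bound; avoids overflow at the boundary
_TERMS = ("date", "year", "mass")


# ---------------------------------------------------------------------------
# capture histories


@dataclass
class CaptureHistory:
    """Binary encounter vector for one bird over the daily occasions."""

    bird_id: str
    encounters: np.ndarray  # uint8, one entry per occasion
    first_capture_index: int
    covariates: dict

    def __post_init__(self) -> None:
        enc = np.asarray(self.encounters, dtype=np.uint8)
        if enc.sum() < 1:
            raise ValueError("capture history must contain at least one capture")
        if int(np.argmax(enc)) != self.first_capture_index:
            raise ValueError("first_capture_index does not match encounters")
        self.encounters = enc


def _day_of_season(dates: pd.Series, years: pd.Series, season_start: str) -> np.ndarray:
    starts = pd.to_datetime(years.astype(str) + "-" + season_start)
    return (pd.to_datetime(dates) - starts).dt.days.to_numpy() + 1


def build_capture_histories(
    banding: pd.DataFrame,
    season: tuple[int, int] | None = None,
    effort_days: set[int] | None = None,
    season_start: str = "04-01",
) -> list[CaptureHistory]:
    """Build one capture history per bird from the banding table.

    Occasions are day-of-season integers (day 1 = season start), shared
    across years so that year enters as a covariate. Occasions outside the
    supplied effort calendar are dropped. Duplicate (bird, occasion) rows
    collapse to a single 1. Covariates (day, mass, year) are taken from the
    first capture.
    """
    if banding is None or len(banding) == 0:
        raise ValueError("banding table is empty")
    df = banding.copy()
    df["_day"] = _day_of_season(df["date"], df["year"], season_start)
    lo, hi = (
        season
        if season is not None
        else (int(df["_day"].min()), int(df["_day"].max()))
    )
    days = [d for d in range(lo, hi + 1) if effort_days is None or d in effort_days]
    if not days:
        raise ValueError("no occasions with netting effort in the season window")
    day_index = {d: j for j, d in enumerate(days)}
    histories: list[CaptureHistory] = []
    for bird_id, grp in df.sort_values("_day").groupby("bird_id", sort=True):
        grp = grp[grp["_day"].isin(day_index)]
        if grp.empty:
            continue
        enc = np.zeros(len(days), dtype=np.uint8)
        for d in grp["_day"]:
            enc[day_index[int(d)]] = 1
        first = grp.iloc[0]
        f_idx = int(np.argmax(enc))
        histories.append(
            CaptureHistory(
                bird_id=str(bird_id),
                encounters=enc,
                first_capture_index=f_idx,
                covariates={
                    "date_first": float(first["_day"]),
                    "mass_first": float(first["mass_g"]),
                    "year": int(first["year"]),
                },
            )
        )
    if not histories:
        raise ValueError("no usable capture histories")
    for h in histories:
        h.covariates["occasion_days"] = days  # shared occasion calendar
    return histories


# ---------------------------------------------------------------------------
# packed data and likelihood


class _HistoryData:
    """Dense arrays for the packed histories, plus standardized covariates."""

    def __init__(self, histories: list[CaptureHistory]):
        Y = np.stack([h.encounters for h in histories]).astype(np.int8)
        self.Y = Y
        self.n, self.T = Y.shape
        self.f = np.array([h.first_capture_index for h in histories])
        rev = Y[:, ::-1]
        self.l = self.T - 1 - np.argmax(rev, axis=1)
        days = histories[0].covariates.get("occasion_days")
        if days is None:
            days = list(range(1, self.T + 1))
        days = np.asarray(days, dtype=float)
        self.occ_days = days
        d_mu, d_sd = days.mean(), max(days.std(), 1e-9)
        self.date_std = (days - d_mu) / d_sd  # per-occasion, standardized
        mass = np.array([h.covariates.get("mass_first", np.nan) for h in histories])
        if np.isnan(mass).any():
            mass = np.where(np.isnan(mass), np.nanmean(mass), mass)
        m_mu, m_sd = mass.mean(), max(mass.std(), 1e-9)
        self.mass_std = (mass - m_mu) / m_sd
        self.year = np.array([int(h.covariates.get("year", 0)) for h in histories])
        self.years = sorted(set(self.year.tolist()))
        self.bird_ids = [h.bird_id for h in histories]
        self.n_recaptured = int((self.l > self.f).sum())
        if not np.all(np.isfinite(self.mass_std)):
            raise ValueError("non-finite covariate values")

    def features(self, terms: tuple[str, ...], reverse: bool) -> list[tuple[str, str, np.ndarray]]:
        """Feature list: (name, axis 'i'|'t', values). Interval t runs over
        T-1 gaps; its date covariate is the date of the interval's starting
        occasion (in reversed time, of the later real occasion)."""
        date_t = self.date_std[::-1] if reverse else self.date_std
        feats: list[tuple[str, str, np.ndarray]] = []
        for term in terms:
            if term == "date":
                feats.append(("Date", "t", date_t[: self.T - 1]))
            elif term == "mass":
                feats.append(("mass", "i", self.mass_std))
            elif term == "year":
                for y in self.years[1:]:
                    feats.append((f"year{y}", "i", (self.year == y).astype(float)))
            else:
                raise ValueError(f"unknown covariate term: {term}")
        return feats


def _eta(beta: np.ndarray, feats: list, n: int, T1: int) -> np.ndarray:
    """Linear predictor matrix (n, T-1) from intercept + separable features."""
    u = np.zeros(n)
    v = np.full(T1, beta[0])
    for b, (_, axis, vals) in zip(beta[1:], feats):
        if axis == "i":
            u = u + b * vals
        else:
            v = v + b * vals
    return np.clip(u[:, None] + v[None, :], -_ETA_CLIP, _ETA_CLIP)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _Direction:
    """One orientation (forward=survival or reversed=seniority) of the data,
    with the conditional-on-first-capture CJS likelihood and its gradient."""

    def __init__(self, data: _HistoryData, terms: tuple[str, ...], reverse: bool):
        self.data = data
        self.terms = terms
        self.reverse = reverse
        Y = data.Y[:, ::-1] if reverse else data.Y
        self.Y = Y
        n, T = Y.shape
        self.n, self.T = n, T
        self.f = (T - 1 - data.l) if reverse else data.f
        self.l = (T - 1 - data.f) if reverse else data.l
        self.feats = data.features(terms, reverse)
        self.k = 1 + len(self.feats)  # + logit(p) appended in the parameter vector
        t_idx = np.arange(T - 1)
        self.active = (t_idx[None, :] >= self.f[:, None]) & (
            t_idx[None, :] < self.l[:, None]
        )
        occ = np.arange(T)
        between = (occ[None, :] > self.f[:, None]) & (occ[None, :] <= self.l[:, None])
        self.n1 = int((Y * between).sum())  # recapture events after first capture
        self.n0 = int(between.sum()) - self.n1
        tail = t_idx[None, :] >= self.l[:, None]
        self.tail = tail

    def loglik(self, params: np.ndarray, grad: bool = False):
        beta, q = params[:-1], params[-1]
        q = float(np.clip(q, -_ETA_CLIP, _ETA_CLIP))
        p = _sigmoid(np.array(q))
        eta = _eta(beta, self.feats, self.n, self.T - 1)
        phi = _sigmoid(eta)
        n, T = self.n, self.T
        # chi recursion and (optionally) its p-derivative, backwards in time
        chi = np.ones((n, T))
        D = np.zeros((n, T))
        for t in range(T - 2, -1, -1):
            chi[:, t] = (1.0 - phi[:, t]) + phi[:, t] * (1.0 - p) * chi[:, t + 1]
            if grad:
                D[:, t] = -phi[:, t] * chi[:, t + 1] + phi[:, t] * (1.0 - p) * D[:, t + 1]
        rows = np.arange(n)
        chi_l = np.maximum(chi[rows, self.l], 1e-300)
        ll = (
            float(np.sum(np.log(phi) * self.active))
            + self.n1 * math.log(p)
            + self.n0 * math.log1p(-p)
            + float(np.sum(np.log(chi_l)))
        )
        if not grad:
            return ll
        # d loglik / d eta_it accumulated into W (n, T-1):
        #   active survival part: (1 - phi)
        #   tail part: d log chi_l / d eta via path products in log space
        logstep = np.log(np.maximum(phi * (1.0 - p), 1e-300))
        logQ = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(logstep, axis=1)], axis=1
        )  # logQ[:, s] = sum_{t<s} log(phi_t (1-p))
        logP = logQ - logQ[rows, self.l][:, None]  # P_{i,s} for s >= l_i
        tailmask = self.tail
        chi_next = chi[:, 1:]
        A = np.where(
            tailmask,
            np.exp(np.clip(logP[:, :-1], -700, 0))
            * (-1.0 + (1.0 - p) * chi_next)
            / chi_l[:, None],
            0.0,
        )
        W = self.active * (1.0 - phi) + A * phi * (1.0 - phi)
        g = np.empty(self.k + 1)
        g[0] = W.sum()
        row_w = W.sum(axis=1)
        col_w = W.sum(axis=0)
        for j, (_, axis, vals) in enumerate(self.feats, start=1):
            g[j] = float(row_w @ vals) if axis == "i" else float(col_w @ vals)
        dp = (
            self.n1 / p
            - self.n0 / (1.0 - p)
            + float(np.sum(D[rows, self.l] / chi_l))
        )
        g[-1] = dp * p * (1.0 - p)
        return ll, g

    def fit(self, max_restarts: int = 5, seed: int = 0) -> "_DirectionFit":
        x0 = np.zeros(self.k + 1)
        x0[0] = 2.2  # logit(0.9): most birds stay from one day to the next
        x0[-1] = -2.2  # logit(0.1): recapture is rare
        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(max_restarts):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=x0.shape)

            def nll(x):
                ll, g = self.loglik(x, grad=True)
                return -ll, -g

            res = minimize(
                nll,
                start,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success and attempt >= 0:
                break
        assert best is not None
        return _DirectionFit(
            direction=self,
            params=best.x,
            logL=-float(best.fun),
            converged=bool(best.success),
        )


@dataclass
class _DirectionFit:
    direction: _Direction
    params: np.ndarray
    logL: float
    converged: bool
    _cov: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def p(self) -> float:
        return float(_sigmoid(self.params[-1]))

    @property
    def feature_names(self) -> list[str]:
        return ["(Intercept)"] + [f[0] for f in self.direction.feats]

    def prob_matrix(self) -> np.ndarray:
        eta = _eta(
            self.beta, self.direction.feats, self.direction.n, self.direction.T - 1
        )
        return _sigmoid(eta)

    def weighted_prob(self, rows: np.ndarray | None = None) -> float:
        """Daily probability averaged over active bird-intervals (activity-
        weighted reference value for the stopover transform)."""
        phi = self.prob_matrix()
        act = self.direction.active
        if rows is not None:
            phi, act = phi[rows], act[rows]
        w = act.sum()
        if w == 0:
            return float("nan")
        return float((phi * act).sum() / w)

    @property
    def cov(self) -> np.ndarray:
        if self._cov is None:
            H = _num_hessian(lambda x: self.direction.loglik(x), self.params)
            try:
                self._cov = np.linalg.inv(-H)
            except np.linalg.LinAlgError:
                self._cov = np.full_like(H, np.nan)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))

    def weighted_prob_se(self) -> float:
        """Delta-method SE of the activity-weighted daily probability."""
        phi = self.prob_matrix()
        act = self.direction.active
        w = act.sum()
        W = act * phi * (1.0 - phi) / w
        g = np.zeros(len(self.params))
        g[0] = W.sum()
        row_w, col_w = W.sum(axis=1), W.sum(axis=0)
        for j, (_, axis, vals) in enumerate(self.direction.feats, start=1):
            g[j] = float(row_w @ vals) if axis == "i" else float(col_w @ vals)
        var = float(g @ self.cov @ g)
        return math.sqrt(max(var, 0.0))


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


# ---------------------------------------------------------------------------
# public model / results objects


def total_stopover(phi_hat: float, gamma_hat: float) -> float:
    """Total stopover in days: -1/ln(phi) + -1/ln(gamma).

    Expected residence time after first capture plus expected time already
    spent at the site, each from a daily persistence probability.
    """
    for name, v in (("phi", phi_hat), ("gamma", gamma_hat)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
    return -1.0 / math.log(phi_hat) + -1.0 / math.log(gamma_hat)


@dataclass
class CJSResults:
    """Estimates for one (phi formula, gamma formula) model pair."""

    phi_terms: tuple[str, ...]
    gamma_terms: tuple[str, ...]
    forward: _DirectionFit
    reverse: _DirectionFit
    n_eff: int
    _data: _HistoryData = field(repr=False, default=None)

    @property
    def logL(self) -> float:
        return self.forward.logL + self.reverse.logL

    @property
    def K(self) -> int:
        # independent recapture probability in each direction
        return (len(self.forward.params)) + (len(self.reverse.params))

    @property
    def converged(self) -> bool:
        return self.forward.converged and self.reverse.converged

    @property
    def AICc(self) -> float:
        K, n = self.K, self.n_eff
        if n - K - 1 <= 0:
            return float("inf")
        return -2.0 * self.logL + 2 * K + 2 * K * (K + 1) / (n - K - 1)

    @property
    def phi_hat(self) -> float:
        return self.forward.weighted_prob()

    @property
    def gamma_hat(self) -> float:
        return self.reverse.weighted_prob()

    @property
    def p_hat(self) -> float:
        return self.forward.p

    @property
    def ts_days(self) -> float:
        return total_stopover(self.phi_hat, self.gamma_hat)

    def ts_se(self) -> float:
        phi, gam = self.phi_hat, self.gamma_hat
        dphi = 1.0 / (phi * math.log(phi) ** 2)
        dgam = 1.0 / (gam * math.log(gam) ** 2)
        var = (dphi * self.forward.weighted_prob_se()) ** 2 + (
            dgam * self.reverse.weighted_prob_se()
        ) ** 2
        return math.sqrt(var)

    def ts_by_year(self) -> dict[int, float]:
        out = {}
        for y in self._data.years:
            rows = np.where(self._data.year == y)[0]
            phi = self.forward.weighted_prob(rows)
            gam = self.reverse.weighted_prob(rows)
            out[y] = total_stopover(phi, gam)
        return out

    @property
    def name(self) -> str:
        def fmt(terms):
            return " + ".join(t.capitalize() if t == "date" else t for t in terms) or "1"

        return (
            f"phi(~{fmt(self.phi_terms)}) p(~1) gamma(~{fmt(self.gamma_terms)})"
        )

    def wald_table(self) -> pd.DataFrame:
        """Coefficients, SEs and Wald z/p for phi and gamma (logit scale)."""
        rows = []
        for label, dfit in (("phi", self.forward), ("gamma", self.reverse)):
            bse = dfit.bse
            for nm, b, se in zip(
                dfit.feature_names + ["logit(p)"], dfit.params, bse
            ):
                z = b / se if se > 0 else np.nan
                from scipy.stats import norm

                rows.append(
                    {
                        "component": label,
                        "term": nm,
                        "estimate": b,
                        "se": se,
                        "z": z,
                        "p_value": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"CJS total-stopover model: {self.name}",
            f"  n histories: {self.n_eff}   K: {self.K}   "
            f"logL: {self.logL:.2f}   AICc: {self.AICc:.2f}",
            f"  phi_hat: {self.phi_hat:.4f}   gamma_hat: {self.gamma_hat:.4f}   "
            f"p_hat: {self.p_hat:.4f}",
            f"  total stopover: {self.ts_days:.2f} d",
        ]
        return "\n".join(lines)


class CJSModel:
    """Cormack-Jolly-Seber model with a paired reverse-time seniority fit.

    Parameters
    ----------
    histories : list of CaptureHistory
    phi_terms, gamma_terms : tuple of {"date", "year", "mass"}
        Covariates on the survival / seniority logits; empty tuple for an
        intercept-only component. Recapture probability is intercept-only.
    """

    def __init__(
        self,
        histories: list[CaptureHistory],
        phi_terms: tuple[str, ...] = (),
        gamma_terms: tuple[str, ...] = ("date",),
    ):
        for t in phi_terms + gamma_terms:
            if t not in _TERMS:
                raise ValueError(f"unknown covariate term: {t}")
        self.phi_terms = tuple(phi_terms)
        self.gamma_terms = tuple(gamma_terms)
        self.data = _HistoryData(histories)
        if self.data.n_recaptured == 0:
            raise ValueError(
                "no recaptured birds: survival/seniority are unidentifiable"
            )

    def loglik(self, params: np.ndarray) -> float:
        """Joint log-likelihood at a packed parameter vector
        [beta_phi, logit p_fwd, beta_gamma, logit p_rev]."""
        fwd = _Direction(self.data, self.phi_terms, reverse=False)
        rev = _Direction(self.data, self.gamma_terms, reverse=True)
        kf = fwd.k + 1
        ll = fwd.loglik(params[:kf]) + rev.loglik(params[kf:])
        if not np.isfinite(ll):
            raise ValueError("non-finite log-likelihood")
        return ll

    def fit(self, max_restarts: int = 5, seed: int = 0) -> CJSResults:
        fwd = _Direction(self.data, self.phi_terms, reverse=False).fit(
            max_restarts=max_restarts, seed=seed
        )
        rev = _Direction(self.data, self.gamma_terms, reverse=True).fit(
            max_restarts=max_restarts, seed=seed + 1
        )
        return CJSResults(
            phi_terms=self.phi_terms,
            gamma_terms=self.gamma_terms,
            forward=fwd,
            reverse=rev,
            n_eff=self.data.n,
            _data=self.data,
        )


def cjs_loglik(
    histories: list[CaptureHistory],
    spec: tuple[tuple[str, ...], tuple[str, ...]],
    beta: np.ndarray,
) -> float:
    """Joint forward + seniority log-likelihood for a packed beta vector."""
    model = CJSModel(histories, phi_terms=spec[0], gamma_terms=spec[1])
    return model.loglik(np.asarray(beta, dtype=float))


def fit_cjs(
    histories: list[CaptureHistory],
    spec: tuple[tuple[str, ...], tuple[str, ...]],
    max_restarts: int = 5,
    seed: int = 0,
) -> CJSResults:
    return CJSModel(histories, phi_terms=spec[0], gamma_terms=spec[1]).fit(
        max_restarts=max_restarts, seed=seed
    )


# ---------------------------------------------------------------------------
# candidate set, selection, averaging


def candidate_specs() -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Default 20-model candidate set.

    Survival: intercept-only, or any of Date / year / Date+year /
    Date+year+mass. Seniority always includes Date (migration phenology is
    bell-shaped, so the chance of already being present must change through
    the season), optionally plus year and/or mass.
    """
    phi_opts = [(), ("date",), ("year",), ("date", "year"), ("date", "year", "mass")]
    gamma_opts = [
        ("date",),
        ("date", "mass"),
        ("date", "year"),
        ("date", "year", "mass"),
    ]
    return list(itertools.product(phi_opts, gamma_opts))


def fit_candidate_set(
    histories: list[CaptureHistory],
    specs: list[tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
    max_restarts: int = 5,
    seed: int = 0,
) -> list[CJSResults]:
    """Fit every candidate model; non-converged fits are kept but flagged."""
    specs = specs if specs is not None else candidate_specs()
    fits = []
    for j, (phi_t, gam_t) in enumerate(specs):
        fits.append(
            CJSModel(histories, phi_terms=phi_t, gamma_terms=gam_t).fit(
                max_restarts=max_restarts, seed=seed + 101 * j
            )
        )
    return fits


@dataclass
class ModelAverage:
    """Akaike-weighted summary across the candidate set."""

    table: pd.DataFrame  # one row per model, sorted by AICc
    ts_days: float
    ts_se: float
    ts_by_year: dict[int, float]
    delta_max: float
    n_averaged: int

    def summary(self) -> str:
        lines = [
            f"Model-averaged total stopover: {self.ts_days:.2f} +- {self.ts_se:.2f} d "
            f"(over {self.n_averaged} models with delta AICc <= {self.delta_max:g})",
        ]
        for y, ts in sorted(self.ts_by_year.items()):
            lines.append(f"  {y}: {ts:.2f} d")
        return "\n".join(lines)


def select_and_average(
    fits: list[CJSResults], delta_max: float = 6.0
) -> ModelAverage:
    """AICc ranking, Akaike weights, and weighted averaging of TS.

    Weights are computed over all converged fits; averaging uses the models
    within ``delta_max`` AICc units of the best, with weights renormalized
    over that set. The averaged SE combines within-model (delta-method) and
    between-model components. AICc ties break toward fewer parameters, then
    lexical model name.
    """
    eps = 1e-4  # boundary guard: phi/gamma at 0 or 1 make TS undefined
    usable = [
        fit
        for fit in fits
        if fit.converged
        and np.isfinite(fit.AICc)
        and eps < fit.phi_hat < 1 - eps
        and eps < fit.gamma_hat < 1 - eps
    ]
    if not usable:
        raise ValueError("no converged, identifiable model fits to average")
    usable.sort(key=lambda r: (r.AICc, r.K, r.name))
    aicc = np.array([r.AICc for r in usable])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    keep = delta <= delta_max
    wk = w[keep] / w[keep].sum()
    kept = [r for r, k in zip(usable, keep) if k]
    ts = np.array([r.ts_days for r in kept])
    ts_bar = float(wk @ ts)
    se_within = np.array([r.ts_se() for r in kept])
    ts_se = float(np.sqrt(wk @ (se_within**2 + (ts - ts_bar) ** 2)))
    by_year: dict[int, float] = {}
    for r, wi in zip(kept, wk):
        for y, t in r.ts_by_year().items():
            by_year[y] = by_year.get(y, 0.0) + wi * t
    table = pd.DataFrame(
        {
            "model": [r.name for r in usable],
            "K": [r.K for r in usable],
            "logL": [r.logL for r in usable],
            "AICc": aicc,
            "delta_AICc": delta,
            "weight": w,
            "phi_hat": [r.phi_hat for r in usable],
            "gamma_hat": [r.gamma_hat for r in usable],
            "p_hat": [r.p_hat for r in usable],
            "TS_days": [r.ts_days for r in usable],
            "averaged": keep,
        }
    )
    return ModelAverage(
        table=table,
        ts_days=ts_bar,
        ts_se=ts_se,
        ts_by_year=by_year,
        delta_max=delta_max,
        n_averaged=int(keep.sum()),
    )
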