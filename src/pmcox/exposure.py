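"""Exposure assignment and transformation.

Exposure surfaces arrive as location × calendar-month concentration tables
(PM2.5 in µg/m³, NO2 and O3 in ppb). Beneficiaries are matched to the
surface location nearest (great-circle) to their ZIP-code centroid, and the
time-varying exposure covariate for month *t* is the trailing 12-month mean
over months t-11..t, evaluated along the beneficiary's own residence path so
that windows crossing a residential move mix the two ZIPs' series
month-by-month.

The "non-traffic PM2.5" construction is a two-stage procedure: ordinary
least squares of 12-month PM2.5 on 12-month NO2 (pooled over ZIP-months),
with the stage-1 residual carried forward as the exposure measure in stage-2
hazard models. Because NO2 is predominantly traffic-derived, the residual is
interpreted as the PM2.5 fraction unrelated to traffic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .months import month_index_array, month_str

EARTH_RADIUS_MILES = 3958.7613
WARM_SEASON_MONTHS = (4, 5, 6, 7, 8, 9)  # April-September


class ExposureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# surfaces


@dataclass
class ZipMonthSurface:
    """Dense location × month concentration grid for one pollutant."""

    pollutant: str
    zips: np.ndarray          # sorted location ids
    start_month: int          # month index of column 0
    values: np.ndarray        # (n_zips, n_months), NaN = missing

    @property
    def n_months(self) -> int:
        return self.values.shape[1]

    @property
    def months(self) -> np.ndarray:
        return self.start_month + np.arange(self.n_months)

    def zip_positions(self, zip_codes) -> np.ndarray:
        pos = np.searchsorted(self.zips, zip_codes)
        pos = np.clip(pos, 0, len(self.zips) - 1)
        if not np.array_equal(self.zips[pos], np.asarray(zip_codes)):
            missing = np.asarray(zip_codes)[self.zips[pos] != np.asarray(zip_codes)]
            raise ExposureError(
                f"{self.pollutant}: no exposure series for ZIP(s) {missing[:5].tolist()}"
            )
        return pos

    @classmethod
    def from_long(cls, df: pd.DataFrame, pollutant: str) -> "ZipMonthSurface":
        """Build from long format (columns zip, month [YYYY-MM or int], value)."""
        sub = df[df["pollutant"] == pollutant] if "pollutant" in df.columns else df
        if len(sub) == 0:
            raise ExposureError(f"no rows for pollutant {pollutant!r}")
        months = sub["month"]
        if months.dtype == object or str(months.dtype) == "string":
            months = pd.Series(month_index_array(months.astype(str)), index=sub.index)
        zips = np.sort(sub["zip"].unique())
        m0, m1 = int(months.min()), int(months.max())
        values = np.full((len(zips), m1 - m0 + 1), np.nan)
        zi = np.searchsorted(zips, sub["zip"].to_numpy())
        values[zi, months.to_numpy() - m0] = sub["value"].to_numpy(float)
        return cls(pollutant, zips, m0, values)

    def to_long(self) -> pd.DataFrame:
        zi, mi = np.nonzero(~np.isnan(self.values))
        return pd.DataFrame(
            {
                "pollutant": self.pollutant,
                "zip": self.zips[zi],
                "month": [month_str(self.start_month + m) for m in mi],
                "value": self.values[zi, mi],
            }
        )


# ---------------------------------------------------------------------------
# geometry

def haversine_miles(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in miles; broadcasts over array inputs."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def match_to_grid(centroids: pd.DataFrame, grid: pd.DataFrame) -> pd.Series:
    """Nearest grid point for each ZIP centroid (ties -> smaller point id).

    ``centroids``: columns zip, lat, lon; ``grid``: columns point, lat, lon.
    """
    if len(grid) == 0:
        raise ExposureError("empty exposure grid")
    g = grid.sort_values("point").reset_index(drop=True)
    d = haversine_miles(
        centroids["lat"].to_numpy()[:, None],
        centroids["lon"].to_numpy()[:, None],
        g["lat"].to_numpy()[None, :],
        g["lon"].to_numpy()[None, :],
    )
    # argmin returns the first minimum; grid sorted by id => smaller id on ties
    best = np.argmin(d, axis=1)
    return pd.Series(g["point"].to_numpy()[best], index=centroids["zip"].to_numpy())


def monitor_subset(
    centroids: pd.DataFrame, monitors: pd.DataFrame, radius_miles: float = 6.0
) -> np.ndarray:
    """ZIPs whose centroid lies within ``radius_miles`` of any monitor."""
    if len(centroids) == 0 or len(monitors) == 0:
        raise ExposureError("need non-empty centroid and monitor sets")
    d = haversine_miles(
        centroids["lat"].to_numpy()[:, None],
        centroids["lon"].to_numpy()[:, None],
        monitors["lat"].to_numpy()[None, :],
        monitors["lon"].to_numpy()[None, :],
    )
    keep = (d <= radius_miles).any(axis=1)
    return centroids["zip"].to_numpy()[keep]


# ---------------------------------------------------------------------------
# averaging

def moving_average_12(values: np.ndarray, window: int = 12) -> np.ndarray:
    """Trailing mean over months t-window+1..t along the last axis.

    Output month t is NaN unless all ``window`` months are present — a
    missing month signals a missing exposure for that person-month rather
    than being imputed.
    """
    v = np.asarray(values, float)
    mask = np.isfinite(v)
    filled = np.where(mask, v, 0.0)
    pad = [(0, 0)] * (v.ndim - 1) + [(1, 0)]
    cs = np.pad(np.cumsum(filled, axis=-1), pad)
    cn = np.pad(np.cumsum(mask, axis=-1), pad)
    out = np.full_like(v, np.nan)
    sl = (Ellipsis, slice(window - 1, None))
    total = cs[..., window:] - cs[..., :-window]
    count = cn[..., window:] - cn[..., :-window]
    with np.errstate(invalid="ignore"):
        out[sl] = np.where(count == window, total / window, np.nan)
    return out


def warm_season_ozone(
    daily: pd.Series, year: int, max_missing_frac: float = 0.25
) -> float:
    """Warm-season (Apr-Sep) mean of daily 1-h maximum ozone for one year.

    ``daily`` is indexed by datetime-like values. Returns NaN (the
    missing-ozone signal) when more than ``max_missing_frac`` of the season's
    days are absent or NaN.
    """
    idx = pd.DatetimeIndex(daily.index)
    sel = (idx.year == year) & np.isin(idx.month, WARM_SEASON_MONTHS)
    vals = daily[sel].astype(float)
    n_days = sum(
        pd.Period(f"{year}-{m:02d}").days_in_month for m in WARM_SEASON_MONTHS
    )
    n_ok = int(vals.notna().sum())
    if n_ok < (1 - max_missing_frac) * n_days:
        return float("nan")
    return float(vals.mean())


def warm_season_from_monthly(surface: ZipMonthSurface, year: int) -> pd.Series:
    """Warm-season average from monthly means, weighting months by day count."""
    months = [year * 12 + (m - 1) for m in WARM_SEASON_MONTHS]
    cols = [m - surface.start_month for m in months]
    if min(cols) < 0 or max(cols) >= surface.n_months:
        raise ExposureError(f"surface does not cover warm season {year}")
    days = np.array(
        [pd.Period(f"{year}-{m:02d}").days_in_month for m in WARM_SEASON_MONTHS], float
    )
    vals = surface.values[:, cols]
    return pd.Series((vals * days).sum(axis=1) / days.sum(), index=surface.zips)


# ---------------------------------------------------------------------------
# residence-aware person series

def residence_zip_matrix(
    cohort: pd.DataFrame,
    residence: pd.DataFrame,
    surface_zips: np.ndarray,
    start_month: int,
    n_months: int,
) -> np.ndarray:
    """(n_beneficiaries, n_months) matrix of surface-ZIP positions.

    Row order follows ``cohort``; months before a beneficiary's first
    recorded segment use the first segment's ZIP (the pre-entry exposure
    window is attributed to the entry residence).
    """
    n = len(cohort)
    id_pos = pd.Series(np.arange(n), index=cohort["id"])
    res = residence.sort_values(["id", "start_month"])
    rows = id_pos[res["id"]].to_numpy()
    zpos = np.searchsorted(surface_zips, res["zip"].to_numpy())
    if not np.array_equal(surface_zips[np.clip(zpos, 0, len(surface_zips) - 1)], res["zip"].to_numpy()):
        raise ExposureError("residence ZIP absent from exposure surface")
    cols = np.clip(res["start_month"].to_numpy() - start_month, 0, n_months - 1)

    mat = np.full((n, n_months), -1, dtype=np.int32)
    mat[rows, cols] = zpos  # later segments at the same clipped column overwrite
    # forward fill along time
    have = mat >= 0
    idx = np.where(have, np.arange(n_months)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    mat = mat[np.arange(n)[:, None], idx]
    # back fill the pre-first-segment stub with the first segment's zip
    first = np.argmax(have, axis=1)
    first_zip = mat[np.arange(n), np.maximum(first, 0)]
    lead = np.arange(n_months)[None, :] < first[:, None]
    mat = np.where(lead, first_zip[:, None], mat)
    if (mat < 0).any():
        raise ExposureError("beneficiary with no residence segment")
    return mat


def person_month_exposure(
    cohort: pd.DataFrame,
    residence: pd.DataFrame,
    surface: ZipMonthSurface,
    window: int = 12,
) -> tuple[np.ndarray, int]:
    """Trailing ``window``-month mean exposure along each residence path.

    Returns ``(matrix, start_month)`` where ``matrix[i, t]`` is the 12-month
    average for cohort row *i* in calendar month ``start_month + t`` (NaN
    where the window is incomplete).
    """
    zmat = residence_zip_matrix(
        cohort, residence, surface.zips, surface.start_month, surface.n_months
    )
    monthly = surface.values[zmat, np.arange(surface.n_months)[None, :]]
    return moving_average_12(monthly, window=window), surface.start_month


# ---------------------------------------------------------------------------
# restriction analyses

def restrict_low_pm(zip_means: pd.Series, threshold: float) -> np.ndarray:
    """ZIPs with study-period mean PM2.5 strictly below ``threshold`` µg/m³."""
    s = pd.Series(zip_means)
    return s.index.to_numpy()[s.to_numpy(float) < threshold]


# ---------------------------------------------------------------------------
# two-stage non-traffic PM2.5


@dataclass
class ResidualModel:
    """Stage-1 OLS of 12-month PM2.5 on 12-month NO2; residual = non-traffic PM2.5."""

    intercept: float
    slope: float
    residuals: np.ndarray = field(repr=False)

    def predict_residual(self, pm25_12mo, no2_12mo) -> np.ndarray:
        return (
            np.asarray(pm25_12mo, float)
            - self.intercept
            - self.slope * np.asarray(no2_12mo, float)
        )


def fit_residual_model(pm25_12mo, no2_12mo) -> ResidualModel:
    """OLS (with intercept) of PM2.5 on NO2 over pooled ZIP-month observations."""
    y = np.asarray(pm25_12mo, float)
    x = np.asarray(no2_12mo, float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(np.unique(x)) < 2:
        raise ExposureError("constant NO2 regressor: singular stage-1 design")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return ResidualModel(float(beta[0]), float(beta[1]), resid)


def validate_residual_vs_tracers(
    annual: pd.DataFrame, tracers: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of annual-average residual and total PM2.5 with tracers.

    ``annual``: columns zip, year, pm25, residual. ``tracers``: columns zip,
    year, species, value. Purely descriptive — the report mirrors the
    validation one would run against speciation-network measurements.
    """
    from scipy import stats

    rows = []
    for species, sub in tracers.groupby("species"):
        merged = annual.merge(sub, on=["zip", "year"])
        if len(merged) < 3:
            raise ExposureError(f"<3 aligned ZIP-years for tracer {species!r}")
        for col in ("residual", "pm25"):
            r, p = stats.pearsonr(merged[col], merged["value"])
            rows.append(
                {"species": species, "exposure": col, "r": r, "p": p, "n": len(merged)}
            )
    return pd.DataFrame(rows)
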