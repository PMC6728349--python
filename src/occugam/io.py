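"""Delimited-text readers/writers and covariate preparation.

All tables are comma-delimited UTF-8 with header rows; missing values are
empty fields.  Detection data travel in long format (site_id, year,
replicate, detected, wind, first_year, protocol, observer_id); sites as
(site_id, latitude, longitude); climate covariates either pre-derived
(site_id, year, var1..var5) or as monthly series from which the five
bioclim summaries are computed for the June-May year preceding each
survey.  Every writer's output is re-readable by the paired reader.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from occugam.basis import SiteCoordinates
from occugam.model import N_CLIMATE, OccupancyData

BIOCLIM_NAMES = [
    "mean_temp", "diurnal_range", "wettest_quarter_temp",
    "annual_precip", "warmest_quarter_precip",
]


def atomic_write_csv(df: pd.DataFrame, path: str) -> None:
    """Write a CSV atomically (temp file + rename) so failures leave no
    partial outputs."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# sites


def read_sites(path: str) -> SiteCoordinates:
    df = pd.read_csv(path)
    for col in ("site_id", "latitude", "longitude"):
        if col not in df.columns:
            raise ValueError(f"sites file {path} is missing column '{col}'")
    bad = df.index[~np.isfinite(df["latitude"]) | ~np.isfinite(df["longitude"])]
    if len(bad):
        raise ValueError(f"sites file {path}: non-finite coordinates at rows {list(bad + 2)}")
    return SiteCoordinates(df["site_id"].to_numpy(), df["latitude"].to_numpy(float),
                           df["longitude"].to_numpy(float))


def write_sites(coords: SiteCoordinates, path: str) -> None:
    atomic_write_csv(pd.DataFrame({
        "site_id": coords.site_id, "latitude": coords.latitude,
        "longitude": coords.longitude,
    }), path)


# ---------------------------------------------------------------------------
# detections (long format)


def write_detections(data: OccupancyData, path: str, years=None) -> None:
    years = np.arange(data.n_periods) if years is None else np.asarray(years)
    ii, tt = np.nonzero(data.observed)
    recs = []
    for i, t in zip(ii, tt):
        for j in range(data.J):
            recs.append((
                data.coords.site_id[i], years[t], j + 1, int(data.h[i, j, t]),
                int(data.wind[i, t]), int(data.first_year[i, t]),
                int(data.protocol[i, t]), int(data.observer_id[i, t]),
            ))
    atomic_write_csv(pd.DataFrame(recs, columns=[
        "site_id", "year", "replicate", "detected", "wind", "first_year",
        "protocol", "observer_id",
    ]), path)


def write_covariates(data: OccupancyData, path: str, years=None) -> None:
    years = np.arange(data.n_periods) if years is None else np.asarray(years)
    recs = []
    for i in range(data.n_sites):
        for t in range(data.n_periods):
            recs.append((data.coords.site_id[i], years[t], *data.X[i, t]))
    atomic_write_csv(pd.DataFrame(
        recs, columns=["site_id", "year"] + [f"var{m+1}" for m in range(N_CLIMATE)]
    ), path)


def read_occupancy_data(detections_path: str, sites_path: str,
                        covariates_path: str) -> tuple[OccupancyData, np.ndarray]:
    """Assemble an OccupancyData from the three CSVs.

    Returns (data, years) with years the sorted distinct survey years.
    Rows violating the schema raise with a row-numbered message.
    """
    coords = read_sites(sites_path)
    det = pd.read_csv(detections_path)
    need = ["site_id", "year", "replicate", "detected", "wind", "first_year",
            "protocol", "observer_id"]
    for col in need:
        if col not in det.columns:
            raise ValueError(f"detections file is missing column '{col}'")
    bad = det.index[~det["detected"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"detections file: 'detected' not in {{0,1}} at rows {list(bad + 2)}")
    cov = pd.read_csv(covariates_path)
    var_cols = [f"var{m+1}" for m in range(N_CLIMATE)]
    for col in ["site_id", "year"] + var_cols:
        if col not in cov.columns:
            raise ValueError(f"covariates file is missing column '{col}'")

    site_index = {s: i for i, s in enumerate(coords.site_id)}
    unknown = set(det["site_id"]) - set(site_index)
    if unknown:
        raise ValueError(f"detections reference unknown site_ids: {sorted(unknown)[:5]}")
    years = np.sort(det["year"].unique())
    year_index = {y: t for t, y in enumerate(years)}
    N, T = len(coords), len(years)
    J = int(det["replicate"].max())
    h = np.zeros((N, J, T), dtype=np.int8)
    observed = np.zeros((N, T), dtype=bool)
    wind = np.zeros((N, T), dtype=int)
    first_year = np.zeros((N, T), dtype=np.int8)
    protocol = np.zeros((N, T), dtype=np.int8)
    observer_id = np.full((N, T), -1, dtype=int)
    for row in det.itertuples(index=False):
        i, t = site_index[row.site_id], year_index[row.year]
        j = int(row.replicate) - 1
        h[i, j, t] = int(row.detected)
        observed[i, t] = True
        wind[i, t] = int(row.wind)
        first_year[i, t] = int(row.first_year)
        protocol[i, t] = int(row.protocol)
        observer_id[i, t] = int(row.observer_id)
    # re-code observers densely
    used = np.unique(observer_id[observed])
    recode = {o: k for k, o in enumerate(used)}
    for i, t in zip(*np.nonzero(observed)):
        observer_id[i, t] = recode[observer_id[i, t]]

    X = np.full((N, T, N_CLIMATE), np.nan)
    for row in cov.itertuples(index=False):
        if row.site_id not in site_index or row.year not in year_index:
            continue
        X[site_index[row.site_id], year_index[row.year]] = [
            getattr(row, c) for c in var_cols
        ]
    data = OccupancyData(h=h, observed=observed, wind=wind, first_year=first_year,
                         protocol=protocol, observer_id=observer_id, X=X, coords=coords)
    return data, years


# ---------------------------------------------------------------------------
# raw counts and climate preparation


def counts_to_presence(raw_counts: np.ndarray) -> np.ndarray:
    """Stop-group counts -> binary replicate indicators (1 iff count > 0)."""
    raw_counts = np.asarray(raw_counts)
    if np.any(raw_counts < 0):
        raise ValueError("counts must be nonnegative")
    return (raw_counts > 0).astype(np.int8)


@dataclass
class MonthlyClimate:
    """One cell-year of monthly climate, June -> May preceding the survey."""

    precip: np.ndarray   # (12,) total precipitation, mm
    tmin: np.ndarray     # (12,) mean daily minimum temperature, degrees C
    tmax: np.ndarray     # (12,) mean daily maximum temperature, degrees C

    def __post_init__(self) -> None:
        for name in ("precip", "tmin", "tmax"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains missing months")
            object.__setattr__(self, name, arr)
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be nonnegative")


def monthly_to_bioclim(mc: MonthlyClimate) -> np.ndarray:
    """The five bioclim covariates from one June-May monthly series.

    Quarters are the 12 wrapping 3-month windows of the June-May year.
    Returns (mean_temp, mean_diurnal_range, wettest_quarter_mean_temp,
    annual_precip, warmest_quarter_total_precip).
    """
    tavg = 0.5 * (mc.tmin + mc.tmax)
    win = (np.arange(12)[:, None] + np.arange(3)[None, :]) % 12   # (12, 3)
    q_precip = mc.precip[win].sum(axis=1)
    q_temp = tavg[win].mean(axis=1)
    wettest = int(np.argmax(q_precip))
    warmest = int(np.argmax(q_temp))
    return np.array([
        tavg.mean(),
        float(np.mean(mc.tmax - mc.tmin)),
        q_temp[wettest],
        mc.precip.sum(),
        q_precip[warmest],
    ])


# ---------------------------------------------------------------------------
# covariate standardization


def standardize_covariates(X_raw: np.ndarray, mask: np.ndarray | None = None):
    """Scale each covariate to mean 0, sd 1 over observed cells.

    Returns (X_std, transform); the stored transform is applied unchanged
    to prediction grids via :func:`apply_standardization`.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    flat = X_raw.reshape(-1, X_raw.shape[-1])
    if mask is not None:
        flat = flat[np.asarray(mask).ravel()]
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance covariate column(s): {[int(z) for z in zero]}")
    transform = {"mean": mean, "sd": sd}
    return (X_raw - mean) / sd, transform


def apply_standardization(X_raw: np.ndarray, transform: dict) -> np.ndarray:
    return (np.asarray(X_raw, dtype=float) - transform["mean"]) / transform["sd"]


def unstandardize(X_std: np.ndarray, transform: dict) -> np.ndarray:
    return np.asarray(X_std, dtype=float) * transform["sd"] + transform["mean"]
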