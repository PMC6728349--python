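"""Posterior occupancy maps and range-dynamics indices.

Occupancy is predicted on a regular raster of cell centres (0.5 degrees by
default) restricted to a buffered convex hull around the occupied survey
routes, by evaluating the fitted spline basis and climate terms under each
posterior draw.  Four per-year indices summarise range dynamics:

* proportion of area occupied (PAO): mean occupancy over included cells;
* mean breeding latitude: occupancy-weighted mean cell latitude;
* northern / southern range limits: the latitudes above/below which only a
  0.1% tail of the total occupancy mass lies, read off a monotone
  (shape-preserving) interpolant of the cumulative occupancy curve over
  sorted cell latitudes.

Cells are equally weighted (no cos-latitude correction) and cells sharing
a latitude are aggregated before the cumulative curve is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit
from shapely.geometry import MultiPoint, Point

from occugam.basis import SiteCoordinates, SplineBasis, evaluate_basis
from occugam.model import N_CLIMATE
from occugam.sampler import PosteriorSamples


@dataclass
class PredictionGrid:
    """Raster cell centres with per-cell-year covariates.

    ``X`` must already be standardized with the training transform.
    """

    cell_id: np.ndarray           # (M,)
    center_latitude: np.ndarray   # (M,) degrees
    center_longitude: np.ndarray  # (M,) degrees
    X: np.ndarray                 # (M, T, 5) standardized covariates
    inclusion_mask: np.ndarray | None = None  # (M,) bool

    def __post_init__(self) -> None:
        M = self.cell_id.shape[0]
        if self.center_latitude.shape != (M,) or self.center_longitude.shape != (M,):
            raise ValueError("cell centre arrays must be 1-D of equal length")
        if self.X.ndim != 3 or self.X.shape[0] != M or self.X.shape[2] != N_CLIMATE:
            raise ValueError(f"X must be (M, T, {N_CLIMATE})")
        if self.inclusion_mask is None:
            self.inclusion_mask = np.ones(M, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.cell_id.shape[0]

    @property
    def coords(self) -> SiteCoordinates:
        return SiteCoordinates(self.cell_id, self.center_latitude, self.center_longitude)


@dataclass
class RangeIndexSeries:
    """Posterior summaries (mean, 95% credible bounds) of the four indices per year."""

    summary: pd.DataFrame         # columns: year, index, mean, lo95, hi95
    draws: dict = field(default_factory=dict)  # index name -> (n_draws, T) array

    def series(self, index: str) -> pd.DataFrame:
        return self.summary[self.summary["index"] == index].reset_index(drop=True)


def make_grid(lat_range, lon_range, spacing: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Regular lattice of cell centres covering the given ranges."""
    lats = np.arange(lat_range[0] + spacing / 2, lat_range[1], spacing)
    lons = np.arange(lon_range[0] + spacing / 2, lon_range[1], spacing)
    glon, glat = np.meshgrid(lons, lats)
    return glat.ravel(), glon.ravel()


def buffered_hull_mask(occupied_coords: SiteCoordinates, grid: PredictionGrid,
                       buffer_deg: float = 2.0) -> np.ndarray:
    """Cells whose centre lies inside the convex hull of the occupied sites
    dilated by ``buffer_deg`` (degree units, unprojected)."""
    if len(occupied_coords) < 3:
        raise ValueError("need at least 3 occupied sites to form a hull")
    pts = MultiPoint([(lon, lat) for lat, lon in occupied_coords.xy])
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("occupied sites are collinear; the hull is degenerate")
    region = hull.buffer(buffer_deg) if buffer_deg > 0 else hull
    return np.array([
        region.covers(Point(lon, lat))
        for lat, lon in zip(grid.center_latitude, grid.center_longitude)
    ])


def predict_occupancy(samples: PosteriorSamples, basis: SplineBasis,
                      grid: PredictionGrid, thin: int = 1) -> np.ndarray:
    """Per-draw occupancy probability at every included cell-year.

    Returns an array of shape (n_draws, M, T) over the included cells
    (rows of the grid where ``inclusion_mask`` is True).
    """
    mask = grid.inclusion_mask
    if not np.isfinite(grid.X[mask]).all():
        raise ValueError("missing covariates for included cells")
    coords = SiteCoordinates(grid.cell_id[mask], grid.center_latitude[mask],
                             grid.center_longitude[mask])
    G = evaluate_basis(basis, coords)                      # (M, K)
    Xf = np.concatenate([grid.X[mask], grid.X[mask] ** 2], axis=2)  # (M, T, 10)
    nu = samples.stacked("nu")[::thin]                     # (D, K, T)
    beta = samples.stacked("beta")[::thin]
    omega = samples.stacked("omega")[::thin]
    smooth = np.einsum("mk,dkt->dmt", G, nu)
    clim = np.einsum("mtq,dq->dmt", Xf, omega * beta)
    return expit(smooth + clim)


def proportion_area_occupied(psi_map: np.ndarray) -> float:
    """Mean occupancy probability over the map cells of one draw-year."""
    psi_map = np.asarray(psi_map, dtype=float)
    if psi_map.size == 0:
        raise ValueError("empty occupancy map")
    return float(psi_map.mean())


def mean_breeding_latitude(psi_map: np.ndarray, latitudes: np.ndarray) -> float:
    """Occupancy-weighted mean latitude: sum(lat * psi) / sum(psi)."""
    psi_map = np.asarray(psi_map, dtype=float)
    latitudes = np.asarray(latitudes, dtype=float)
    tot = psi_map.sum()
    if tot <= 0:
        raise ValueError("total occupancy probability is zero")
    return float((latitudes * psi_map).sum() / tot)


def range_limits(psi_map: np.ndarray, latitudes: np.ndarray,
                 tail_mass: float = 0.001) -> tuple[float, float]:
    """(southern, northern) latitudes bounding 1 - 2*tail_mass of occupancy mass.

    Cells sharing a latitude are aggregated; the cumulative occupancy
    fraction over sorted latitudes is inverted with a monotone PCHIP
    interpolant anchored at (0, southernmost latitude with mass).
    """
    psi_map = np.asarray(psi_map, dtype=float)
    latitudes = np.asarray(latitudes, dtype=float)
    lat_u, inv = np.unique(latitudes, return_inverse=True)
    mass = np.bincount(inv, weights=psi_map, minlength=lat_u.size)
    pos = mass > 0
    lat_u, mass = lat_u[pos], mass[pos]
    if lat_u.size < 2:
        raise ValueError("need occupancy mass at >= 2 distinct latitudes")
    frac = np.cumsum(mass) / mass.sum()
    x = np.concatenate([[0.0], frac])
    ylat = np.concatenate([[lat_u[0]], lat_u])
    # guard against numerically duplicated cumulative values
    keep = np.concatenate([[True], np.diff(x) > 1e-12])
    interp = PchipInterpolator(x[keep], ylat[keep])
    south = float(interp(tail_mass))
    north = float(interp(1.0 - tail_mass))
    lo, hi = float(lat_u[0]), float(lat_u[-1])
    return (min(max(south, lo), hi), min(max(north, lo), hi))


def net_change_map(psi_first: np.ndarray, psi_last: np.ndarray) -> pd.DataFrame:
    """Draw-wise posterior summaries of the per-cell change psi_T - psi_1.

    ``psi_first`` and ``psi_last`` are (n_draws, M) arrays on the same grid.
    """
    psi_first = np.asarray(psi_first, dtype=float)
    psi_last = np.asarray(psi_last, dtype=float)
    if psi_first.shape != psi_last.shape:
        raise ValueError("first- and last-year maps must share draws and grid")
    diff = psi_last - psi_first
    return pd.DataFrame({
        "mean": diff.mean(axis=0),
        "lo95": np.quantile(diff, 0.025, axis=0),
        "hi95": np.quantile(diff, 0.975, axis=0),
    })


def compute_range_indices(psi: np.ndarray, latitudes: np.ndarray,
                          tail_mass: float = 0.001,
                          years: np.ndarray | None = None) -> RangeIndexSeries:
    """All four indices per posterior draw and year, with 95% credible bounds.

    ``psi`` is the (n_draws, M, T) output of :func:`predict_occupancy`.
    The draw-wise ordering south_limit <= mean latitude <= north_limit is
    guaranteed by construction of the monotone cumulative curve.
    """
    D, M, T = psi.shape
    years = np.arange(T) if years is None else np.asarray(years)
    out = {name: np.empty((D, T)) for name in
           ("pao", "mean_lat", "south_limit", "north_limit")}
    for d in range(D):
        for t in range(T):
            pm = psi[d, :, t]
            out["pao"][d, t] = proportion_area_occupied(pm)
            out["mean_lat"][d, t] = mean_breeding_latitude(pm, latitudes)
            s, n = range_limits(pm, latitudes, tail_mass)
            out["south_limit"][d, t] = s
            out["north_limit"][d, t] = n
    rows = []
    for name, arr in out.items():
        for t in range(T):
            rows.append({
                "year": years[t], "index": name, "mean": arr[:, t].mean(),
                "lo95": np.quantile(arr[:, t], 0.025),
                "hi95": np.quantile(arr[:, t], 0.975),
            })
    return RangeIndexSeries(summary=pd.DataFrame(rows), draws=out)
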