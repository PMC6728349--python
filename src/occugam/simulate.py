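"""Synthetic data with the exact statistical structure the model assumes.

The generator is the test-bed for every stage of the pipeline: it draws a
smooth occupancy surface from the spline prior (penalised wiggly part plus
a proper Gaussian on the affine null space), evolves it through time by the
coefficient random walk, layers route occupancy, the stop-level Markov
availability chain, and logit-linear detection with observer random
effects on top, and returns both the dataset and the full generating truth.

Climate covariates are standard normal with AR(1) year-to-year correlation
(default 0.8), mimicking slowly varying climate without external data;
route-years are dropped independently at a stated missingness rate to
emulate incomplete survey coverage.  Observers hold a route for a
multi-year stint of geometric length (mean 7 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from occugam.basis import SiteCoordinates, SplineBasis, build_tprs_basis
from occugam.model import N_CLIMATE, ModelParams, OccupancyData

DEFAULT_WINDOW = ((30.0, 45.0), (-95.0, -75.0))  # (lat range, lon range)


@dataclass
class SimDesign:
    """Study design and generating parameter values.

    Defaults are the conditions used throughout the test-bed: moderate
    availability (theta = 0.4, theta' = 0.8, pi = 0.75), detection
    intercept alpha0 = 0.8 with small negative wind / first-year /
    protocol effects, a slowly drifting surface (sigma2_rw = 0.05) and
    15% missing route-years.
    """

    n_sites: int = 150
    n_periods: int = 6
    J: int = 5
    K: int | None = 12            # None -> affine surface (no spline), for tiny designs
    sigma2_rw: float = 0.05
    lam: float = 2.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(2 * N_CLIMATE))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(2 * N_CLIMATE, dtype=int))
    alpha: np.ndarray = field(default_factory=lambda: np.array([0.8, -0.1, -0.2, -0.2]))
    theta: float = 0.4
    theta_prime: float = 0.8
    pi: float = 0.75              # first-stop availability, constant across years
    sigma2_obs: float = 0.25
    missing_rate: float = 0.15
    covariate_ar1: float = 0.8
    observer_mean_tenure: float = 7.0
    intercept: float = 0.5        # mean of the surface's constant coefficient
    lat_trend: float = 0.0        # per-period drift added to the latitude slope (scaled coords)
    window: tuple = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=int)
        if np.any((self.omega[N_CLIMATE:] == 1) & (self.omega[:N_CLIMATE] == 0)):
            raise ValueError("design violates marginality")


@dataclass
class SyntheticTruth:
    """Everything the generator used, for recovery checks."""

    design: SimDesign
    seed: int
    nu: np.ndarray | None        # (K, T) or None for affine designs
    beta: np.ndarray
    omega: np.ndarray
    sigma2_rw: float
    pi_t: np.ndarray
    theta: float
    theta_prime: float
    alpha: np.ndarray
    eta: np.ndarray
    sigma2_obs: float
    psi: np.ndarray              # (N, T) true occupancy probability
    z: np.ndarray                # (N, T)
    y: np.ndarray                # (N, J, T)
    basis: SplineBasis | None = None

    def params(self) -> ModelParams:
        if self.nu is None:
            raise ValueError("affine designs carry no spline coefficients")
        return ModelParams(
            nu=self.nu, beta=self.beta, omega=self.omega, sigma2_rw=self.sigma2_rw,
            lam=self.design.lam, pi_t=self.pi_t, theta=self.theta,
            theta_prime=self.theta_prime, alpha=self.alpha, eta=self.eta,
            sigma2_obs=self.sigma2_obs,
        )


def _draw_sites(n_sites: int, window, rng) -> SiteCoordinates:
    (lat_lo, lat_hi), (lon_lo, lon_hi) = window
    return SiteCoordinates(
        site_id=np.arange(n_sites),
        latitude=rng.uniform(lat_lo, lat_hi, n_sites),
        longitude=rng.uniform(lon_lo, lon_hi, n_sites),
    )


def _draw_nu(basis: SplineBasis, n_periods: int, sigma2_rw: float, lam: float,
             rng, intercept: float = 0.0, null_sd: float = 1.0,
             lat_trend: float = 0.0) -> np.ndarray:
    """nu_{.,1} from the penalised prior (null-space coefficients from a
    proper Gaussian), then the Gaussian random walk, plus an optional
    deterministic drift on the latitude slope."""
    K = basis.K
    nd = basis.null_space_dim
    S_pen = basis.penalty_matrix[: K - nd, : K - nd]
    evals, evecs = np.linalg.eigh(S_pen)
    evals = np.maximum(evals, 1e-12)
    # wiggly part ~ N(0, (lam * S_pen)^-1)
    wiggly = evecs @ (rng.standard_normal(K - nd) / np.sqrt(lam * evals))
    null = null_sd * rng.standard_normal(nd)
    null[0] += intercept
    nu = np.empty((K, n_periods))
    nu[:, 0] = np.concatenate([wiggly, null])
    for t in range(1, n_periods):
        nu[:, t] = nu[:, t - 1] + np.sqrt(sigma2_rw) * rng.standard_normal(K)
    if lat_trend != 0.0:
        lat_idx = K - nd + 1  # [const, lat, lon] ordering of the null block
        nu[lat_idx, :] += lat_trend * np.arange(n_periods)
    return nu


def simulate_surface(n_sites: int, n_periods: int, K: int, sigma2_rw: float,
                     lam: float, seed: int, window=DEFAULT_WINDOW,
                     intercept: float = 0.0, null_sd: float = 1.0,
                     lat_trend: float = 0.0):
    """Sites, spline basis, coefficient paths and the smooth surface f_t.

    Returns (coords, basis, nu, f) with f of shape (n_sites, n_periods).
    """
    if K > n_sites:
        raise ValueError("K must not exceed the number of sites")
    rng = np.random.default_rng(seed)
    coords = _draw_sites(n_sites, window, rng)
    basis = build_tprs_basis(coords, K)
    nu = _draw_nu(basis, n_periods, sigma2_rw, lam, rng,
                  intercept=intercept, null_sd=null_sd, lat_trend=lat_trend)
    f = basis.basis_matrix @ nu
    return coords, basis, nu, f


def _draw_covariates(n_sites: int, n_periods: int, rho: float, rng) -> np.ndarray:
    """Standard-normal climate covariates with AR(1) correlation across years."""
    X = np.empty((n_sites, n_periods, N_CLIMATE))
    X[:, 0] = rng.standard_normal((n_sites, N_CLIMATE))
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, n_periods):
        X[:, t] = rho * X[:, t - 1] + innov_sd * rng.standard_normal((n_sites, N_CLIMATE))
    return X


def _assign_observers(n_sites: int, n_periods: int, mean_tenure: float, rng) -> np.ndarray:
    """Observer codes per route-year: consecutive stints of geometric length."""
    oid = np.empty((n_sites, n_periods), dtype=int)
    next_id = 0
    for i in range(n_sites):
        t = 0
        while t < n_periods:
            stint = int(rng.geometric(1.0 / mean_tenure))
            oid[i, t: t + stint] = next_id
            next_id += 1
            t += stint
    return oid


def simulate_dataset(design: SimDesign, seed: int):
    """Draw a complete dataset (z, y, h sequentially per the model).

    Returns (OccupancyData, SyntheticTruth).  Regenerating with the same
    design and seed reproduces the dataset bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    N, T, J = design.n_sites, design.n_periods, design.J
    coords = _draw_sites(N, design.window, rng)
    basis = None
    nu = None
    if design.K is not None:
        basis = build_tprs_basis(coords, design.K)
        nu = _draw_nu(basis, T, design.sigma2_rw, design.lam, rng,
                      intercept=design.intercept, lat_trend=design.lat_trend)
        f = basis.basis_matrix @ nu
    else:
        # affine surface for designs too small to carry a spline
        lat_c = (coords.latitude - coords.latitude.mean()) / max(np.ptp(coords.latitude), 1e-9)
        lon_c = (coords.longitude - coords.longitude.mean()) / max(np.ptp(coords.longitude), 1e-9)
        f = (design.intercept + 1.0 * lat_c[:, None] - 0.5 * lon_c[:, None]
             + design.lat_trend * np.arange(T)[None, :] * lat_c[:, None])
        f = np.broadcast_to(f, (N, T)).copy()

    X = _draw_covariates(N, T, design.covariate_ar1, rng)
    Xf = np.concatenate([X, X**2], axis=2)
    psi = expit(f + Xf @ (design.omega * design.beta))

    z = (rng.random((N, T)) < psi).astype(np.int8)
    y = np.zeros((N, J, T), dtype=np.int8)
    y[:, 0, :] = (rng.random((N, T)) < design.pi) & (z == 1)
    for j in range(1, J):
        pj = np.where(y[:, j - 1, :] == 1, design.theta_prime, design.theta)
        y[:, j, :] = (rng.random((N, T)) < pj) & (z == 1)

    oid = _assign_observers(N, T, design.observer_mean_tenure, rng)
    n_observers = int(oid.max()) + 1
    eta = np.sqrt(design.sigma2_obs) * rng.standard_normal(n_observers)
    wind = rng.integers(0, 6, size=(N, T))
    first_year = np.zeros((N, T), dtype=np.int8)
    first_year[:, 0] = 1
    for t in range(1, T):
        first_year[:, t] = oid[:, t] != oid[:, t - 1]
    protocol = (rng.random((N, T)) < 0.03).astype(np.int8)
    a = design.alpha
    p = expit(a[0] + a[1] * wind + a[2] * first_year + a[3] * protocol + eta[oid])
    h = ((rng.random((N, J, T)) < p[:, None, :]) & (y == 1)).astype(np.int8)

    observed = rng.random((N, T)) >= design.missing_rate
    data = OccupancyData(
        h=h, observed=observed, wind=wind, first_year=first_year,
        protocol=protocol, observer_id=oid, X=X, coords=coords,
    )
    truth = SyntheticTruth(
        design=design, seed=seed, nu=nu, beta=design.beta.copy(),
        omega=design.omega.copy(), sigma2_rw=design.sigma2_rw,
        pi_t=np.full(T, design.pi), theta=design.theta,
        theta_prime=design.theta_prime, alpha=a.copy(), eta=eta,
        sigma2_obs=design.sigma2_obs, psi=psi, z=z, y=y, basis=basis,
    )
    return data, truth


_FIXTURES = {
    # 3 sites x 2 years, affine surface: small enough for exhaustive oracles
    "tiny": SimDesign(n_sites=3, n_periods=2, K=None, missing_rate=0.0,
                      intercept=0.0, sigma2_obs=0.1),
    # 300 sites x 6 years, 2 of 5 linear climate terms active: GVS tests
    "selection": SimDesign(
        n_sites=300, n_periods=6, K=12,
        beta=np.array([1.0, -0.7, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float),
        omega=np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]),
    ),
    # 150 sites x 10 years with an imposed northward trend: index tests
    "shift": SimDesign(n_sites=150, n_periods=10, K=12, sigma2_rw=0.01,
                       lat_trend=0.35, intercept=0.0),
}


def make_fixture(name: str, seed: int = 20240601):
    """Canned datasets: 'tiny', 'selection' or 'shift' (see module docstring)."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return simulate_dataset(_FIXTURES[name], seed)
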