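"""Probability model: state process, availability, detection, and priors.

The model has three stacked binary layers per surveyed route-year (i, t):

* occupancy       z_{i,t} ~ Bernoulli(psi_{i,t}),
                  logit(psi_{i,t}) = sum_k g_k(i) nu_{k,t} + sum_m omega_m beta_m x_m
* availability    y_{i,1,t} ~ Bernoulli(z pi_t) at the first stop group and
                  y_{i,j,t} | y_{i,j-1,t} ~ Bernoulli(z theta) or
                  Bernoulli(z theta') for j > 1 (first-order Markov chain)
* detection       h_{i,j,t} ~ Bernoulli(z y p_{i,t}),
                  logit(p) = a0 + a1 wind + a2 first_year + a3 protocol + eta_obs

The smooth coefficients nu_{.,1} carry a wiggliness penalty prior with
precision lambda * S (plus a proper wide Gaussian on the 3-dimensional
penalty null space); for t > 1 they follow a Gaussian random walk with
variance sigma^2.  Climate covariates (5 linear + 5 quadratic terms) are
selected by binary inclusion indicators omega with Gibbs-variable-selection
pseudo-priors and a marginality constraint: a quadratic term may enter only
if its linear term is in the model.

This module exposes exact evaluators (marginal likelihood of a replicate
history with the latent layers summed out, log prior, log joint) used both
for testing and by the samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from occugam.basis import SiteCoordinates, SplineBasis

N_CLIMATE = 5  # linear climate covariates; quadratic terms double this


# ---------------------------------------------------------------------------
# domain types


@dataclass
class OccupancyData:
    """Detection histories and covariates for N sites x T primary periods.

    Arrays are indexed (site i, replicate j, period t); a route-year is
    surveyed or not as a whole, recorded in ``observed``.
    """

    h: np.ndarray              # (N, J, T) binary; arbitrary where unobserved
    observed: np.ndarray       # (N, T) bool survey mask
    wind: np.ndarray           # (N, T) int wind score
    first_year: np.ndarray     # (N, T) binary first-year-observer flag
    protocol: np.ndarray       # (N, T) binary; 1 = time-distance protocol
    observer_id: np.ndarray    # (N, T) int codes >= 0 (-1 where unobserved)
    X: np.ndarray              # (N, T, 5) standardized climate covariates
    coords: SiteCoordinates

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h)
        self.observed = np.asarray(self.observed, dtype=bool)
        N, J, T = self.h.shape
        if self.observed.shape != (N, T):
            raise ValueError("observed mask must be (N, T)")
        for name in ("wind", "first_year", "protocol", "observer_id"):
            if getattr(self, name).shape != (N, T):
                raise ValueError(f"{name} must be (N, T)")
        if self.X.shape != (N, T, N_CLIMATE):
            raise ValueError(f"X must be (N, T, {N_CLIMATE})")
        if len(self.coords) != N:
            raise ValueError("coords must match the number of sites")
        ii, tt = np.nonzero(self.observed)
        hobs = self.h[ii, :, tt]
        if hobs.size and not np.isin(hobs, [0, 1]).all():
            raise ValueError("h must be binary where observed")
        if not np.isfinite(self.X[self.observed]).all():
            raise ValueError("covariates must be finite on surveyed route-years")

    @property
    def n_sites(self) -> int:
        return self.h.shape[0]

    @property
    def J(self) -> int:
        return self.h.shape[1]

    @property
    def n_periods(self) -> int:
        return self.h.shape[2]

    @property
    def n_observers(self) -> int:
        oid = self.observer_id[self.observed]
        return int(oid.max()) + 1 if oid.size else 0

    def X_full(self) -> np.ndarray:
        """(N, T, 10) covariates: 5 standardized linear terms then their squares.

        Quadratic terms are plain squares of the standardized linear terms
        (not re-standardized), preserving the marginality interpretation.
        """
        return np.concatenate([self.X, self.X**2], axis=2)


@dataclass
class PriorConfig:
    """Hyperprior settings (vague by default; all configurable)."""

    lambda_shape: float = 0.05       # Gamma shape for the smoothing penalty
    lambda_rate: float = 0.005       # Gamma rate
    sigma_rw_scale: float = 2.0      # half-Normal scale for the RW sd sigma
    sigma_obs_scale: float = 2.0     # half-Normal scale for the observer sd
    alpha_var: float = 10.0          # Normal variance for detection coefficients
    null_space_sd: float = 10.0      # wide proper Normal sd on penalty-null coefficients of nu_{.,1}


@dataclass
class GVSConfig:
    """Gibbs-variable-selection pseudo-prior settings.

    When omega_m = 0 the idle coefficient beta_m is sampled from the
    pseudo-prior Normal(mu_pseudo[m], sigma_pseudo[m]^2); when omega_m = 1
    it carries the vague slab Normal(0, slab_variance).
    """

    mu_pseudo: np.ndarray            # (10,)
    sigma_pseudo: np.ndarray         # (10,) > 0
    slab_variance: float = 100.0

    def __post_init__(self) -> None:
        self.mu_pseudo = np.asarray(self.mu_pseudo, dtype=float)
        self.sigma_pseudo = np.asarray(self.sigma_pseudo, dtype=float)
        if self.mu_pseudo.shape != (2 * N_CLIMATE,) or self.sigma_pseudo.shape != (2 * N_CLIMATE,):
            raise ValueError(f"pseudo-prior vectors must have length {2 * N_CLIMATE}")
        if np.any(self.sigma_pseudo <= 0):
            raise ValueError("sigma_pseudo must be positive")

    @classmethod
    def default(cls) -> "GVSConfig":
        """Neutral pseudo-priors (zero mean, unit sd) for prior-only runs."""
        return cls(np.zeros(2 * N_CLIMATE), np.ones(2 * N_CLIMATE))


@dataclass
class ModelParams:
    """One complete point in parameter space."""

    nu: np.ndarray             # (K, T) spline coefficients
    beta: np.ndarray           # (10,) climate coefficients (linear then quadratic)
    omega: np.ndarray          # (10,) binary inclusion indicators
    sigma2_rw: float           # random-walk variance among periods
    lam: float                 # smoothing penalty
    pi_t: np.ndarray           # (T,) first-stop availability per period
    theta: float               # availability | previous stop unavailable
    theta_prime: float         # availability | previous stop available
    alpha: np.ndarray          # (4,) detection coefficients
    eta: np.ndarray            # (n_observers,) observer random effects
    sigma2_obs: float          # observer-effect variance

    def validate(self) -> None:
        probs = np.concatenate([np.atleast_1d(self.pi_t), [self.theta, self.theta_prime]])
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("availability probabilities must lie in [0, 1]")
        if self.sigma2_rw <= 0 or self.lam <= 0 or self.sigma2_obs <= 0:
            raise ValueError("variances and the smoothing penalty must be positive")
        if np.any((self.omega[N_CLIMATE:] == 1) & (self.omega[:N_CLIMATE] == 0)):
            raise ValueError("marginality violated: quadratic term included without its linear term")

    def copy(self) -> "ModelParams":
        return ModelParams(
            nu=self.nu.copy(), beta=self.beta.copy(), omega=self.omega.copy(),
            sigma2_rw=self.sigma2_rw, lam=self.lam, pi_t=np.atleast_1d(self.pi_t).copy(),
            theta=self.theta, theta_prime=self.theta_prime, alpha=self.alpha.copy(),
            eta=self.eta.copy(), sigma2_obs=self.sigma2_obs,
        )


# ---------------------------------------------------------------------------
# pointwise probabilities


def occupancy_prob(params: ModelParams, basis: SplineBasis, X_row: np.ndarray,
                   i: int, t: int) -> float:
    """Occupancy probability psi_{i,t} for one site-period.

    ``X_row`` holds the 5 standardized linear climate terms; quadratic
    terms are their squares.  Excluded covariates (omega = 0) contribute
    nothing regardless of beta.
    """
    X_row = np.asarray(X_row, dtype=float)
    if X_row.shape != (N_CLIMATE,):
        raise ValueError(f"X_row must contain the {N_CLIMATE} linear climate terms")
    if not np.isfinite(X_row).all():
        raise ValueError("non-finite covariates")
    x_full = np.concatenate([X_row, X_row**2])
    lin = basis.basis_matrix[i] @ params.nu[:, t] + np.sum(params.omega * params.beta * x_full)
    return float(expit(lin))


def detection_prob(alpha: np.ndarray, wind: float, first_year: float,
                   protocol: float, eta_o: float) -> float:
    """Per-stop detection probability from the logit-linear model."""
    vals = np.array([wind, first_year, protocol, eta_o], dtype=float)
    if not (np.isfinite(vals).all() and np.isfinite(alpha).all()):
        raise ValueError("non-finite detection inputs")
    lin = alpha[0] + alpha[1] * wind + alpha[2] * first_year + alpha[3] * protocol + eta_o
    return float(expit(lin))


def occupancy_logits(params: ModelParams, basis: SplineBasis, data: OccupancyData) -> np.ndarray:
    """(N, T) linear predictor of occupancy for all site-periods."""
    smooth = basis.basis_matrix @ params.nu                      # (N, T)
    clim = data.X_full() @ (params.omega * params.beta)          # (N, T)
    return smooth + clim


def detection_logits(params: ModelParams, data: OccupancyData) -> np.ndarray:
    """(N, T) linear predictor of per-stop detection for all site-periods."""
    a = params.alpha
    eta_term = np.zeros(data.observer_id.shape)
    obs = data.observed & (data.observer_id >= 0)
    if params.eta.size:
        eta_term[obs] = params.eta[data.observer_id[obs]]
    return a[0] + a[1] * data.wind + a[2] * data.first_year + a[3] * data.protocol + eta_term


# ---------------------------------------------------------------------------
# marginal likelihood of a replicate history


def _history_prob_given_occupied(h: np.ndarray, pi: np.ndarray, theta, theta_prime,
                                 p: np.ndarray) -> np.ndarray:
    """Pr(h_row | z = 1) for R route-years by forward recursion over the
    latent availability chain.  h is (R, J); pi and p broadcast over R."""
    h = np.asarray(h, dtype=float)
    R, J = h.shape
    pi = np.broadcast_to(np.asarray(pi, dtype=float), (R,))
    p = np.broadcast_to(np.asarray(p, dtype=float), (R,))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (R,))
    theta_prime = np.broadcast_to(np.asarray(theta_prime, dtype=float), (R,))
    e1 = np.where(h == 1, p[:, None], 1.0 - p[:, None])   # emission given y=1
    e0 = 1.0 - h                                          # emission given y=0
    f0 = (1.0 - pi) * e0[:, 0]
    f1 = pi * e1[:, 0]
    for j in range(1, J):
        g1 = (f0 * theta + f1 * theta_prime) * e1[:, j]
        g0 = (f0 * (1.0 - theta) + f1 * (1.0 - theta_prime)) * e0[:, j]
        f0, f1 = g0, g1
    return f0 + f1


def marginal_likelihood_vec(h: np.ndarray, psi, pi, theta, theta_prime, p) -> np.ndarray:
    """Pr(h_row) with occupancy and availability marginalised, vectorised
    over R route-years.  h is (R, J)."""
    h = np.asarray(h, dtype=float)
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (h.shape[0],))
    m1 = _history_prob_given_occupied(h, pi, theta, theta_prime, p)
    all_zero = (h.sum(axis=1) == 0).astype(float)
    return psi * m1 + (1.0 - psi) * all_zero


def route_year_marginal_loglik(h_row: np.ndarray, psi: float, pi_t: float,
                               theta: float, theta_prime: float, p: float) -> float:
    """Log Pr(h_row) for one route-year with z and y summed out.

    Exponentials over all 2^J histories sum to one for any parameter set.
    """
    h_row = np.asarray(h_row)
    if not np.isin(h_row, [0, 1]).all():
        raise ValueError("h_row must be binary")
    prob = marginal_likelihood_vec(h_row[None, :], psi, pi_t, theta, theta_prime, p)[0]
    with np.errstate(divide="ignore"):
        return float(np.log(prob))


def enumerate_histories(J: int) -> np.ndarray:
    """All 2^J binary detection histories in lexicographic order, (2^J, J)."""
    if J < 1:
        raise ValueError("J must be >= 1")
    idx = np.arange(2**J)
    return ((idx[:, None] >> np.arange(J - 1, -1, -1)) & 1).astype(np.int8)


# ---------------------------------------------------------------------------
# priors and joint density


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (np.asarray(x) - mean) ** 2 / var)


def log_prior(params: ModelParams, basis: SplineBasis, gvs: GVSConfig, T: int,
              prior: PriorConfig | None = None) -> float:
    """Log prior density of a parameter point (marginality violations give -inf).

    Parameter-dependent terms are exact; additive constants that do not
    depend on any parameter are dropped only where stated.
    """
    prior = prior or PriorConfig()
    om = params.omega
    # marginality: quadratic only with its linear term
    if np.any((om[N_CLIMATE:] == 1) & (om[:N_CLIMATE] == 0)):
        return -np.inf
    probs = np.concatenate([np.atleast_1d(params.pi_t), [params.theta, params.theta_prime]])
    if np.any(probs < 0) or np.any(probs > 1):
        return -np.inf
    if params.sigma2_rw <= 0 or params.lam <= 0 or params.sigma2_obs <= 0:
        return -np.inf

    S = basis.penalty_matrix
    K = basis.K
    nd = basis.null_space_dim
    rank = K - nd
    nu1 = params.nu[:, 0]
    # penalised MVN for nu_{.,1}: precision lam * S on the wiggly part,
    # proper wide Gaussian on the null-space coefficients
    lp = 0.5 * rank * np.log(params.lam) - 0.5 * params.lam * (nu1 @ S @ nu1)
    lp += np.sum(_norm_logpdf(nu1[K - nd:], 0.0, prior.null_space_sd**2))
    # random walk across periods
    if T > 1:
        diffs = params.nu[:, 1:] - params.nu[:, :-1]
        lp += np.sum(_norm_logpdf(diffs, 0.0, params.sigma2_rw))
    # GVS mixture for each climate coefficient
    slab = gvs.slab_variance
    for m in range(2 * N_CLIMATE):
        if om[m] == 1:
            lp += _norm_logpdf(params.beta[m], 0.0, slab)
        else:
            lp += _norm_logpdf(params.beta[m], gvs.mu_pseudo[m], gvs.sigma_pseudo[m] ** 2)
    # inclusion indicators: omega_m ~ Bern(0.5); omega_{m^2} ~ Bern(omega_m * 0.5)
    lp += N_CLIMATE * np.log(0.5)                       # linear terms
    lp += np.log(0.5) * np.sum(om[:N_CLIMATE] == 1)     # quadratic mass where allowed
    # hyperpriors
    lp += (prior.lambda_shape - 1.0) * np.log(params.lam) - prior.lambda_rate * params.lam
    sig = np.sqrt(params.sigma2_rw)
    lp += -0.5 * sig**2 / prior.sigma_rw_scale**2       # half-Normal kernel on sigma
    sig_o = np.sqrt(params.sigma2_obs)
    lp += -0.5 * sig_o**2 / prior.sigma_obs_scale**2
    lp += np.sum(_norm_logpdf(params.alpha, 0.0, prior.alpha_var))
    # pi_t, theta, theta' ~ Uniform(0,1): zero inside the support
    if params.eta.size:
        lp += np.sum(_norm_logpdf(params.eta, 0.0, params.sigma2_obs))
    return float(lp)


def log_likelihood(params: ModelParams, data: OccupancyData, basis: SplineBasis) -> float:
    """Sum of route-year marginal log-likelihoods over surveyed route-years."""
    ii, tt = np.nonzero(data.observed)
    if ii.size == 0:
        return 0.0
    psi = expit(occupancy_logits(params, basis, data))[ii, tt]
    p = expit(detection_logits(params, data))[ii, tt]
    h = data.h[ii, :, tt]  # (R, J)
    pi = np.atleast_1d(params.pi_t)[tt]
    probs = marginal_likelihood_vec(h, psi, pi, params.theta, params.theta_prime, p)
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(probs)))


def log_joint(params: ModelParams, data: OccupancyData, basis: SplineBasis,
              gvs: GVSConfig, prior: PriorConfig | None = None) -> float:
    """log prior + log marginal likelihood; unsurveyed route-years contribute zero."""
    if params.nu.shape != (basis.K, data.n_periods):
        raise ValueError("nu has inconsistent dimensions with basis/data")
    if np.atleast_1d(params.pi_t).shape[0] != data.n_periods:
        raise ValueError("pi_t must have one entry per period")
    lp = log_prior(params, basis, gvs, data.n_periods, prior)
    if not np.isfinite(lp):
        return lp
    return lp + log_likelihood(params, data, basis)
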