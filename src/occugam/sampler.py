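"""Block Gibbs sampler for the dynamic spatial-GAM occupancy model.

The posterior is sampled by data augmentation:

* the latent occupancy state z and the stop-level availability chain y are
  drawn exactly from their joint full conditional by forward filtering /
  backward sampling along the stops;
* given imputed (z, y), the first-stop availability pi_t and the Markov
  transition probabilities theta, theta' have conjugate Beta updates;
* the two logistic regressions (occupancy on the spline + climate terms,
  detection on survey covariates + observer effects) are made conditionally
  Gaussian by Polya-Gamma augmentation, giving exact multivariate normal
  updates for the spline coefficient blocks nu_t, the climate coefficients
  beta, the detection coefficients alpha and the observer effects eta;
* inclusion indicators omega are updated pairwise (linear, quadratic) from
  their exact 3-state conditional (the marginality constraint rules out the
  fourth state); the scan is repeated with idle coefficients refreshed from
  the GVS pseudo-prior between passes so indicators can flip within a sweep;
* the smoothing penalty lambda has a conjugate Gamma update; the random-walk
  and observer standard deviations are slice-sampled under half-normal
  hyperpriors;
* each sweep opens with collapsed slice-sampling moves on (alpha0, pi_t, theta,
  theta') against the latent-marginalised likelihood, which traverse the
  availability/detection ridge that the conditional blocks alone cannot
  cross (when p -> 1 the imputed availability equals the history and the
  conditional updates are nearly absorbing).

All randomness flows from a single seed; identical configuration gives
bit-identical draw sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, logit

from occugam._polyagamma import pg_draw_array, seed_pg
from occugam.basis import SplineBasis
from occugam.model import (
    N_CLIMATE,
    GVSConfig,
    ModelParams,
    OccupancyData,
    PriorConfig,
    marginal_likelihood_vec,
)

_TINY = 1e-300


@dataclass
class MCMCConfig:
    """Run configuration for :func:`fit`."""

    n_chains: int = 3
    n_warmup: int = 2000
    n_samples: int = 2000
    thin: int = 1
    seed: int = 0
    fix_omega: bool = False          # hold all inclusion indicators at 1
    n_monitor_nu: int = 10           # spline coefficients monitored for R-hat
    rhat_threshold: float = 1.1


@dataclass
class PosteriorSamples:
    """Posterior draws plus imputed latent states and convergence diagnostics.

    ``draws`` maps parameter names to arrays with leading (chain, draw)
    axes.  Latent states are stored per surveyed route-year: ``z`` has
    shape (chain, draw, R) and ``y`` (chain, draw, R, J), with the
    route-year order given by ``chain_meta['obs_site']`` /
    ``chain_meta['obs_period']``.
    """

    draws: dict
    chain_meta: dict
    diagnostics: pd.DataFrame
    converged: bool

    @property
    def n_chains(self) -> int:
        return self.draws["theta"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["theta"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains concatenated."""
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    def params_at(self, chain: int, draw: int) -> ModelParams:
        d = self.draws
        return ModelParams(
            nu=d["nu"][chain, draw], beta=d["beta"][chain, draw],
            omega=d["omega"][chain, draw], sigma2_rw=float(d["sigma2_rw"][chain, draw]),
            lam=float(d["lam"][chain, draw]), pi_t=d["pi_t"][chain, draw],
            theta=float(d["theta"][chain, draw]),
            theta_prime=float(d["theta_prime"][chain, draw]),
            alpha=d["alpha"][chain, draw], eta=d["eta"][chain, draw],
            sigma2_obs=float(d["sigma2_obs"][chain, draw]),
        )

    def iter_params(self, thin: int = 1):
        """Yield (chain, draw, ModelParams) over kept draws."""
        for c in range(self.n_chains):
            for d in range(0, self.n_draws, thin):
                yield c, d, self.params_at(c, d)

    def save(self, path: str) -> None:
        """Serialise draws and metadata to a .npz container."""
        payload = {f"draw_{k}": v for k, v in self.draws.items()}
        payload["meta_obs_site"] = self.chain_meta["obs_site"]
        payload["meta_obs_period"] = self.chain_meta["obs_period"]
        payload["meta_config"] = np.array(
            [self.chain_meta[k] for k in ("n_chains", "n_warmup", "n_samples", "thin", "seed")]
        )
        payload["meta_converged"] = np.array([self.converged])
        payload["diag_names"] = self.diagnostics["param"].to_numpy().astype(str)
        payload["diag_rhat"] = self.diagnostics["rhat"].to_numpy()
        payload["diag_ess"] = self.diagnostics["ess"].to_numpy()
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path: str) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as f:
            draws = {k[5:]: f[k] for k in f.files if k.startswith("draw_")}
            nc, nw, ns, thin, seed = (int(v) for v in f["meta_config"])
            meta = {
                "obs_site": f["meta_obs_site"], "obs_period": f["meta_obs_period"],
                "n_chains": nc, "n_warmup": nw, "n_samples": ns, "thin": thin, "seed": seed,
            }
            diag = pd.DataFrame(
                {"param": f["diag_names"], "rhat": f["diag_rhat"], "ess": f["diag_ess"]}
            )
            converged = bool(f["meta_converged"][0])
        return cls(draws=draws, chain_meta=meta, diagnostics=diag, converged=converged)


def _slice_sample(logf, x0: float, rng, w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping out (exact for log-concave and
    general unimodal targets; used for the half-normal sd updates)."""
    f0 = logf(x0)
    logy = f0 + np.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logf(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < logy:
            break
        hi += w
    while True:
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _draw_mvn(A: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(A^-1 b, A^-1) given precision A and linear term b."""
    c, low = cho_factor(A, lower=True)
    mu = cho_solve((c, low), b)
    z = rng.standard_normal(b.shape[0])
    return mu + solve_triangular(c, z, lower=low, trans="T" if low else "N")


class GibbsSampler:
    """One-sweep Gibbs kernel for a fixed dataset/basis/pseudo-prior.

    Exposed separately from :func:`fit` so each update block can be tested
    against enumeration oracles and a Geweke-style joint-distribution test.
    """

    def __init__(self, data: OccupancyData, basis: SplineBasis, gvs: GVSConfig,
                 prior: PriorConfig | None = None, fix_omega: bool = False):
        if basis.n_sites != data.n_sites:
            raise ValueError("basis was built for a different number of sites")
        self.data = data
        self.basis = basis
        self.gvs = gvs
        self.prior = prior or PriorConfig()
        self.fix_omega = fix_omega

        self.K = basis.K
        self.T = data.n_periods
        self.J = data.J
        ii, tt = np.nonzero(data.observed)
        self.ii, self.tt = ii, tt
        self.R = ii.size
        self.h = data.h[ii, :, tt].astype(float) if self.R else np.zeros((0, data.J))
        self.G_obs = basis.basis_matrix[ii]
        self.Xf = data.X_full()[ii, tt] if self.R else np.zeros((0, 2 * N_CLIMATE))
        self.W = np.column_stack([
            np.ones(self.R), data.wind[ii, tt], data.first_year[ii, tt],
            data.protocol[ii, tt],
        ]) if self.R else np.zeros((0, 4))
        self.oid = data.observer_id[ii, tt].astype(int) if self.R else np.zeros(0, int)
        self.n_obs = data.n_observers
        self.rows_by_t = [np.flatnonzero(tt == t) for t in range(self.T)]
        S = basis.penalty_matrix
        self.S = S
        self.rank = self.K - basis.null_space_dim
        null_prec = np.zeros(self.K)
        null_prec[self.K - basis.null_space_dim:] = 1.0 / self.prior.null_space_sd**2
        self.null_prec = null_prec

    # -- state ------------------------------------------------------------

    def init_state(self, rng) -> dict:
        K, T, R, J = self.K, self.T, self.R, self.J
        anyh = self.h.sum(axis=1) > 0 if R else np.zeros(0, bool)
        z = np.where(anyh, 1, (rng.random(R) < 0.5).astype(int)).astype(np.int8)
        y = np.maximum(self.h, (rng.random((R, J)) < 0.3)).astype(np.int8) * z[:, None]
        occ_rate = float(np.clip(anyh.mean() if R else 0.5, 0.05, 0.95))
        nu = 0.01 * rng.standard_normal((K, T))
        nu[K - self.basis.null_space_dim, :] = logit(occ_rate)  # constant column
        det_rate = float(np.clip(self.h[anyh].mean() if anyh.any() else 0.5, 0.05, 0.95))
        omega = np.zeros(2 * N_CLIMATE, dtype=np.int8)
        if self.fix_omega:
            omega[:] = 1
        else:
            omega[:N_CLIMATE] = rng.random(N_CLIMATE) < 0.5
            omega[N_CLIMATE:] = (rng.random(N_CLIMATE) < 0.5) & (omega[:N_CLIMATE] == 1)
        return {
            "nu": nu,
            "beta": self.gvs.mu_pseudo.copy(),
            "omega": omega,
            "sigma2_rw": 0.1,
            "lam": 1.0,
            "pi_t": np.full(T, 0.5),
            "theta": 0.5,
            "theta_prime": 0.5,
            "alpha": np.array([logit(det_rate), 0.0, 0.0, 0.0]),
            "eta": np.zeros(self.n_obs),
            "sigma2_obs": 0.1,
            "z": z,
            "y": y,
        }

    def state_from_params(self, params: ModelParams, rng) -> dict:
        st = self.init_state(rng)
        for name in ("nu", "beta", "omega", "pi_t", "alpha", "eta"):
            st[name] = np.array(getattr(params, name), copy=True)
        st["omega"] = st["omega"].astype(np.int8)
        for name in ("sigma2_rw", "lam", "theta", "theta_prime", "sigma2_obs"):
            st[name] = float(getattr(params, name))
        return st

    def params_from_state(self, st: dict) -> ModelParams:
        return ModelParams(
            nu=st["nu"].copy(), beta=st["beta"].copy(), omega=st["omega"].copy(),
            sigma2_rw=st["sigma2_rw"], lam=st["lam"], pi_t=st["pi_t"].copy(),
            theta=st["theta"], theta_prime=st["theta_prime"], alpha=st["alpha"].copy(),
            eta=st["eta"].copy(), sigma2_obs=st["sigma2_obs"],
        )

    # -- linear predictors -------------------------------------------------

    def _occ_lin(self, st) -> np.ndarray:
        if self.R == 0:
            return np.zeros(0)
        smooth = np.einsum("rk,kr->r", self.G_obs, st["nu"][:, self.tt])
        return smooth + self.Xf @ (st["omega"] * st["beta"])

    def _det_lin(self, st) -> np.ndarray:
        lin = self.W @ st["alpha"]
        if self.n_obs and self.R:
            lin = lin + st["eta"][self.oid]
        return lin

    # -- update blocks -----------------------------------------------------

    def update_latents(self, st, rng) -> None:
        """Joint draw of (z, y) from the exact full conditional (FFBS)."""
        R, J = self.R, self.J
        if R == 0:
            return
        psi = expit(self._occ_lin(st))
        p = expit(self._det_lin(st))
        h = self.h
        e1 = np.where(h == 1, p[:, None], 1.0 - p[:, None])
        e0 = 1.0 - h
        th, tp = st["theta"], st["theta_prime"]
        F0 = np.empty((R, J))
        F1 = np.empty((R, J))
        pi_r = st["pi_t"][self.tt]
        F0[:, 0] = (1.0 - pi_r) * e0[:, 0]
        F1[:, 0] = pi_r * e1[:, 0]
        for j in range(1, J):
            F1[:, j] = (F0[:, j - 1] * th + F1[:, j - 1] * tp) * e1[:, j]
            F0[:, j] = (F0[:, j - 1] * (1.0 - th) + F1[:, j - 1] * (1.0 - tp)) * e0[:, j]
        m1 = F0[:, -1] + F1[:, -1]
        anyh = h.sum(axis=1) > 0
        num = psi * m1
        den = num + (1.0 - psi) * (~anyh)
        pz = np.where(den > 0, num / np.maximum(den, _TINY), 1.0)
        z = (rng.random(R) < pz).astype(np.int8)
        u = rng.random((R, J))
        y = np.zeros((R, J), dtype=np.int8)
        y[:, -1] = u[:, -1] < F1[:, -1] / np.maximum(m1, _TINY)
        for j in range(J - 2, -1, -1):
            nxt = y[:, j + 1]
            w1 = F1[:, j] * np.where(nxt == 1, tp, 1.0 - tp)
            w0 = F0[:, j] * np.where(nxt == 1, th, 1.0 - th)
            y[:, j] = u[:, j] < w1 / np.maximum(w0 + w1, _TINY)
        y *= z[:, None]
        st["z"], st["y"] = z, y

    def update_availability_detection_marginal(self, st, rng) -> None:
        """Collapsed slice-sampling moves for the detection intercept and the
        availability parameters against the latent-marginalised likelihood.

        Given the latents, p -> 1 forces y = h, which is nearly absorbing
        for the conditional blocks: the sampler cannot traverse the ridge
        along which per-stop detection trades off against availability.
        These moves target p(alpha0, pi_t, theta, theta' | h, rest) with
        (z, y) summed out.  They run before the FFBS draw and never read
        (z, y); the FFBS then refreshes the latents from their exact
        conditional, so the joint posterior stays invariant.
        """
        if self.R == 0:
            return
        pc = self.prior
        T = self.T
        # recentering move: the likelihood only sees alpha0 + eta_o, so the
        # shift (alpha0 + s, eta - s) leaves it invariant and the priors give
        # an exact Gaussian conditional for s; without it, inflated observer
        # effects pin the detection level in place
        if self.n_obs:
            prec = 1.0 / pc.alpha_var + self.n_obs / st["sigma2_obs"]
            mean = (-st["alpha"][0] / pc.alpha_var
                    + st["eta"].sum() / st["sigma2_obs"]) / prec
            shift = mean + rng.standard_normal() / np.sqrt(prec)
            st["alpha"][0] += shift
            st["eta"] -= shift
        psi = expit(self._occ_lin(st))
        # detection predictor split so alpha0 and the eta scale can move:
        # p = expit(a0 + covariate part + e^{s_e} * eta_o)
        cov_lin = self.W[:, 1:] @ st["alpha"][1:]
        eta_r = st["eta"][self.oid] if self.n_obs else np.zeros(self.R)
        v_obs = float(st["sigma2_obs"])
        c_h2 = pc.sigma_obs_scale**2
        h = self.h

        def _ljac(l):
            # log density of a flat Beta(1,1) prior on the logit scale
            return -np.logaddexp(0.0, l) - np.logaddexp(0.0, -l)

        def logpost(u):
            a0, lpi, lth, ltp, s_e = u[0], u[1:1 + T], u[T + 1], u[T + 2], u[T + 3]
            p = expit(a0 + cov_lin + np.exp(s_e) * eta_r)
            probs = marginal_likelihood_vec(
                h, psi, expit(lpi)[self.tt], expit(lth), expit(ltp), p)
            ll = float(np.log(np.maximum(probs, _TINY)).sum())
            # the s_e terms are the orbit density of the joint rescaling
            # (eta, sigma2_obs) -> (e^s eta, e^{2s} sigma2_obs), under which
            # the eta prior is invariant and only the half-normal hyperprior
            # and the group Jacobian remain
            return (ll - 0.5 * a0**2 / pc.alpha_var
                    + float(np.sum(_ljac(lpi))) + _ljac(lth) + _ljac(ltp)
                    - 0.5 * np.exp(2.0 * s_e) * v_obs / c_h2 + s_e)

        clip = lambda x: np.clip(x, 1e-12, 1 - 1e-12)
        u = np.concatenate([
            [float(st["alpha"][0])], logit(clip(st["pi_t"])),
            [logit(clip(st["theta"])), logit(clip(st["theta_prime"])), 0.0],
        ])
        # slice-sample along lines: the scalar coordinates, then ridge
        # directions (detection up, availability logits down, eta scale
        # with detection) whose relative slopes are drawn fresh each sweep --
        # the flat ridge's true slope varies by dataset, so random
        # directions cover it stochastically
        # theta, theta' and pi_t keep their conjugate updates, so only
        # alpha0 and the eta scale need their own coordinate slices here
        n_u = T + 4
        dirs = [np.zeros(n_u) for _ in range(2)]
        dirs[0][0] = dirs[1][T + 3] = 1.0
        for _ in range(3):
            c_pi, c_th, c_tp, c_e = rng.random(4)
            dirs.append(np.concatenate(
                [[1.0], np.full(T, -c_pi), [-c_th, -c_tp, c_e]]))
        # isotropic signed directions: the trade between a persistent chain
        # thinned by mid detection and a weakly persistent chain seen with
        # high detection moves theta and theta' in opposite directions, so
        # fixed-sign ridge slopes alone cannot cross between those modes
        for _ in range(3):
            g = rng.standard_normal(5)
            dirs.append(np.concatenate(
                [[g[0]], np.full(T, g[1]), g[2:]]))
        for d in dirs:
            delta = _slice_sample(lambda s: logpost(u + s * d), 0.0, rng, w=1.0)
            u = u + delta * d
        st["alpha"][0] = u[0]
        st["pi_t"][:] = expit(u[1:1 + T])
        st["theta"] = float(expit(u[T + 1]))
        st["theta_prime"] = float(expit(u[T + 2]))
        if self.n_obs:
            scale = float(np.exp(u[T + 3]))
            st["eta"] *= scale
            st["sigma2_obs"] = v_obs * scale**2

    def update_availability(self, st, rng) -> None:
        """Conjugate Beta updates for pi_t, theta, theta' given imputed (z, y)."""
        occ = st["z"] == 1
        y = st["y"]
        for t in range(self.T):
            rows = self.rows_by_t[t]
            rows = rows[occ[rows]] if rows.size else rows
            s1 = int(y[rows, 0].sum()) if rows.size else 0
            n = rows.size
            st["pi_t"][t] = rng.beta(1 + s1, 1 + n - s1)
        if occ.any() and self.J > 1:
            prev = y[occ, :-1]
            nxt = y[occ, 1:]
            n01 = int(((prev == 0) & (nxt == 1)).sum())
            n00 = int(((prev == 0) & (nxt == 0)).sum())
            n11 = int(((prev == 1) & (nxt == 1)).sum())
            n10 = int(((prev == 1) & (nxt == 0)).sum())
        else:
            n01 = n00 = n11 = n10 = 0
        st["theta"] = rng.beta(1 + n01, 1 + n00)
        st["theta_prime"] = rng.beta(1 + n11, 1 + n10)

    def update_detection(self, st, rng) -> None:
        """PG-augmented Gaussian updates for alpha and eta; slice for sigma_obs."""
        pc = self.prior
        mask = (st["z"][:, None] == 1) & (st["y"] == 1)
        ridx, jidx = np.nonzero(mask)
        if ridx.size:
            Wd = self.W[ridx]
            od = self.oid[ridx]
            resp = self.h[ridx, jidx]
            kappa = resp - 0.5
            lin = Wd @ st["alpha"]
            if self.n_obs:
                lin = lin + st["eta"][od]
            om = pg_draw_array(lin)
            eta_part = st["eta"][od] if self.n_obs else 0.0
            A = Wd.T @ (Wd * om[:, None]) + np.eye(4) / pc.alpha_var
            b = Wd.T @ (kappa - om * eta_part)
            st["alpha"] = _draw_mvn(A, b, rng)
            if self.n_obs:
                resid = kappa - om * (Wd @ st["alpha"])
                prec = np.bincount(od, weights=om, minlength=self.n_obs) + 1.0 / st["sigma2_obs"]
                mean = np.bincount(od, weights=resid, minlength=self.n_obs) / prec
                st["eta"] = mean + rng.standard_normal(self.n_obs) / np.sqrt(prec)
        else:
            st["alpha"] = rng.standard_normal(4) * np.sqrt(pc.alpha_var)
            if self.n_obs:
                st["eta"] = rng.standard_normal(self.n_obs) * np.sqrt(st["sigma2_obs"])
        # observer sd under its half-normal hyperprior
        if self.n_obs:
            ssq = float(st["eta"] @ st["eta"])
            n = self.n_obs
            c2 = pc.sigma_obs_scale**2

            def logf(s):
                v = np.exp(2.0 * s)
                return -n * s - 0.5 * ssq / v - 0.5 * v / c2 + s

            s_new = _slice_sample(logf, 0.5 * np.log(st["sigma2_obs"]), rng)
            st["sigma2_obs"] = float(np.exp(2.0 * s_new))
        else:
            st["sigma2_obs"] = float(rng.normal(0.0, pc.sigma_obs_scale) ** 2)

    def update_gvs_indicators(self, st, rng) -> None:
        """Exact 3-state Gibbs update of each (linear, quadratic) indicator pair.

        States (0,0), (1,0), (1,1) are weighted by the Bernoulli occupancy
        likelihood of the imputed z, the indicator prior masses and the
        slab/pseudo-prior density of the current beta values; (0,1) is
        excluded by marginality.

        The scan is repeated several times per sweep, refreshing the idle
        coefficients from their pseudo-priors between scans (the exact
        conditional of an excluded coefficient).  A switch only happens
        when the current idle draw lands in a high-likelihood region, so
        repeated refresh-and-scan passes are what lets indicators flip
        within a sweep instead of waiting many sweeps for a lucky draw.
        """
        if self.fix_omega:
            return
        z = st["z"].astype(float) if self.R else np.zeros(0)
        gvs, beta, omega = self.gvs, st["beta"], st["omega"]
        lin = self._occ_lin(st)
        slab_v = gvs.slab_variance
        log_mass = np.log(np.array([0.5, 0.25, 0.25]))

        def beta_logprior(m, included):
            if included:
                return -0.5 * (np.log(2 * np.pi * slab_v) + beta[m] ** 2 / slab_v)
            sd = gvs.sigma_pseudo[m]
            return -0.5 * (np.log(2 * np.pi * sd**2) + (beta[m] - gvs.mu_pseudo[m]) ** 2 / sd**2)

        for scan in range(10):
            if scan:
                idle = omega == 0
                beta[idle] = (gvs.mu_pseudo[idle]
                              + gvs.sigma_pseudo[idle]
                              * rng.standard_normal(int(idle.sum())))
            for m in range(N_CLIMATE):
                q = m + N_CLIMATE
                xm, xq = self.Xf[:, m], self.Xf[:, q]
                base = lin - omega[m] * beta[m] * xm - omega[q] * beta[q] * xq
                logw = np.empty(3)
                for s, (a, bq) in enumerate(((0, 0), (1, 0), (1, 1))):
                    lin_s = base + a * beta[m] * xm + bq * beta[q] * xq
                    ll = float(z @ lin_s - np.logaddexp(0.0, lin_s).sum()) if self.R else 0.0
                    logw[s] = (ll + log_mass[s]
                               + beta_logprior(m, a == 1) + beta_logprior(q, bq == 1))
                w = np.exp(logw - logw.max())
                s = int(rng.choice(3, p=w / w.sum()))
                omega[m], omega[q] = ((0, 0), (1, 0), (1, 1))[s]
                lin = base + omega[m] * beta[m] * xm + omega[q] * beta[q] * xq

    def update_occupancy_coefficients(self, st, rng) -> None:
        """PG-augmented Gaussian updates for the spline blocks nu_t and the
        active climate coefficients; idle coefficients from the pseudo-prior."""
        K, T = self.K, self.T
        pc, gvs = self.prior, self.gvs
        kappa_z = st["z"].astype(float) - 0.5 if self.R else np.zeros(0)
        om_z = pg_draw_array(self._occ_lin(st)) if self.R else np.zeros(0)
        clim = self.Xf @ (st["omega"] * st["beta"]) if self.R else np.zeros(0)
        nu, s2 = st["nu"], st["sigma2_rw"]
        for t in range(T):
            rows = self.rows_by_t[t]
            if rows.size:
                Gt = self.G_obs[rows]
                omt = om_z[rows]
                A = Gt.T @ (Gt * omt[:, None])
                b = Gt.T @ (kappa_z[rows] - omt * clim[rows])
            else:
                A = np.zeros((K, K))
                b = np.zeros(K)
            if t == 0:
                A = A + st["lam"] * self.S + np.diag(self.null_prec)
                if T > 1:
                    A = A + np.eye(K) / s2
                    b = b + nu[:, 1] / s2
            elif t < T - 1:
                A = A + 2.0 * np.eye(K) / s2
                b = b + (nu[:, t - 1] + nu[:, t + 1]) / s2
            else:
                A = A + np.eye(K) / s2
                b = b + nu[:, t - 1] / s2
            nu[:, t] = _draw_mvn(A, b, rng)
        act = st["omega"] == 1
        if act.any():
            if self.R:
                smooth = np.einsum("rk,kr->r", self.G_obs, nu[:, self.tt])
                Xa = self.Xf[:, act]
                A = Xa.T @ (Xa * om_z[:, None]) + np.eye(int(act.sum())) / gvs.slab_variance
                b = Xa.T @ (kappa_z - om_z * smooth)
            else:
                A = np.eye(int(act.sum())) / gvs.slab_variance
                b = np.zeros(int(act.sum()))
            st["beta"][act] = _draw_mvn(A, b, rng)
        idle = ~act
        st["beta"][idle] = (gvs.mu_pseudo[idle]
                            + gvs.sigma_pseudo[idle] * rng.standard_normal(int(idle.sum())))

    def update_smoothing(self, st, rng) -> None:
        """Conjugate Gamma update for lambda; slice update for the RW sd."""
        pc = self.prior
        nu1 = st["nu"][:, 0]
        shape = pc.lambda_shape + 0.5 * self.rank
        rate = pc.lambda_rate + 0.5 * float(nu1 @ self.S @ nu1)
        st["lam"] = float(rng.gamma(shape, 1.0 / rate))
        if self.T > 1:
            diffs = st["nu"][:, 1:] - st["nu"][:, :-1]
            ssq = float(np.sum(diffs**2))
            n = diffs.size
            c2 = pc.sigma_rw_scale**2

            def logf(s):
                v = np.exp(2.0 * s)
                return -n * s - 0.5 * ssq / v - 0.5 * v / c2 + s

            s_new = _slice_sample(logf, 0.5 * np.log(st["sigma2_rw"]), rng)
            st["sigma2_rw"] = float(np.exp(2.0 * s_new))
        else:
            st["sigma2_rw"] = float(rng.normal(0.0, pc.sigma_rw_scale) ** 2)

    def sweep(self, st, rng) -> None:
        """One full Gibbs scan over every block."""
        self.update_availability_detection_marginal(st, rng)
        self.update_latents(st, rng)
        self.update_availability(st, rng)
        self.update_detection(st, rng)
        self.update_gvs_indicators(st, rng)
        self.update_occupancy_coefficients(st, rng)
        self.update_smoothing(st, rng)


# ---------------------------------------------------------------------------
# public API


def fit(data: OccupancyData, basis: SplineBasis, gvs: GVSConfig,
        config: MCMCConfig | None = None, prior: PriorConfig | None = None) -> PosteriorSamples:
    """Sample the posterior of the full model.

    Runs ``config.n_chains`` independent chains (sequentially), discards
    ``n_warmup`` sweeps, keeps ``n_samples`` draws per chain (after
    thinning), and attaches split-R-hat / effective-sample-size
    diagnostics for the monitored scalars.  Non-converged runs are
    returned with ``converged=False``, never silently accepted.
    """
    config = config or MCMCConfig()
    kernel = GibbsSampler(data, basis, gvs, prior=prior, fix_omega=config.fix_omega)
    K, T, R, J = kernel.K, kernel.T, kernel.R, kernel.J
    C, D = config.n_chains, config.n_samples
    draws = {
        "nu": np.empty((C, D, K, T)), "beta": np.empty((C, D, 2 * N_CLIMATE)),
        "omega": np.empty((C, D, 2 * N_CLIMATE), dtype=np.int8),
        "sigma2_rw": np.empty((C, D)), "lam": np.empty((C, D)),
        "pi_t": np.empty((C, D, T)), "theta": np.empty((C, D)),
        "theta_prime": np.empty((C, D)), "alpha": np.empty((C, D, 4)),
        "eta": np.empty((C, D, kernel.n_obs)), "sigma2_obs": np.empty((C, D)),
        "z": np.empty((C, D, R), dtype=np.int8), "y": np.empty((C, D, R, J), dtype=np.int8),
    }
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)
    for c in range(C):
        rng = np.random.default_rng(children[c])
        seed_pg(int(children[c].generate_state(1)[0] % (2**31 - 1)) + 1)
        st = kernel.init_state(rng)
        for _ in range(config.n_warmup):
            kernel.sweep(st, rng)
        for d in range(D):
            for _ in range(config.thin):
                kernel.sweep(st, rng)
            draws["nu"][c, d] = st["nu"]
            draws["beta"][c, d] = st["beta"]
            draws["omega"][c, d] = st["omega"]
            draws["sigma2_rw"][c, d] = st["sigma2_rw"]
            draws["lam"][c, d] = st["lam"]
            draws["pi_t"][c, d] = st["pi_t"]
            draws["theta"][c, d] = st["theta"]
            draws["theta_prime"][c, d] = st["theta_prime"]
            draws["alpha"][c, d] = st["alpha"]
            draws["eta"][c, d] = st["eta"]
            draws["sigma2_obs"][c, d] = st["sigma2_obs"]
            draws["z"][c, d] = st["z"]
            draws["y"][c, d] = st["y"]
    diagnostics = _diagnostics(draws, kernel, config)
    finite_rhat = diagnostics["rhat"].dropna()
    converged = bool((finite_rhat < config.rhat_threshold).all()) if len(finite_rhat) else True
    meta = {
        "obs_site": kernel.ii, "obs_period": kernel.tt,
        "n_chains": C, "n_warmup": config.n_warmup, "n_samples": D,
        "thin": config.thin, "seed": config.seed,
    }
    return PosteriorSamples(draws=draws, chain_meta=meta,
                            diagnostics=diagnostics, converged=converged)


def _diagnostics(draws: dict, kernel: GibbsSampler, config: MCMCConfig) -> pd.DataFrame:
    """Split-R-hat and bulk ESS for the monitored scalar parameters."""
    import arviz as az

    monitored: dict[str, np.ndarray] = {}
    for l in range(4):
        monitored[f"alpha[{l}]"] = draws["alpha"][:, :, l]
    monitored["theta"] = draws["theta"]
    monitored["theta_prime"] = draws["theta_prime"]
    monitored["sigma2_rw"] = draws["sigma2_rw"]
    monitored["lam"] = draws["lam"]
    for m in range(2 * N_CLIMATE):
        monitored[f"omega[{m}]"] = draws["omega"][:, :, m].astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 977]))
    K, T = kernel.K, kernel.T
    n_pick = min(config.n_monitor_nu, K * T)
    flat = rng.choice(K * T, size=n_pick, replace=False)
    for idx in flat:
        k, t = divmod(int(idx), T)
        monitored[f"nu[{k},{t}]"] = draws["nu"][:, :, k, t]
    rows = []
    for name, arr in monitored.items():
        if arr.shape[0] < 2 or np.allclose(arr.std(), 0.0):
            rh, ess = np.nan, np.nan
        else:
            rh = float(az.rhat(arr))
            ess = float(az.ess(arr))
        rows.append({"param": name, "rhat": rh, "ess": ess})
    return pd.DataFrame(rows)


def update_latent_states(params: ModelParams, data: OccupancyData, basis: SplineBasis,
                         rng) -> tuple[np.ndarray, np.ndarray]:
    """Exact draw of (z, y) from their joint full conditional given h and params.

    Returns (N, T) occupancy and (N, J, T) availability arrays; unsurveyed
    route-years are zero.
    """
    kernel = GibbsSampler(data, basis, GVSConfig.default())
    st = kernel.state_from_params(params, rng)
    kernel.update_latents(st, rng)
    z = np.zeros((data.n_sites, data.n_periods), dtype=np.int8)
    y = np.zeros((data.n_sites, data.J, data.n_periods), dtype=np.int8)
    z[kernel.ii, kernel.tt] = st["z"]
    y[kernel.ii, :, kernel.tt] = st["y"]
    return z, y


def update_gvs(params: ModelParams, data: OccupancyData, basis: SplineBasis,
               gvs: GVSConfig, z: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """One Gibbs update of (omega, beta) given the imputed occupancy states z.

    ``z`` is the (N, T) imputed occupancy array.  Returns the new
    (omega, beta); marginality (omega_q <= omega_m) always holds on output.
    """
    kernel = GibbsSampler(data, basis, gvs)
    st = kernel.state_from_params(params, rng)
    st["z"] = np.asarray(z)[kernel.ii, kernel.tt].astype(np.int8)
    kernel.update_gvs_indicators(st, rng)
    kernel.update_occupancy_coefficients(st, rng)
    return st["omega"].copy(), st["beta"].copy()


# ---------------------------------------------------------------------------
# pilot maximum-likelihood fit for the GVS pseudo-priors


def estimate_pseudopriors(data: OccupancyData, basis: SplineBasis,
                          n_pilot_periods: int = 10, smooth_ridge: float = 1.0,
                          maxiter: int = 600) -> GVSConfig:
    """Pseudo-priors (mu_m, sigma_m) from a pilot maximum-likelihood fit.

    Maximises the marginal likelihood (z and y summed out) over the first
    ``n_pilot_periods`` periods with every climate term included, a static
    smooth (one nu vector shared across the pilot years, lightly ridge-
    penalised for identifiability), a single shared first-stop availability
    and no observer effects.  Returns the MLEs of the ten climate
    coefficients as pseudo-prior means and their asymptotic standard
    errors (inverse observed information) as pseudo-prior sds.
    """
    T0 = min(n_pilot_periods, data.n_periods)
    ii, tt = np.nonzero(data.observed[:, :T0])
    if ii.size == 0:
        raise ValueError("no surveyed route-years in the pilot window")
    h = data.h[ii, :, tt].astype(float)
    G = basis.basis_matrix[ii]
    Xf = data.X_full()[ii, tt]
    W = np.column_stack([np.ones(ii.size), data.wind[ii, tt],
                         data.first_year[ii, tt], data.protocol[ii, tt]])
    K = basis.K
    S = basis.penalty_matrix
    nb = 2 * N_CLIMATE
    # parameter vector: nu (K), beta (10), alpha (4), logit(pi, theta, theta')
    n_par = K + nb + 4 + 3
    sl_nu = slice(0, K)
    sl_b = slice(K, K + nb)
    sl_a = slice(K + nb, K + nb + 4)
    sl_q = slice(K + nb + 4, n_par)

    def negll(v):
        psi = expit(G @ v[sl_nu] + Xf @ v[sl_b])
        p = expit(W @ v[sl_a])
        pi, th, tp = expit(v[sl_q])
        prob = marginal_likelihood_vec(h, psi, pi, th, tp, p)
        pen = 0.5 * smooth_ridge * float(v[sl_nu] @ S @ v[sl_nu])
        pen += 0.5 * 1e-4 * float(v[sl_nu] @ v[sl_nu])
        # working normal priors keep the pilot finite under quasi-separation
        # (sparse standardized covariates can otherwise drive coefficients
        # to +-infinity): N(0, 2^2) on climate terms, N(0, 10) on detection
        pen += 0.5 * float(v[sl_b] @ v[sl_b]) / 4.0
        pen += 0.5 * float(v[sl_a] @ v[sl_a]) / 10.0
        with np.errstate(divide="ignore"):
            return -float(np.sum(np.log(np.maximum(prob, _TINY)))) + pen

    v0 = np.zeros(n_par)
    anyh = h.sum(axis=1) > 0
    v0[K - basis.null_space_dim] = logit(float(np.clip(anyh.mean(), 0.05, 0.95)))
    v0[sl_a][0] = logit(float(np.clip(h[anyh].mean() if anyh.any() else 0.5, 0.05, 0.95)))
    res = minimize(negll, v0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 10 * maxiter * n_par})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"pilot optimisation failed: {res.message}")
    vhat = res.x
    H = _numeric_hessian(negll, vhat)
    # observed information -> asymptotic covariance of the full vector
    jitter = 1e-8 * np.eye(n_par)
    try:
        cov = np.linalg.inv(H + jitter)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("pilot information matrix is singular") from exc
    var_b = np.diag(cov)[sl_b]
    if np.any(var_b <= 0) or not np.all(np.isfinite(var_b)):
        raise RuntimeError("pilot standard errors are not positive/finite; "
                           "the optimisation likely did not converge")
    return GVSConfig(mu_pseudo=vhat[sl_b].copy(), sigma_pseudo=np.sqrt(var_b))


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian."""
    n = x.size
    H = np.empty((n, n))
    fx = f(x)
    ei = np.eye(n) * eps
    fp = np.array([f(x + ei[i]) for i in range(n)])
    fm = np.array([f(x - ei[i]) for i in range(n)])
    for i in range(n):
        H[i, i] = (fp[i] - 2.0 * fx + fm[i]) / eps**2
        for j in range(i + 1, n):
            fpp = f(x + ei[i] + ei[j])
            fmm = f(x - ei[i] - ei[j])
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * fx - fm[i] - fm[j] + fmm) / (2.0 * eps**2)
    return H
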