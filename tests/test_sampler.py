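"""Gibbs sampler: exact conditionals, joint-distribution validity,
determinism, and the pilot pseudo-prior fit."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from occugam.basis import SiteCoordinates, affine_basis, build_tprs_basis
from occugam.model import (
    GVSConfig,
    ModelParams,
    N_CLIMATE,
    OccupancyData,
    PriorConfig,
)
from occugam.sampler import (
    GibbsSampler,
    MCMCConfig,
    PosteriorSamples,
    _draw_mvn,
    _slice_sample,
    estimate_pseudopriors,
    fit,
    update_gvs,
    update_latent_states,
)
from occugam.simulate import SimDesign, simulate_dataset

from conftest import BASE_SEED, derived_seed


def three_site_coords():
    return SiteCoordinates(np.array([0, 1, 2]), np.array([30.0, 35.0, 40.0]),
                           np.array([-80.0, -85.0, -82.0]))


def one_route_data(h_obs, J=2):
    """Three sites (for a valid affine basis) with only site 0 surveyed."""
    coords = three_site_coords()
    h = np.zeros((3, J, 1), dtype=np.int8)
    h[0, :, 0] = h_obs
    observed = np.zeros((3, 1), dtype=bool)
    observed[0, 0] = True
    return OccupancyData(
        h=h, observed=observed, wind=np.zeros((3, 1), int),
        first_year=np.zeros((3, 1), np.int8), protocol=np.zeros((3, 1), np.int8),
        observer_id=np.zeros((3, 1), int), X=np.zeros((3, 1, N_CLIMATE)),
        coords=coords,
    )


def exact_latent_conditional(h, psi, pi, th, tp, p):
    """Enumerate Pr(z, y | h) for one route-year with J = 2."""
    probs = {}
    for z, y1, y2 in itertools.product((0, 1), repeat=3):
        pr = psi if z else 1.0 - psi
        if z:
            pr *= pi if y1 else 1.0 - pi
            tr = tp if y1 else th
            pr *= tr if y2 else 1.0 - tr
        elif y1 or y2:
            continue
        for hj, yj in zip(h, (y1, y2)):
            pd = p if yj else 0.0
            pr *= pd if hj else 1.0 - pd
        if pr > 0:
            probs[(z, y1, y2)] = probs.get((z, y1, y2), 0.0) + pr
    tot = sum(probs.values())
    return {k: v / tot for k, v in probs.items()}


@pytest.mark.parametrize("h_obs", [(0, 0), (1, 0), (0, 1), (1, 1)])
def test_latent_draw_matches_enumeration(h_obs):
    data = one_route_data(h_obs)
    basis = affine_basis(data.coords)
    psi_t, p_t, pi, th, tp = 0.6, 0.7, 0.55, 0.3, 0.85
    nu = np.zeros((3, 1))
    nu[0, 0] = logit(psi_t)
    params = ModelParams(nu=nu, beta=np.zeros(10), omega=np.zeros(10, int),
                         sigma2_rw=0.1, lam=1.0, pi_t=np.array([pi]), theta=th,
                         theta_prime=tp, alpha=np.array([logit(p_t), 0, 0, 0.0]),
                         eta=np.zeros(1), sigma2_obs=0.1)
    exact = exact_latent_conditional(h_obs, psi_t, pi, th, tp, p_t)
    rng = np.random.default_rng(derived_seed(BASE_SEED, "ffbs", *h_obs))
    kernel = GibbsSampler(data, basis, GVSConfig.default())
    st = kernel.state_from_params(params, rng)
    M = 60_000
    counts: dict = {}
    for _ in range(M):
        kernel.update_latents(st, rng)
        key = (int(st["z"][0]), int(st["y"][0, 0]), int(st["y"][0, 1]))
        counts[key] = counts.get(key, 0) + 1
    tv = 0.5 * sum(abs(counts.get(k, 0) / M - exact.get(k, 0.0))
                   for k in set(counts) | set(exact))
    assert tv < 0.015, (tv, exact)


def test_latent_draw_forces_occupancy_when_detected():
    data = one_route_data((1, 1))
    basis = affine_basis(data.coords)
    rng = np.random.default_rng(0)
    params = ModelParams(nu=np.zeros((3, 1)), beta=np.zeros(10),
                         omega=np.zeros(10, int), sigma2_rw=0.1, lam=1.0,
                         pi_t=np.array([0.5]), theta=0.4, theta_prime=0.8,
                         alpha=np.zeros(4), eta=np.zeros(1), sigma2_obs=0.1)
    for _ in range(200):
        z, y = update_latent_states(params, data, basis, rng)
        assert z[0, 0] == 1
        assert y[0, :, 0].tolist() == [1, 1]
        # unsurveyed sites stay zero
        assert z[1:].sum() == 0


def test_gvs_update_preserves_marginality():
    design = SimDesign(n_sites=60, n_periods=3, K=6)
    data, truth = simulate_dataset(design, derived_seed(BASE_SEED, "gvs-marg"))
    basis = truth.basis
    rng = np.random.default_rng(derived_seed(BASE_SEED, "gvs-marg-rng"))
    params = truth.params()
    gvs = GVSConfig.default()
    z = truth.z
    for _ in range(50):
        omega, beta = update_gvs(params, data, basis, gvs, z, rng)
        assert not np.any((omega[N_CLIMATE:] == 1) & (omega[:N_CLIMATE] == 0))
        params.omega, params.beta = omega, beta


def test_sweep_leaves_joint_distribution_invariant():
    """Successive-conditional (Geweke-style) check: alternating
    data-simulation and one Gibbs sweep must keep every parameter
    distributed according to its prior."""
    rng = np.random.default_rng(derived_seed(BASE_SEED, "geweke"))
    N, T, J, K = 15, 2, 3, 4
    coords = SiteCoordinates(np.arange(N), rng.uniform(30, 45, N),
                             rng.uniform(-95, -75, N))
    basis = build_tprs_basis(coords, K)
    prior = PriorConfig(lambda_shape=50.0, lambda_rate=25.0, sigma_rw_scale=0.3,
                        sigma_obs_scale=0.5, alpha_var=1.0, null_space_sd=1.0)
    gvs = GVSConfig.default()
    wind = rng.integers(0, 3, (N, T))
    first_year = rng.integers(0, 2, (N, T)).astype(np.int8)
    protocol = np.zeros((N, T), np.int8)
    oid = rng.integers(0, 3, (N, T))
    X = rng.standard_normal((N, T, N_CLIMATE))
    observed = np.ones((N, T), dtype=bool)

    def simulate_h(st):
        psi = expit(basis.basis_matrix @ st["nu"]
                    + np.einsum("ntq,q->nt", np.concatenate([X, X**2], axis=2),
                                st["omega"] * st["beta"]))
        z = (rng.random((N, T)) < psi).astype(np.int8)
        y = np.zeros((N, J, T), np.int8)
        y[:, 0, :] = (rng.random((N, T)) < st["pi_t"][None, :]) & (z == 1)
        for j in range(1, J):
            pj = np.where(y[:, j - 1, :] == 1, st["theta_prime"], st["theta"])
            y[:, j, :] = (rng.random((N, T)) < pj) & (z == 1)
        p = expit(st["alpha"][0] + st["alpha"][1] * wind
                  + st["alpha"][2] * first_year + st["alpha"][3] * protocol
                  + st["eta"][oid])
        return ((rng.random((N, J, T)) < p[:, None, :]) & (y == 1)).astype(np.int8)

    def draw_prior_state(kernel):
        st = kernel.init_state(rng)
        st["lam"] = rng.gamma(prior.lambda_shape, 1.0 / prior.lambda_rate)
        st["sigma2_rw"] = float(rng.normal(0, prior.sigma_rw_scale) ** 2)
        st["sigma2_obs"] = float(rng.normal(0, prior.sigma_obs_scale) ** 2)
        S_pen = basis.penalty_matrix[: K - 3, : K - 3]
        evals, evecs = np.linalg.eigh(S_pen)
        wig = evecs @ (rng.standard_normal(K - 3) / np.sqrt(st["lam"] * np.maximum(evals, 1e-12)))
        nu = np.empty((K, T))
        nu[:, 0] = np.concatenate([wig, prior.null_space_sd * rng.standard_normal(3)])
        for t in range(1, T):
            nu[:, t] = nu[:, t - 1] + np.sqrt(st["sigma2_rw"]) * rng.standard_normal(K)
        st["nu"] = nu
        st["omega"][:N_CLIMATE] = rng.random(N_CLIMATE) < 0.5
        st["omega"][N_CLIMATE:] = (rng.random(N_CLIMATE) < 0.5) & (st["omega"][:N_CLIMATE] == 1)
        st["beta"] = np.where(
            st["omega"] == 1,
            np.sqrt(gvs.slab_variance) * rng.standard_normal(2 * N_CLIMATE),
            gvs.mu_pseudo + gvs.sigma_pseudo * rng.standard_normal(2 * N_CLIMATE))
        st["pi_t"] = rng.random(T)
        st["theta"] = float(rng.random())
        st["theta_prime"] = float(rng.random())
        st["alpha"] = np.sqrt(prior.alpha_var) * rng.standard_normal(4)
        st["sigma2_obs"] = max(st["sigma2_obs"], 1e-8)
        st["eta"] = np.sqrt(st["sigma2_obs"]) * rng.standard_normal(3)
        return st

    from occugam._polyagamma import seed_pg

    seed_pg(derived_seed(BASE_SEED, "geweke-pg") % (2**31 - 1) + 1)
    data0 = OccupancyData(h=np.zeros((N, J, T), np.int8), observed=observed,
                          wind=wind, first_year=first_year, protocol=protocol,
                          observer_id=oid, X=X, coords=coords)
    kernel = GibbsSampler(data0, basis, gvs, prior=prior)
    st = draw_prior_state(kernel)
    M, burn = 20_000, 200
    rec = {k: [] for k in ("theta", "theta_prime", "pi0", "alpha0", "sigma2_obs")}
    for m in range(M + burn):
        kernel.h = simulate_h(st).astype(float)[kernel.ii, :, kernel.tt]
        kernel.sweep(st, rng)
        if m >= burn:
            rec["theta"].append(st["theta"])
            rec["theta_prime"].append(st["theta_prime"])
            rec["pi0"].append(st["pi_t"][0])
            rec["alpha0"].append(st["alpha"][0])
            rec["sigma2_obs"].append(st["sigma2_obs"])
    # Uniform(0,1) marginals for the availability probabilities
    for name in ("theta", "theta_prime", "pi0"):
        v = np.asarray(rec[name])
        assert abs(v.mean() - 0.5) < 0.035, name
        assert abs(v.std() - np.sqrt(1.0 / 12.0)) < 0.03, name
    a0 = np.asarray(rec["alpha0"])
    assert abs(a0.mean()) < 0.12
    assert 0.85 < a0.std() < 1.15
    # sigma2_obs ~ (half-normal scale 0.5)^2 has mean 0.25
    assert abs(np.mean(rec["sigma2_obs"]) - 0.25) < 0.08


def test_fit_is_deterministic_given_seed():
    design = SimDesign(n_sites=40, n_periods=3, K=6)
    data, truth = simulate_dataset(design, derived_seed(BASE_SEED, "det-data"))
    cfg = MCMCConfig(n_chains=2, n_warmup=50, n_samples=50,
                     seed=derived_seed(BASE_SEED, "det-fit"))
    s1 = fit(data, truth.basis, GVSConfig.default(), cfg)
    s2 = fit(data, truth.basis, GVSConfig.default(), cfg)
    for name in s1.draws:
        assert np.array_equal(s1.draws[name], s2.draws[name]), name


def test_samples_save_load_roundtrip(tmp_path):
    design = SimDesign(n_sites=30, n_periods=2, K=5)
    data, truth = simulate_dataset(design, derived_seed(BASE_SEED, "io-data"))
    cfg = MCMCConfig(n_chains=2, n_warmup=20, n_samples=30,
                     seed=derived_seed(BASE_SEED, "io-fit"))
    s = fit(data, truth.basis, GVSConfig.default(), cfg)
    path = tmp_path / "draws.npz"
    s.save(str(path))
    s2 = PosteriorSamples.load(str(path))
    for name in s.draws:
        assert np.array_equal(s.draws[name], s2.draws[name]), name
    assert np.array_equal(s.chain_meta["obs_site"], s2.chain_meta["obs_site"])
    assert s.converged == s2.converged
    assert list(s.diagnostics["param"]) == list(s2.diagnostics["param"])


def test_diagnostics_cover_monitored_parameters():
    design = SimDesign(n_sites=30, n_periods=2, K=5)
    data, truth = simulate_dataset(design, derived_seed(BASE_SEED, "diag-data"))
    cfg = MCMCConfig(n_chains=2, n_warmup=20, n_samples=30,
                     seed=derived_seed(BASE_SEED, "diag-fit"))
    s = fit(data, truth.basis, GVSConfig.default(), cfg)
    names = set(s.diagnostics["param"])
    assert {"theta", "theta_prime", "lam", "sigma2_rw"} <= names
    assert any(n.startswith("alpha") for n in names)
    assert any(n.startswith("nu") for n in names)
    assert isinstance(s.converged, bool)


def test_slice_sampler_targets_the_given_density():
    rng = np.random.default_rng(derived_seed(BASE_SEED, "slice"))
    logf = lambda x: -0.5 * x**2
    x = 0.0
    draws = []
    for _ in range(20_000):
        x = _slice_sample(logf, x, rng)
        draws.append(x)
    draws = np.asarray(draws[500:])
    assert abs(draws.mean()) < 0.05
    assert abs(draws.std() - 1.0) < 0.05


def test_draw_mvn_moments():
    rng = np.random.default_rng(derived_seed(BASE_SEED, "mvn"))
    L = rng.standard_normal((3, 3))
    A = L @ L.T + 3.0 * np.eye(3)
    b = rng.standard_normal(3)
    draws = np.array([_draw_mvn(A, b, rng) for _ in range(40_000)])
    mu = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    assert np.abs(draws.mean(axis=0) - mu).max() < 0.02
    assert np.abs(np.cov(draws.T) - cov).max() < 0.02


# ---------------------------------------------------------------------------
# pilot pseudo-prior fit


def static_pilot_design():
    return SimDesign(n_sites=250, n_periods=3, K=8, sigma2_rw=1e-8,
                     beta=np.array([1.0, -0.7, 0, 0, 0, 0, 0, 0, 0, 0], float),
                     omega=np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]))


def test_pilot_estimates_cover_truth_across_replicates():
    """Sampling-distribution check on near-static surfaces (the pilot
    assumes a time-constant smooth): at least 90% of the 50 coefficient
    estimates over 5 replicates fall within 3.5 standard errors of truth."""
    hits = total = 0
    truth_beta = np.array([1.0, -0.7, 0, 0, 0, 0, 0, 0, 0, 0], float)
    for rep in range(5):
        data, truth = simulate_dataset(static_pilot_design(),
                                       derived_seed(BASE_SEED, "pilot", rep))
        gvs = estimate_pseudopriors(data, truth.basis)
        assert np.all(gvs.sigma_pseudo > 0)
        dev = np.abs(gvs.mu_pseudo - truth_beta) / gvs.sigma_pseudo
        hits += int((dev < 3.5).sum())
        total += dev.size
    assert hits / total >= 0.9, (hits, total)


def test_pilot_is_deterministic():
    data, truth = simulate_dataset(static_pilot_design(),
                                   derived_seed(BASE_SEED, "pilot", 0))
    g1 = estimate_pseudopriors(data, truth.basis)
    g2 = estimate_pseudopriors(data, truth.basis)
    assert np.array_equal(g1.mu_pseudo, g2.mu_pseudo)
    assert np.array_equal(g1.sigma_pseudo, g2.sigma_pseudo)


def test_pilot_requires_surveyed_routes():
    data, truth = simulate_dataset(SimDesign(n_sites=30, n_periods=2, K=5),
                                   derived_seed(BASE_SEED, "pilot-empty"))
    data.observed[:] = False
    with pytest.raises(ValueError, match="pilot"):
        estimate_pseudopriors(data, truth.basis)


def test_posterior_collapses_to_logistic_regression():
    """With one period and a null-space-only basis the model reduces to a
    plain logistic occupancy fit: posterior means of the climate
    coefficients match the pilot maximum-likelihood estimates within
    Monte-Carlo error (well under one standard error)."""
    design = SimDesign(n_sites=400, n_periods=1, K=None, missing_rate=0.0,
                       beta=np.array([1.2, -0.9, 0, 0, 0, 0, 0, 0, 0, 0], float),
                       omega=np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]),
                       alpha=np.array([2.5, 0.0, 0.0, 0.0]), pi=0.9,
                       theta=0.5, theta_prime=0.9, sigma2_obs=1e-10)
    data, _ = simulate_dataset(design, derived_seed(BASE_SEED, "collapse"))
    # a single shared observer keeps detection free of per-route effects
    data = OccupancyData(h=data.h, observed=data.observed, wind=data.wind,
                         first_year=np.zeros_like(data.first_year),
                         protocol=data.protocol,
                         observer_id=np.zeros_like(data.observer_id),
                         X=data.X, coords=data.coords)
    basis = affine_basis(data.coords)
    gvs = estimate_pseudopriors(data, basis)
    cfg = MCMCConfig(n_chains=2, n_warmup=600, n_samples=1000,
                     seed=derived_seed(BASE_SEED, "collapse-fit"), fix_omega=True)
    s = fit(data, basis, gvs, cfg)
    post_mean = s.stacked("beta").mean(axis=0)
    dev = np.abs(post_mean - gvs.mu_pseudo) / gvs.sigma_pseudo
    assert dev.max() < 0.8, dev
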