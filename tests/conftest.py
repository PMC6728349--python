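"""Shared fixtures and exhaustive-enumeration helpers.

The expensive fixture is ``recovery_study``: twenty simulate-then-fit
replicates at the selection scale (150-300 sites, 6-8 periods) shared by
the parameter-recovery, covariate-ranking and PPC-calibration tests so
the MCMC cost is paid once per session.
"""

from __future__ import annotations

import zlib

import numpy as np
import pytest

from occugam.model import GVSConfig, N_CLIMATE
from occugam.sampler import MCMCConfig, estimate_pseudopriors, fit
from occugam.simulate import SimDesign, make_fixture, simulate_dataset

BASE_SEED = 20240601
N_RECOVERY = 20

# generating values shared by the recovery replicates (the selection design)
RECOVERY_BETA = np.array([1.0, -0.7, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
RECOVERY_OMEGA = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])


def derived_seed(*key) -> int:
    """Deterministic sub-seed below 2^31 from a tuple of ints/strings."""
    parts = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def brute_force_history_prob(h_row, psi, pi, theta, theta_prime, p) -> float:
    """Pr(history) by exhaustive summation over z in {0,1} and all 2^J
    availability sequences; the independent oracle for the forward
    recursion in the model module."""
    h_row = np.asarray(h_row)
    J = h_row.size
    total = 0.0
    for z in (0, 1):
        pz = psi if z == 1 else 1.0 - psi
        for code in range(2**J):
            y = [(code >> (J - 1 - j)) & 1 for j in range(J)]
            py = 1.0
            for j in range(J):
                if z == 0:
                    py *= 1.0 if y[j] == 0 else 0.0
                elif j == 0:
                    py *= pi if y[0] == 1 else 1.0 - pi
                else:
                    tr = theta_prime if y[j - 1] == 1 else theta
                    py *= tr if y[j] == 1 else 1.0 - tr
            if py == 0.0:
                continue
            ph = 1.0
            for j in range(J):
                pd = p if y[j] == 1 else 0.0
                ph *= pd if h_row[j] == 1 else 1.0 - pd
            total += pz * py * ph
    return total


@pytest.fixture(scope="session")
def tiny_pair():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def selection_pair():
    return make_fixture("selection")


@pytest.fixture(scope="session")
def shift_pair():
    return make_fixture("shift")


def recovery_design(rep: int) -> SimDesign:
    """Replicate designs spanning 150-300 sites and 6-8 periods.

    The availability/detection values put the truth inside the
    high-likelihood region of the (availability, detection) trade-off: a
    persistent availability chain (theta << theta') thinned by mid-range
    per-stop detection leaves a strong serial signature in the histories,
    which is what identifies the split.
    """
    sites = [150, 300, 200, 250, 175, 225, 275, 160, 240, 190,
             210, 260, 155, 285, 170, 230, 295, 205, 245, 180][rep]
    periods = [6, 7, 8][rep % 3]
    return SimDesign(n_sites=sites, n_periods=periods, K=12,
                     beta=RECOVERY_BETA.copy(), omega=RECOVERY_OMEGA.copy(),
                     theta=0.2, theta_prime=0.85, pi=0.7, intercept=1.0,
                     alpha=np.array([0.0, -0.3, -0.2, -0.2]))


@pytest.fixture(scope="session")
def recovery_study():
    """Twenty simulate + pilot + fit replicates at the selection scale."""
    results = []
    for rep in range(N_RECOVERY):
        design = recovery_design(rep)
        data, truth = simulate_dataset(design, derived_seed(BASE_SEED, "recovery-data", rep))
        basis = truth.basis
        try:
            gvs = estimate_pseudopriors(data, basis)
        except RuntimeError:
            gvs = GVSConfig.default()
        cfg = MCMCConfig(n_chains=2, n_warmup=400, n_samples=600,
                         seed=derived_seed(BASE_SEED, "recovery-fit", rep))
        samples = fit(data, basis, gvs, cfg)
        results.append({"rep": rep, "design": design, "data": data,
                        "truth": truth, "basis": basis, "gvs": gvs,
                        "samples": samples})
    return results
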