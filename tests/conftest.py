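"""Shared fixtures.

Simulation pools are session-scoped and seeded so the replicate experiments
(parameter recovery, branch averaging) compute each scenario once.
"""

import pytest

from selage.inference import SelectionLikelihood
from selage.popmodel import constant_model
from selage.simulator import simulate_sites, tune_theta


@pytest.fixture(scope="session")
def small_constant():
    """Small constant model (n=10, N=200, gamma=-2) with its trajectory and
    joint matrix; cheap enough for exhaustive equivalence checks."""
    from selage.age_distribution import joint_age_frequency
    from selage.sfs_dynamics import evolve_sfs

    model = constant_model(n=10, N=200, s=-0.005, mu=1.0 / 800.0, Tmax=2000)
    traj = evolve_sfs(model)
    joint = joint_age_frequency(model)
    return model, traj, joint


def _scenario(gamma: float, Tmax: int, n_reps: int, seed0: int):
    """Simulated replicate pool plus a cached likelihood for one scenario.

    Study conditions follow the simulation design the simulator emulates:
    N = 10,000 diploids, n = 100 sampled diploids, additive selection with
    the stated scaled coefficient, mutation influx tuned so each replicate
    holds ~1,000 segregating sites.
    """
    N, n = 10000, 100
    tpl = constant_model(n=n, N=N, s=0.0, mu=0.0, Tmax=Tmax)
    tpl.mu[:] = 1.0 / (4 * N)
    s_true = gamma / (2 * N)
    theta = tune_theta(tpl.with_selection(s_true), 1000.0)
    tpl.mu[:] = theta / (4.0 * N)
    reps = [simulate_sites(tpl.with_selection(s_true), seed=seed0 + r, theta=theta)
            for r in range(n_reps)]
    lik = SelectionLikelihood(tpl, s_resolution=2e-5)
    return {"gamma": gamma, "s_true": s_true, "template": tpl, "theta": theta,
            "replicates": reps, "likelihood": lik, "N": N, "n": n, "Tmax": Tmax}


@pytest.fixture(scope="session")
def pool_gamma20():
    """30 replicates of ~1,000 sites at gamma = -20 (constant N = 10,000)."""
    return _scenario(-20.0, Tmax=6000, n_reps=30, seed0=20000)


@pytest.fixture(scope="session")
def pool_gamma100():
    """30 replicates of ~1,000 sites at gamma = -100 (constant N = 10,000)."""
    return _scenario(-100.0, Tmax=2500, n_reps=30, seed0=10000)
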