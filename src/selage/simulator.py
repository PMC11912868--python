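"""Forward-in-time Wright-Fisher simulator of unlinked selected sites.

Sites are independent (Poisson random field regime): each generation a
Poisson number of new mutations arises, each starting at one copy; each
segregating allele's frequency is updated by deterministic additive
selection (``x' = x + s x (1-x)``, the same per-copy convention as the
moment operator, verified by a shared stationary-density oracle) followed
by binomial resampling of 2N chromosomes; fixed and lost alleles are
dropped.  At the present the population is sampled binomially down to 2n
chromosomes and sites segregating in the sample are retained, yielding
paired (derived count, true age) observations.

The per-generation mutation influx is ``2 N_t mu_t`` new alleles, each at
initial frequency ``1/(2N)``, which injects ``2n mu_t`` expected sample
singletons per generation — the same bookkeeping as the expected-SFS
recursion.  The scaled rate ``theta = 4 N_0 mu`` refers to the present-day
size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .errors import ValidationError
from .popmodel import PopulationModel

__all__ = [
    "simulate_sites",
    "apply_maf_threshold",
    "synthesize_branch_intervals",
    "tune_theta",
]


@njit(cache=False)
def _run_wf(twoN: np.ndarray, s: np.ndarray, influx: np.ndarray, Tmax: int,
            K: int, seed: int):
    """Inner Wright-Fisher loop.

    ``twoN[t]``: chromosomes at generation t; ``influx[t]``: expected new
    mutations during the step producing generation t-1 (these arise at one
    copy in generation t-1 and carry age t).  Returns (sample counts, ages,
    present population frequencies) of sites segregating in the sample.
    """
    np.random.seed(seed)
    cap = 4096
    k = np.zeros(cap, dtype=np.int64)
    age = np.zeros(cap, dtype=np.int64)
    m = 0
    for t in range(Tmax, 0, -1):
        twoN_cur = twoN[t]
        twoN_next = twoN[t - 1]
        st = s[t]
        j = 0
        for idx in range(m):
            x = k[idx] / twoN_cur
            xp = x + st * x * (1.0 - x)
            if xp < 0.0:
                xp = 0.0
            elif xp > 1.0:
                xp = 1.0
            kk = np.random.binomial(twoN_next, xp)
            if 0 < kk < twoN_next:
                k[j] = kk
                age[j] = age[idx]
                j += 1
        m = j
        nnew = np.random.poisson(influx[t])
        if m + nnew > cap:
            while cap < m + nnew:
                cap *= 2
            knew = np.zeros(cap, dtype=np.int64)
            anew = np.zeros(cap, dtype=np.int64)
            knew[:m] = k[:m]
            anew[:m] = age[:m]
            k, age = knew, anew
        for _ in range(nnew):
            k[m] = 1
            age[m] = t
            m += 1
    # present-day binomial sampling down to K chromosomes
    out_i = np.empty(m, dtype=np.int64)
    out_age = np.empty(m, dtype=np.int64)
    out_x = np.empty(m, dtype=np.float64)
    nseg = 0
    twoN0 = twoN[0]
    for idx in range(m):
        x = k[idx] / twoN0
        i = np.random.binomial(K, x)
        if 0 < i < K:
            out_i[nseg] = i
            out_age[nseg] = age[idx]
            out_x[nseg] = x
            nseg += 1
    return out_i[:nseg], out_age[:nseg], out_x[:nseg]


def simulate_sites(model: PopulationModel, seed: int,
                   theta: float | None = None,
                   keep_trajectories: bool = False):
    """Simulate paired (derived count, age) data for sites segregating in a
    sample of 2n chromosomes.

    ``theta``, if given, overrides the model's mutation rates with the
    constant rate ``mu = theta / (4 N_0)``.  A seed is required: simulation
    is the only stochastic component of the package and identical seeds
    yield identical site tables.

    Returns a DataFrame with columns ``site_id``, ``derived_count``,
    ``sample_n``, ``age_gen``, ``pop_freq``.  With
    ``keep_trajectories=True`` a pair ``(sites, trajectories)`` is returned
    instead, the second element a long-format DataFrame (site_id, gen,
    pop_count, pop_freq) holding the full population-frequency path of
    every retained site; this path runs in pure Python and is intended for
    small horizons (debugging, visualisation), not production-scale runs.
    """
    if seed is None:
        raise ValidationError("simulate_sites requires a seed")
    mu = model.mu
    if theta is not None:
        if theta <= 0:
            raise ValidationError("theta must be positive")
        mu = np.full_like(mu, theta / (4.0 * model.N[0]))
    twoN = np.rint(2.0 * model.N).astype(np.int64)
    influx = twoN[np.maximum(np.arange(model.Tmax + 1) - 1, 0)] * mu
    if keep_trajectories:
        return _run_wf_py(twoN, model.s, influx, model.Tmax, model.K,
                          model.n, int(seed) & 0x7FFFFFFF)
    i_arr, age_arr, x_arr = _run_wf(twoN, model.s.astype(np.float64),
                                    influx.astype(np.float64),
                                    model.Tmax, model.K, int(seed) & 0x7FFFFFFF)
    return pd.DataFrame({
        "site_id": np.arange(len(i_arr)),
        "derived_count": i_arr,
        "sample_n": model.n,
        "age_gen": age_arr,
        "pop_freq": x_arr,
    })


def _run_wf_py(twoN, s, influx, Tmax, K, n, seed):
    """Trajectory-recording reference loop (same dynamics as the compiled
    path, independent RNG stream)."""
    rng = np.random.default_rng(seed)
    alleles: list[dict] = []  # each: age, count, path [(gen, count), ...]
    for t in range(Tmax, 0, -1):
        twoN_cur, twoN_next, st = twoN[t], twoN[t - 1], s[t]
        survivors = []
        for al in alleles:
            x = al["count"] / twoN_cur
            xp = min(max(x + st * x * (1.0 - x), 0.0), 1.0)
            kk = int(rng.binomial(twoN_next, xp))
            if 0 < kk < twoN_next:
                al["count"] = kk
                al["path"].append((t - 1, kk))
                survivors.append(al)
        alleles = survivors
        for _ in range(rng.poisson(influx[t])):
            alleles.append({"age": t, "count": 1, "path": [(t - 1, 1)]})
    rows, traj_rows = [], []
    site_id = 0
    for al in alleles:
        i = int(rng.binomial(K, al["count"] / twoN[0]))
        if 0 < i < K:
            rows.append((site_id, i, n, al["age"], al["count"] / twoN[0]))
            for gen, cnt in al["path"]:
                traj_rows.append((site_id, gen, cnt, cnt / twoN[gen]))
            site_id += 1
    sites = pd.DataFrame(rows, columns=["site_id", "derived_count", "sample_n",
                                        "age_gen", "pop_freq"])
    trajs = pd.DataFrame(traj_rows, columns=["site_id", "gen", "pop_count",
                                             "pop_freq"])
    return sites, trajs


def apply_maf_threshold(sites: pd.DataFrame, n: int, x_star: float) -> pd.DataFrame:
    """Retain sites with minor allele frequency >= x_star in the sample.

    MAF is ``min(i, 2n-i) / 2n`` computed on the derived count.
    """
    if not (0 <= x_star < 0.5):
        raise ValidationError("x_star must lie in [0, 0.5)")
    K = 2 * n
    i = sites["derived_count"].to_numpy()
    maf = np.minimum(i, K - i) / K
    return sites.loc[maf >= x_star].reset_index(drop=True)


def synthesize_branch_intervals(sites: pd.DataFrame, relative_width: float,
                                seed: int, Tmax: int | None = None) -> pd.DataFrame:
    """Attach synthetic branch intervals [a_b, a_e] around the true ages.

    Stands in for branch intervals estimated from reconstructed gene trees.
    All sites share a common interval width ``W = relative_width * mean(a)``
    (so the expected width is ``relative_width`` times the typical true
    age), and each interval contains its site's true age at a uniformly
    random position: ``a_b = a - U * W``, ``a_e = a_b + W`` with U uniform.

    The width is deliberately *independent of the site's own age*: given
    the interval, the probability of producing it is then the same for
    every age the interval covers, which is the property of a dated
    genealogical branch (age uniform along the branch, given the tree)
    that makes the interval-averaged likelihood a valid marginal
    likelihood.  An age-proportional per-site width would leak the age
    through the width and bias interval-averaged estimates.  Width 0
    collapses to the point age.
    """
    if relative_width < 0:
        raise ValidationError("relative_width must be nonnegative")
    if "age_gen" not in sites.columns or sites["age_gen"].isna().any():
        raise ValidationError("sites must carry true ages")
    rng = np.random.default_rng(seed)
    a = sites["age_gen"].to_numpy().astype(float)
    W = relative_width * a.mean()
    u = rng.random(len(a))
    lo = np.floor(a - u * W)
    hi = np.ceil((a - u * W) + W)
    lo = np.clip(lo, 1, a)
    hi = np.maximum(hi, a)
    if Tmax is not None:
        hi = np.minimum(hi, Tmax)
    out = sites.copy()
    out["branch_lower_gen"] = lo.astype(int)
    out["branch_upper_gen"] = hi.astype(int)
    return out


def tune_theta(model: PopulationModel, target_segregating: float = 1000.0) -> float:
    """Scaled mutation rate theta = 4 N_0 mu yielding the requested expected
    number of segregating sites in the sample.

    Uses linearity of the expected SFS in mu: the spectrum is computed once
    at theta = 1 and rescaled.
    """
    from .sfs_dynamics import evolve_sfs

    if target_segregating <= 0:
        raise ValidationError("target_segregating must be positive")
    probe = 1.0
    mdl = model.with_mu_scaled(0.0)
    mdl.mu = np.full_like(model.mu, probe / (4.0 * model.N[0]))
    seg = evolve_sfs(mdl).phi0.sum()
    return probe * target_segregating / seg
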