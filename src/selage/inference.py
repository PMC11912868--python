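"""Poisson random field likelihoods and maximum-likelihood estimation of
selection coefficients, with Fisher-information diagnostics.

Under the PRF model the number of sites observed at derived sample count i
is Poisson with mean equal to the expected SFS entry, independently across
bins; given ages, the counts split further into independent Poisson cells
``X[i][a] ~ Pois(Phi0[i] * P(a|i))`` (Poisson splitting).  Likelihood
modes:

* ``freq``       — frequency-only: product of Poisson terms over SFS bins.
* ``freq_age``   — joint frequency and (exact) age.
* ``branch``     — ages known only up to a genealogical branch interval;
  each site's age term is averaged over the interval (uniformly over the
  discrete generations it covers, or by Monte Carlo draws).

A minor-allele-frequency threshold restricts the Poisson product to the
retained bins (valid by independence).  The total mutation rate is treated
as known by default; ``profile_theta=True`` profiles out an overall scale
of the Poisson means analytically (the MLE scale matches the observed
total), so that only the shape of the spectrum and the ages inform the
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .age_distribution import joint_age_frequency
from .errors import ValidationError
from .popmodel import PopulationModel
from .sfs_dynamics import equilibrium_sfs, evolve_sfs

__all__ = [
    "SelectionLikelihood",
    "FitResult",
    "InformationSummary",
    "loglik_frequency",
    "loglik_frequency_age",
    "loglik_branch_averaged",
    "fit_gamma",
    "fisher_information",
    "variance_ratio",
    "read_sites",
    "write_sites",
]

_MODES = ("freq", "freq_age", "branch")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def read_sites(path) -> pd.DataFrame:
    """Read a sites TSV (columns site_id, derived_count, sample_n, optional
    age_gen, branch_lower_gen, branch_upper_gen; '#' lines are comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "derived_count" not in df.columns:
        raise ValidationError("sites table must have a derived_count column")
    return df


def write_sites(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _validate_sites(sites: pd.DataFrame, K: int, Tmax: int, mode: str) -> None:
    i = sites["derived_count"].to_numpy()
    if np.any((i < 1) | (i > K - 1)):
        raise ValidationError("derived counts out of range 1..2n-1")
    if mode == "freq_age":
        if "age_gen" not in sites.columns or sites["age_gen"].isna().any():
            raise ValidationError("freq_age mode requires an age for every site")
        a = sites["age_gen"].to_numpy()
        if np.any((a < 1) | (a > Tmax)):
            raise ValidationError(f"site ages outside 1..Tmax={Tmax}")
    if mode == "branch":
        for c in ("branch_lower_gen", "branch_upper_gen"):
            if c not in sites.columns or sites[c].isna().any():
                raise ValidationError("branch mode requires interval columns")
        lo = sites["branch_lower_gen"].to_numpy()
        hi = sites["branch_upper_gen"].to_numpy()
        if np.any(lo > hi) or np.any(lo < 1) or np.any(hi > Tmax):
            raise ValidationError("invalid branch intervals")


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------

def _poisson_loglik(X: np.ndarray, lam: np.ndarray) -> float:
    """Sum of independent Poisson log-pmfs; lam=0 with X>0 gives -inf."""
    X = np.asarray(X, dtype=float)
    lam = np.asarray(lam, dtype=float)
    bad = (lam <= 0) & (X > 0)
    if np.any(bad):
        return -np.inf
    pos = lam > 0
    return float(np.sum(X[pos] * np.log(lam[pos]) - lam[pos] - gammaln(X[pos] + 1.0))
                 - lam[~pos].sum())


def loglik_frequency(X: np.ndarray, lam: np.ndarray,
                     retained: np.ndarray | None = None,
                     profile_theta: bool = False) -> float:
    """Frequency-only PRF log-likelihood.

    ``X[i-1]`` are observed site counts per bin, ``lam`` the expected SFS.
    ``retained`` is an optional boolean mask of bins kept after a MAF
    threshold; the product runs only over retained bins, with unmodified
    Poisson means.
    """
    X = np.asarray(X, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if X.shape != lam.shape:
        raise ValidationError("X and lam must have equal length 2n-1")
    if retained is not None:
        X, lam = X[retained], lam[retained]
    if profile_theta:
        tot = lam.sum()
        if tot <= 0:
            return -np.inf
        lam = lam * (X.sum() / tot)
    return _poisson_loglik(X, lam)


def loglik_frequency_age(sites: pd.DataFrame, lam: np.ndarray,
                         conditional_ages: np.ndarray,
                         retained: np.ndarray | None = None,
                         profile_theta: bool = False,
                         form: str = "split") -> float:
    """Joint frequency-and-age PRF log-likelihood.

    ``conditional_ages[a-1, i-1] = P(a | i)``.  ``form="split"`` evaluates
    the frequency-only Poisson product times the per-site conditional age
    probabilities; ``form="cells"`` evaluates the equivalent product of
    independent Poisson cells over every (i, a) pair.  The two are identical
    by Poisson splitting and are both provided as a consistency check.
    """
    K = len(lam) + 1
    Tmax = conditional_ages.shape[0]
    _validate_sites(sites, K, Tmax, "freq_age")
    i = sites["derived_count"].to_numpy().astype(int)
    a = sites["age_gen"].to_numpy().astype(int)
    if retained is not None:
        keep = retained[i - 1]
        i, a = i[keep], a[keep]
    X = np.bincount(i, minlength=K)[1:K].astype(float)
    if form == "split":
        base = loglik_frequency(X, lam, retained, profile_theta)
        if not np.isfinite(base):
            return base
        p = conditional_ages[a - 1, i - 1]
        if np.any(p <= 0):
            return -np.inf
        # Poisson splitting: Pois(X_i) x Multinomial(ages | X_i); the
        # multinomial coefficient makes this exactly the likelihood of the
        # unordered cell counts (it carries no selection information but
        # keeps the two forms numerically identical)
        cell_counts = pd.DataFrame({"i": i, "a": a}).groupby(["i", "a"]).size().to_numpy()
        coeff = float(gammaln(X + 1.0).sum() - gammaln(cell_counts + 1.0).sum())
        return base + float(np.log(p).sum()) + coeff
    if form != "cells":
        raise ValidationError("form must be 'split' or 'cells'")
    lam_use = lam if retained is None else np.where(retained, lam, 0.0)
    if profile_theta:
        Xtot, ltot = X.sum() if retained is None else X[retained].sum(), lam_use.sum()
        if ltot <= 0:
            return -np.inf
        scale = Xtot / ltot
    else:
        scale = 1.0
    # sparse cells: observed (i, a) pairs, plus the total-mean term
    cells = pd.DataFrame({"i": i, "a": a}).groupby(["i", "a"]).size()
    ll = -float(lam_use.sum()) * scale
    for (ii, aa), x in cells.items():
        mean = lam_use[ii - 1] * conditional_ages[aa - 1, ii - 1] * scale
        if mean <= 0:
            return -np.inf
        ll += x * np.log(mean) - gammaln(x + 1.0)
    return ll


def loglik_branch_averaged(sites: pd.DataFrame, lam: np.ndarray,
                           conditional_ages: np.ndarray,
                           retained: np.ndarray | None = None,
                           profile_theta: bool = False,
                           mode: str = "exact_grid", D: int = 500,
                           seed: int | None = None) -> float:
    """Branch-averaged PRF log-likelihood.

    Each site's age term is the average of P(a|i) over its branch interval
    [a_b, a_e]: in ``exact_grid`` mode the uniform average over the discrete
    generations covered (deterministic); in ``monte_carlo`` mode the average
    over D uniform draws from the interval (requires a seed).  A degenerate
    interval a_b = a_e = a recovers the exact-age likelihood.
    """
    K = len(lam) + 1
    Tmax = conditional_ages.shape[0]
    _validate_sites(sites, K, Tmax, "branch")
    i = sites["derived_count"].to_numpy().astype(int)
    lo = sites["branch_lower_gen"].to_numpy().astype(int)
    hi = sites["branch_upper_gen"].to_numpy().astype(int)
    if retained is not None:
        keep = retained[i - 1]
        i, lo, hi = i[keep], lo[keep], hi[keep]
    X = np.bincount(i, minlength=K)[1:K].astype(float)
    base = loglik_frequency(X, lam, retained, profile_theta)
    if not np.isfinite(base):
        return base
    # cumulative sums along ages give O(1) interval averages per site
    csum = np.vstack([np.zeros(conditional_ages.shape[1]),
                      np.cumsum(conditional_ages, axis=0)])
    if mode == "exact_grid":
        avg = (csum[hi, i - 1] - csum[lo - 1, i - 1]) / (hi - lo + 1)
    elif mode == "monte_carlo":
        if seed is None:
            raise ValidationError("monte_carlo branch averaging requires a seed")
        rng = np.random.default_rng(seed)
        draws = rng.integers(lo[:, None], hi[:, None] + 1, size=(len(i), D))
        avg = conditional_ages[draws - 1, i[:, None] - 1].mean(axis=1)
    else:
        raise ValidationError("mode must be 'exact_grid' or 'monte_carlo'")
    if np.any(avg <= 0):
        return -np.inf
    return base + float(np.log(avg).sum())


# ---------------------------------------------------------------------------
# expected-model cache and fitting
# ---------------------------------------------------------------------------

class SelectionLikelihood:
    """Expected SFS and age machinery for a demographic template, as a
    function of a single constant selection coefficient.

    Results are cached per selection coefficient (Brent's method revisits
    endpoints, and replicate fits on the same template share the cache).
    Constant-parameter templates use the direct equilibrium solve for the
    SFS; the joint age matrix always comes from the cohort recursion.
    """

    def __init__(self, template: PopulationModel, s_resolution: float | None = None):
        self.template = template
        #: optional quantum on s: evaluations snap to multiples, so replicate
        #: fits on a shared template reuse each other's cached spectra (set
        #: it well below the Monte Carlo spread of the estimates)
        self.s_resolution = s_resolution
        self._phi: dict[float, np.ndarray] = {}
        self._cond: dict[float, np.ndarray] = {}

    def _key(self, s: float) -> float:
        if self.s_resolution:
            return round(float(s) / self.s_resolution) * self.s_resolution
        return float(s)

    def model_at(self, s: float) -> PopulationModel:
        return self.template.with_selection(self._key(s))

    def phi0(self, s: float) -> np.ndarray:
        s = self._key(s)
        if s not in self._phi:
            mdl = self.model_at(s)
            if mdl.is_constant():
                self._phi[s] = equilibrium_sfs(mdl.n, mdl.N[1], s, mdl.mu[1])
            else:
                self._phi[s] = evolve_sfs(mdl).phi0
        return self._phi[s]

    def conditional_ages(self, s: float) -> np.ndarray:
        s = self._key(s)
        if s not in self._cond:
            self._cond[s] = joint_age_frequency(self.model_at(s)).conditional_matrix()
        return self._cond[s]

    def gamma(self, s: float) -> float:
        return 2.0 * float(self.template.N[0]) * s


@dataclass
class FitResult:
    """Maximum-likelihood estimate of a selection coefficient."""

    s_hat: float
    gamma_hat: float
    loglik: float
    converged: bool
    mode: str
    maf_min: float = 0.0
    n_sites: int = 0
    at_bound: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("s_hat", "gamma_hat", "loglik", "converged", "mode",
                 "maf_min", "n_sites", "at_bound")}


def _retained_mask(K: int, maf_min: float) -> np.ndarray | None:
    if maf_min <= 0:
        return None
    i = np.arange(1, K)
    return np.minimum(i, K - i) / K >= maf_min


def fit_gamma(sites: pd.DataFrame, likelihood: SelectionLikelihood,
              mode: str = "freq", maf_min: float = 0.0,
              bounds: tuple[float, float] = (-0.05, 0.05),
              profile_theta: bool = False,
              branch_mode: str = "exact_grid", D: int = 500,
              seed: int | None = None, xatol: float = 1e-6) -> FitResult:
    """Estimate the selection coefficient by bounded scalar minimization of
    the negative log-likelihood (Brent-style bounded search over s).

    ``mode`` selects the data used: frequency only, frequency + exact age,
    or frequency + branch interval.  Sites below the MAF threshold are
    discarded before fitting; an empty table after thresholding is an
    error.  The optimum landing at a search bound is flagged.
    """
    if mode not in _MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    K = likelihood.template.K
    mask = _retained_mask(K, maf_min)
    i = sites["derived_count"].to_numpy().astype(int)
    if np.any((i < 1) | (i > K - 1)):
        raise ValidationError("derived counts out of range 1..2n-1")
    n_kept = int(len(i) if mask is None else mask[i - 1].sum())
    if n_kept == 0:
        raise ValidationError("no sites left after thresholding")

    def nll(s: float) -> float:
        lam = likelihood.phi0(s)
        if mode == "freq":
            X = np.bincount(i, minlength=K)[1:K].astype(float)
            ll = loglik_frequency(X, lam, mask, profile_theta)
        elif mode == "freq_age":
            ll = loglik_frequency_age(sites, lam, likelihood.conditional_ages(s),
                                      mask, profile_theta)
        else:
            ll = loglik_branch_averaged(sites, lam, likelihood.conditional_ages(s),
                                        mask, profile_theta,
                                        mode=branch_mode, D=D, seed=seed)
        return -ll if np.isfinite(ll) else 1e300

    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    s_hat = float(res.x)
    span = bounds[1] - bounds[0]
    at_bound = min(s_hat - bounds[0], bounds[1] - s_hat) < 1e-3 * span
    return FitResult(
        s_hat=s_hat,
        gamma_hat=likelihood.gamma(s_hat),
        loglik=-float(res.fun),
        converged=bool(res.success),
        mode=mode,
        maf_min=maf_min,
        n_sites=n_kept,
        at_bound=at_bound,
    )


# ---------------------------------------------------------------------------
# information diagnostics
# ---------------------------------------------------------------------------

@dataclass
class InformationSummary:
    """Per-site Fisher information about gamma, with and without ages."""

    gamma: float
    I_freq: float
    I_freq_age: float
    step_gamma: float
    maf_min: float = 0.0

    @property
    def info_ratio(self) -> float:
        return self.I_freq_age / self.I_freq


def _segregation_probs(likelihood: SelectionLikelihood, s: float,
                       mask: np.ndarray | None):
    """(P(i), joint P(a,i)) conditioned on a site being retained."""
    phi = likelihood.phi0(s)
    cond = likelihood.conditional_ages(s)
    if mask is not None:
        phi = np.where(mask, phi, 0.0)
    tot = phi.sum()
    pi = phi / tot
    joint = cond * pi[None, :]
    return pi, joint


def fisher_information(likelihood: SelectionLikelihood, gamma: float,
                       maf_min: float = 0.0, rel_step: float = 1e-3,
                       max_halvings: int = 6) -> InformationSummary:
    """Per-site Fisher information about gamma by central finite differences.

    ``I_freq`` uses the segregation-conditioned frequency probabilities
    P(i); ``I_freq_age`` uses the joint P(a, i) = P(a|i) P(i).  The
    derivative step is ``rel_step * max(1, |gamma|)`` on the gamma scale,
    halved (up to ``max_halvings`` times) if the result is not finite.
    Cells whose probability underflows to zero at any of the three
    evaluation points are excluded; their weight is negligible by
    construction.
    """
    if likelihood.s_resolution:
        # finite differences need exact off-center evaluations, not
        # cache-quantized ones
        likelihood = SelectionLikelihood(likelihood.template)
    N0 = float(likelihood.template.N[0])
    K = likelihood.template.K
    mask = _retained_mask(K, maf_min)
    step = rel_step * max(1.0, abs(gamma))
    for _ in range(max_halvings + 1):
        gs = (gamma - step, gamma, gamma + step)
        try:
            pis, joints = zip(*(_segregation_probs(likelihood, g / (2 * N0), mask)
                                for g in gs))
        except Exception:
            step /= 2
            continue
        ok_i = (pis[0] > 0) & (pis[1] > 0) & (pis[2] > 0)
        d_i = (np.log(pis[2][ok_i]) - np.log(pis[0][ok_i])) / (2 * step)
        I_freq = float(np.sum(d_i ** 2 * pis[1][ok_i]))
        ok_j = (joints[0] > 0) & (joints[1] > 0) & (joints[2] > 0)
        d_j = (np.log(joints[2][ok_j]) - np.log(joints[0][ok_j])) / (2 * step)
        I_ja = float(np.sum(d_j ** 2 * joints[1][ok_j]))
        if np.isfinite(I_freq) and np.isfinite(I_ja) and I_freq > 0:
            return InformationSummary(gamma=gamma, I_freq=I_freq,
                                      I_freq_age=I_ja, step_gamma=step,
                                      maf_min=maf_min)
        step /= 2
    raise ValidationError("finite-difference Fisher information did not stabilize")


def variance_ratio(estimates_freq, estimates_freq_age) -> float:
    """Ratio of sample variances Var(freq-only) / Var(freq+age) across
    replicate estimates (denominator n-1)."""
    a = np.asarray(estimates_freq, dtype=float)
    b = np.asarray(estimates_freq_age, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValidationError("need two equal-length lists of >= 2 estimates")
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValidationError("zero variance in freq+age estimates")
    return float(a.var(ddof=1) / vb)
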