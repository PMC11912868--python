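"""Probability distributions on allele age.

The age of a segregating variant is the number of generations before the
present at which it arose, a = 1..Tmax.  A mutation injected during the
update producing the spectrum at generation t-1 has age a = t (age 0 does
not exist).

Three routes are implemented:

* :func:`age_density_backward` — the reference algorithm: a backward pass
  propagating the destiny profile of the focal frequency class (the exact
  algebraic adjoint of the forward update), peeling off at each generation
  the expected number of mutations of that age destined for count i.
* :func:`age_density_equilibrium` — shortcut for constant histories: the
  backward pass uses a single operator and the steady-state spectrum, which
  is valid by reversibility of the dynamics with respect to their fixed
  point.
* :func:`joint_age_frequency` — an all-frequencies algorithm: the expected
  number m[a][i] of present-day sites at count i that arose in generation a
  is obtained for every (a, i) at once by propagating origin-generation
  cohorts forward in time.  Columns of the result reproduce the backward
  algorithm; rows sum (over a) to the present-day spectrum to near machine
  precision, because the adjoint accounting is exact.

Cohort identity used throughout: with A_t = I + Xi_t, the cohort that arose
in generation a contributes ``m_a = A_1 A_2 ... A_{a-1} (K mu_a delta_1)``
to the present-day spectrum, and ``sum_a m_a = Phi^0`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistoryError, ValidationError
from .popmodel import PopulationModel
from .sfs_dynamics import (
    SFSTrajectory,
    build_transition_operator,
    equilibrium_sfs,
    evolve_sfs,
)

__all__ = [
    "AgeDensity",
    "JointAgeFrequency",
    "age_density_backward",
    "age_density_equilibrium",
    "joint_age_frequency",
    "unconditional_age_density",
]

_NORM_TOL = 1e-8


@dataclass
class AgeDensity:
    """Normalized probability vector over ages a = 1..Tmax.

    ``i`` is the conditioning sample count, or None for an unconditional
    density.  ``p[a-1]`` is the probability the allele arose a generations
    before present.
    """

    p: np.ndarray
    n: int
    i: int | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        total = self.p.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValidationError("age density has no mass")
        if abs(total - 1.0) > _NORM_TOL:
            raise ValidationError(f"age density normalization off by {total - 1.0:.3e}")
        if self.p.min() < 0:
            raise ValidationError("age density has negative entries")

    @property
    def Tmax(self) -> int:
        return len(self.p)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(1, self.Tmax + 1)

    def mean(self) -> float:
        return float(self.ages @ self.p)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.p)


def _normalize(m: np.ndarray, **meta) -> AgeDensity:
    # roundoff-scale negatives are clipped; anything worse is caught by
    # AgeDensity validation
    if m.min() < 0 and m.min() >= -1e-12 * max(m.max(), 1e-300):
        m = np.clip(m, 0.0, None)
    return AgeDensity(p=m / m.sum(), **meta)


@dataclass
class JointAgeFrequency:
    """Expected counts m[a][i]: sites at present-day count i that arose in
    generation a.  Shape (Tmax, 2n-1); axis 0 is age a = 1..Tmax."""

    m: np.ndarray
    n: int
    gamma: float | None = None

    @property
    def Tmax(self) -> int:
        return self.m.shape[0]

    @property
    def phi0(self) -> np.ndarray:
        """Present-day expected SFS, the column sums of m."""
        return self.m.sum(axis=0)

    def conditional(self, i: int) -> AgeDensity:
        """Age density conditional on present-day sample count i."""
        _check_i(i, self.m.shape[1] + 1)
        return _normalize(self.m[:, i - 1], n=self.n, i=i, gamma=self.gamma)

    def conditional_matrix(self) -> np.ndarray:
        """P(a | i) for all i as a (Tmax, 2n-1) column-stochastic array.

        Frequency classes whose expected counts underflowed to zero (deeply
        suppressed bins under strong selection) yield all-zero columns.
        """
        cols = self.m.sum(axis=0)
        return self.m / np.where(cols > 0, cols, 1.0)


def _check_i(i: int, K: int) -> None:
    if not (1 <= i <= K - 1):
        raise ValidationError(f"sample count i={i} out of range 1..{K - 1}")


def age_density_backward(i: int, model: PopulationModel,
                         trajectory: SFSTrajectory | None = None) -> AgeDensity:
    """Age density conditional on sample count i, by the backward algorithm.

    The backward pass tracks the *destiny profile* q_t[j]: the weight with
    which unit expected mass at count j, t generations ago, contributes to
    the present-day expected count at the focal frequency i.  It satisfies
    q_0 = e_i and q_t = A_t^T q_{t-1} with A_t = I + Xi_t (the transpose of
    the one-generation forward update), so the expected number of age-t
    mutations found at count i today is ``m_t[i] = K mu_t q_{t-1}[1]`` — the
    injected singletons times the destiny of a singleton of that vintage.
    Because transpose propagation is the exact algebraic adjoint of the
    forward update, sum_t m_t[i] equals Phi^0[i] to machine precision, and
    the recursion is unconditionally stable (unlike a pullback by inverse
    solves, whose stiff modes amplify roundoff exponentially in t).
    """
    K = model.K
    _check_i(i, K)
    if trajectory is None:
        trajectory = evolve_sfs(model)
    if trajectory.phi0[i - 1] <= 0:
        raise ValidationError(f"present-day expected count at i={i} is zero; "
                              "no mutations to condition on")
    if not np.any(model.mu[1:] > 0):
        raise DegenerateHistoryError("history injects no mutations; ages are undefined")
    m = np.zeros(model.Tmax)
    q = np.zeros(K - 1)
    q[i - 1] = 1.0
    for t, op in _operators_for_backward(model):
        m[t - 1] = K * model.mu[t] * q[0]
        if t < model.Tmax:
            q = op.step_matrix.T @ q
    return _normalize(m, n=model.n, i=i,
                      gamma=float(model.gamma[1]) if model.is_constant() else None)


def _operators_for_backward(model: PopulationModel):
    """(t, operator) for t = 1..Tmax, rebuilding only on parameter change."""
    op = None
    for t in range(1, model.Tmax + 1):
        if op is None or op.N != model.N[t] or op.s != model.s[t]:
            op = build_transition_operator(model.n, model.N[t], model.s[t])
        yield t, op


def age_density_equilibrium(i: int, n: int, N: float, s: float, mu: float,
                            Tmax: int) -> AgeDensity:
    """Equilibrium shortcut: valid only for constant N, s, mu.

    Uses the steady-state spectrum (obtained by a direct fixed-point solve of
    the forward recursion) and a single backward pass with one operator.
    """
    K = 2 * n
    _check_i(i, K)
    if mu <= 0:
        raise ValidationError("equilibrium age density requires mu > 0")
    op = build_transition_operator(n, N, s)
    phi = equilibrium_sfs(n, N, s, mu)
    if phi[i - 1] <= 0:
        raise ValidationError(f"equilibrium expected count at i={i} is zero")
    stepT = op.step_matrix.T
    q = np.zeros(K - 1)
    q[i - 1] = 1.0
    m = np.empty(Tmax)
    for a in range(1, Tmax + 1):
        m[a - 1] = K * mu * q[0]
        if a < Tmax:
            q = stepT @ q
    return _normalize(m, n=n, i=i, gamma=2.0 * N * s)


def joint_age_frequency(model: PopulationModel) -> JointAgeFrequency:
    """Expected joint (age, frequency) counts m[a][i] for all a and i.

    Constant histories use the single-cohort recurrence
    ``m_{a+1} = (I + Xi) m_a`` starting from the injected singleton mass.
    General histories propagate the full set of origin-generation cohorts in
    one forward sweep (one banded-times-dense product per generation).
    """
    K = model.K
    Tmax = model.Tmax
    m = np.empty((Tmax, K - 1))
    if model.is_constant():
        op = build_transition_operator(model.n, model.N[1], model.s[1])
        step = op.step_matrix
        v = np.zeros(K - 1)
        v[0] = K * model.mu[1]
        m[0] = v
        for a in range(1, Tmax):
            v = step @ v
            m[a] = v
    else:
        # m_a[i] = K mu_a [A_1 ... A_{a-1}]_{i,1}; propagate the transposed
        # product V_a = A_{a-1}^T ... A_1^T, whose first row gives all i.
        V = np.eye(K - 1)
        for t, op in _operators_for_backward(model):
            m[t - 1] = K * model.mu[t] * V[0]
            if t < Tmax:
                V = op.step_matrix.T @ V
    np.clip(m, 0.0, None, out=m)
    return JointAgeFrequency(m=m, n=model.n,
                             gamma=float(model.gamma[1]) if model.is_constant() else None)


def unconditional_age_density(source: JointAgeFrequency | PopulationModel,
                              weighting: str = "frequency") -> AgeDensity:
    """Age density of a segregating site, marginalized over sample count.

    ``weighting="frequency"`` (default) weights each count class by its
    share of segregating sites: p(a) proportional to sum_i m[a][i].  This is
    the age distribution of a site drawn at random from the segregating
    sites, and the quantity a forward simulation of ages reproduces.
    ``weighting="uniform"`` instead averages the normalized conditional
    densities with equal weight per count class.

    Given a :class:`PopulationModel` (frequency weighting only), the
    marginal is computed directly by propagating the all-ones destiny vector
    backward — O(Tmax) work with no joint matrix.
    """
    if isinstance(source, PopulationModel):
        if weighting != "frequency":
            raise ValidationError("direct marginal computation supports only "
                                  "weighting='frequency'; build the joint matrix instead")
        model = source
        m = np.zeros(model.Tmax)
        q = np.ones(model.K - 1)
        for t, op in _operators_for_backward(model):
            m[t - 1] = model.K * model.mu[t] * q[0]
            if t < model.Tmax:
                q = op.step_matrix.T @ q
        gam = float(model.gamma[1]) if model.is_constant() else None
        return _normalize(m, n=model.n, i=None, gamma=gam)
    joint = source
    if weighting == "frequency":
        tot = joint.m.sum(axis=1)
    elif weighting == "uniform":
        tot = joint.conditional_matrix().sum(axis=1)
    else:
        raise ValidationError("weighting must be 'frequency' or 'uniform'")
    return _normalize(tot, n=joint.n, i=None, gamma=joint.gamma)
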