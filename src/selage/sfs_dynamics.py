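"""Single-generation transition operator for the expected SFS and the
forward recursion.

The expected sample frequency spectrum ``Phi[i]`` (i = 1..2n-1, the expected
number of segregating sites with derived count i in a sample of K = 2n
chromosomes) evolves one generation at a time as::

    Phi^{t-1} = (I + Xi_t) Phi^t + K * mu_t * delta_1

``Xi_t`` combines genetic drift and additive selection in generation t:

* Drift follows from projecting the Wright-Fisher diffusion onto binomial
  sample moments; it is exactly tridiagonal with entries
  ``(i-1)(K-i+1)/(4N)``, ``-2 i (K-i)/(4N)``, ``(i+1)(K-i-1)/(4N)``.
  Its fixed point under singleton injection is the neutral theta/i spectrum
  (exactly, at any K).
* Selection couples the size-K spectrum to the size-(K+1) spectrum; the
  hierarchy is closed with an order-3 jackknife that estimates the (K+1)
  spectrum from the K spectrum by locally fitting a quadratic density of
  population frequencies.

Convention: ``s`` is the selection coefficient per derived-allele copy
(h = 1/2: genotype fitnesses 1, 1+s, 1+2s), so the deterministic change per
generation is ``dx = s x (1-x)`` and the stationary density of segregating
sites is proportional to ``(1 - exp(-2*gamma*(1-x))) / (x (1-x))`` with
``gamma = 2 N s``.  The forward simulator uses the identical convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .errors import StabilityError, ValidationError
from .popmodel import PopulationModel

__all__ = [
    "jackknife_matrix",
    "drift_matrix",
    "selection_matrix",
    "build_transition_operator",
    "TransitionOperator",
    "step_forward",
    "evolve_sfs",
    "equilibrium_sfs",
    "SFSTrajectory",
]

#: entries of (I+Xi)Phi more negative than -NEG_TOL * max(Phi) raise
NEG_TOL = 1e-12


@lru_cache(maxsize=64)
def jackknife_matrix(K: int) -> np.ndarray:
    """Order-3 jackknife: (K, K-1) matrix J with ``Phi_{K+1} ~= J @ Phi_K``.

    Assumes the density rho(x) of population frequencies underlying the
    sample spectrum is locally quadratic.  Using
    ``Phi_K[j] = C(K,j) * int x^j (1-x)^{K-j} rho(x) dx`` and exact beta
    integrals, a quadratic rho contributes moments

        g_K(j, c) = prod_{r=1..c} (j+r) / prod_{r=1..c+1} (K+r),   c = 0,1,2

    so three consecutive entries of Phi_K determine the local quadratic and
    hence any entry of Phi_{K+1}.  The stencil for target entry i is centred
    at ``round(i*K/(K+1))``, clipped to stay interior.
    """
    if K < 4:
        raise ValidationError("jackknife closure requires at least 4 sampled chromosomes")

    def g(m: int, j: np.ndarray, c: int) -> np.ndarray:
        num = np.ones_like(j, dtype=float)
        for r in range(1, c + 1):
            num = num * (j + r)
        den = 1.0
        for r in range(1, c + 2):
            den = den * (m + r)
        return num / den

    J = np.zeros((K, K - 1))
    for i in range(1, K + 1):
        j0 = int(np.clip(np.rint(i * K / (K + 1.0)), 2, K - 2))
        js = np.array([j0 - 1, j0, j0 + 1], dtype=float)
        M = np.column_stack([g(K, js, c) for c in range(3)])
        target = np.array([g(K + 1, np.array([float(i)]), c)[0] for c in range(3)])
        # stencil weights y solve M^T y = target, so that y . Phi_stencil
        # reproduces Phi_{K+1}[i] exactly for any quadratic density
        J[i - 1, j0 - 2 : j0 + 1] = np.linalg.solve(M.T, target)
    return J


def drift_matrix(K: int, N: float) -> np.ndarray:
    """Tridiagonal drift generator (per generation) on the (K-1)-vector."""
    i = np.arange(1, K)
    D = np.zeros((K - 1, K - 1))
    D[np.arange(K - 1), np.arange(K - 1)] = -2.0 * i * (K - i)
    sub = (i[1:] - 1) * (K - i[1:] + 1)  # into bin i from i-1
    sup = (i[:-1] + 1) * (K - i[:-1] - 1)  # into bin i from i+1
    D[np.arange(1, K - 1), np.arange(K - 2)] = sub
    D[np.arange(K - 2), np.arange(1, K - 1)] = sup
    return D / (4.0 * N)


@lru_cache(maxsize=64)
def selection_matrix(K: int) -> np.ndarray:
    """Per-unit-s selection operator (K-1, K-1), jackknife closed.

    Projection of ``-d/dx [ x(1-x) rho ]`` onto sample moments couples bin i
    of the size-K spectrum to bins i and i+1 of the size-(K+1) spectrum::

        (dPhi_K[i]/dt)_sel = s * [ i(K+1-i) Phi_{K+1}[i]
                                   - (i+1)(K-i) Phi_{K+1}[i+1] ] / (K+1)

    The returned matrix is this bilinear form composed with the jackknife.
    """
    J = jackknife_matrix(K)
    i = np.arange(1, K)
    S = np.zeros((K - 1, K))
    S[np.arange(K - 1), np.arange(K - 1)] = i * (K + 1 - i) / (K + 1.0)
    S[np.arange(K - 1), np.arange(1, K)] = -(i + 1) * (K - i) / (K + 1.0)
    return S @ J


@dataclass
class TransitionOperator:
    """One-generation operator ``Xi`` for given (K, N, s).

    ``matrix`` holds Xi itself (dense, near-tridiagonal: the drift part is
    exactly tridiagonal, the jackknife-closed selection part has bandwidth
    <= 3).  ``step_matrix`` is I + Xi.  An LU factorization of I + Xi is
    computed lazily for the backward (inverse) iteration.
    """

    K: int
    N: float
    s: float
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self._lu = None

    @property
    def step_matrix(self) -> np.ndarray:
        return np.eye(self.K - 1) + self.matrix

    def apply(self, phi: np.ndarray) -> np.ndarray:
        """(I + Xi) @ phi."""
        return phi + self.matrix @ phi

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve (I + Xi) x = rhs (the exact inverse of :meth:`apply`)."""
        if self._lu is None:
            self._lu = lu_factor(self.step_matrix)
        return lu_solve(self._lu, rhs)

    def diagonals(self) -> dict[int, np.ndarray]:
        """Nonzero diagonals of Xi keyed by offset (0 = main)."""
        out = {}
        for off in range(-(self.K - 2), self.K - 1):
            d = np.diagonal(self.matrix, off)
            if np.any(d != 0.0):
                out[off] = d.copy()
        return out


def build_transition_operator(n: int, N: float, s: float) -> TransitionOperator:
    """Build Xi for a diploid sample of size n in a population of diploid
    size N with additive selection coefficient s (per derived copy).

    Warns when |gamma| = |2 N s| is large relative to the sample size: the
    jackknife closure degrades once the frequency scale 1/(2|gamma|) falls
    below the sample resolution 1/(2n) by a wide margin.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if N <= 0:
        raise ValidationError("N must be positive")
    K = 2 * int(n)
    if K * (K - 1) >= 8.0 * N:
        warnings.warn(
            f"sample size 2n={K} exceeds sqrt(8N)={np.sqrt(8 * N):.0f}: the "
            "stiffest drift mode makes the explicit one-generation update "
            "unstable; increase N or decrease n",
            RuntimeWarning,
            stacklevel=2,
        )
    gamma = 2.0 * N * s
    if abs(gamma) > 2 * K:
        warnings.warn(
            f"|2Ns| = {abs(gamma):.3g} exceeds twice the sample size K={K}; "
            "the jackknife moment closure may be inaccurate or unstable "
            "(watch for negative expected counts)",
            RuntimeWarning,
            stacklevel=2,
        )
    Xi = drift_matrix(K, N)
    if s != 0.0 and K >= 4:
        Xi = Xi + s * selection_matrix(K)
    elif s != 0.0:
        raise ValidationError("selection requires a sample of at least 4 chromosomes (n >= 2)")
    return TransitionOperator(K=K, N=float(N), s=float(s), matrix=Xi)


def _check_nonnegative(phi: np.ndarray, where: str) -> np.ndarray:
    neg = phi < 0.0
    if not np.any(neg):
        return phi
    scale = max(phi.max(initial=0.0), -phi.min())
    worst = phi.min()
    if -worst <= NEG_TOL * max(scale, 1e-300):
        phi = phi.copy()
        phi[neg] = 0.0
        return phi
    bin_ = int(np.argmin(phi)) + 1
    raise StabilityError(
        f"negative expected count {worst:.3e} in bin i={bin_} during {where}; "
        "the moment closure has broken down for these parameters"
    )


def step_forward(phi: np.ndarray, op: TransitionOperator, mu_t: float) -> np.ndarray:
    """One generation forward: ``(I + Xi) phi + K mu_t delta_1``.

    Mass leaves through the singleton and (2n-1)-ton boundaries (loss and
    fixation); new mutations inject ``K mu_t`` expected singletons.
    """
    if mu_t < 0:
        raise ValidationError("mu_t must be nonnegative")
    out = op.apply(np.asarray(phi, dtype=float))
    out[0] += op.K * mu_t
    return _check_nonnegative(out, "forward step")


@dataclass
class SFSTrajectory:
    """Output of :func:`evolve_sfs`.

    ``phi0`` is the present-day expected SFS; ``singletons[t]`` records the
    expected singleton count of Phi^t for t = 0..Tmax (needed by the
    backward age recursion); ``spectra`` optionally retains every Phi^t.
    """

    phi0: np.ndarray
    singletons: np.ndarray
    spectra: list[np.ndarray] | None = None


def _operators_for(model: PopulationModel):
    """Yield (t, operator) for t = Tmax..1, rebuilding only on parameter
    change."""
    op = None
    for t in range(model.Tmax, 0, -1):
        if op is None or op.N != model.N[t] or op.s != model.s[t]:
            op = build_transition_operator(model.n, model.N[t], model.s[t])
        yield t, op


def evolve_sfs(model: PopulationModel, keep: str = "singletons") -> SFSTrajectory:
    """Iterate the forward recursion from Phi^Tmax = 0 down to Phi^0.

    ``keep="full"`` retains the whole trajectory of spectra (index t =
    0..Tmax); the default retains only the singleton series, which is all the
    backward age algorithm needs.
    """
    if keep not in ("singletons", "full"):
        raise ValidationError("keep must be 'singletons' or 'full'")
    K = model.K
    phi = np.zeros(K - 1)
    singles = np.zeros(model.Tmax + 1)
    spectra: list[np.ndarray] | None = None
    if keep == "full":
        spectra = [None] * (model.Tmax + 1)  # type: ignore[list-item]
        spectra[model.Tmax] = phi.copy()
    for t, op in _operators_for(model):
        phi = step_forward(phi, op, model.mu[t])
        singles[t - 1] = phi[0]
        if spectra is not None:
            spectra[t - 1] = phi.copy()
    return SFSTrajectory(phi0=phi, singletons=singles, spectra=spectra)


def equilibrium_sfs(n: int, N: float, s: float, mu: float) -> np.ndarray:
    """Fixed point of the forward recursion for constant parameters.

    Solves ``-Xi Phi = K mu delta_1`` directly; for s = 0 this is the
    classical neutral spectrum theta/i with theta = 4 N mu (exact at any K).
    """
    op = build_transition_operator(n, N, s)
    rhs = np.zeros(op.K - 1)
    rhs[0] = op.K * mu
    phi = np.linalg.solve(-op.matrix, rhs)
    return _check_nonnegative(phi, "equilibrium solve")
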