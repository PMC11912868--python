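"""Neutral-resampling approximation of the selected age distribution, and
divergence diagnostics (base-10 Kullback-Leibler, total variation).

The neutral-resampling approximation imagines drawing (frequency, age)
pairs for neutral sites and retaining each with probability proportional to
``w_i = P(i | gamma, n) / P(i | gamma=0, n)`` — the ratio of the selected
and neutral sample frequency spectra, each conditioned on segregation.  The
implied age distribution is the w-weighted mixture of the *neutral*
conditional age densities.  For negative selection this closely matches the
true age distribution (high-frequency classes, whose conditional ages are
distorted by selection, are suppressed); for positive selection it fails
badly, because selection amplifies exactly those classes.

All divergences are computed on a shared discrete age grid a = 1..Tmax, so
no interpolation is ever involved, and the mutation rate cancels (both
spectra are linear in mu), so only segregation-conditioned distributions
enter.
"""

from __future__ import annotations

import numpy as np

from .age_distribution import AgeDensity, JointAgeFrequency, _normalize
from .errors import ValidationError

__all__ = [
    "resampling_weights",
    "neutral_resampling_age_density",
    "kl_divergence_base10",
    "total_variation",
    "resampling_comparison",
    "critical_gamma",
    "small_sample_maf",
]


def critical_gamma(x_star: float) -> float:
    """Critical scaled selection strength implied by a MAF cutoff.

    The stationary spectrum of a deleterious allele tracks the neutral one
    below the population frequency 1/(2|gamma|) and is suppressed above it,
    so a sample thresholded at minor allele frequency ``x_star`` becomes
    sensitive to ages exactly when |gamma| exceeds ``1 / (2 x_star)``.
    """
    if not (0 < x_star < 0.5):
        raise ValidationError("x_star must lie in (0, 0.5)")
    return 1.0 / (2.0 * x_star)


def small_sample_maf(n: int) -> float:
    """Effective MAF cutoff of an unthresholded sample of n diploids.

    Observing even a singleton requires sample frequency 1/(2n), so a full
    small sample behaves like a large sample thresholded at
    ``x_star = 1/(2n)`` — and its critical |gamma| is therefore n.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    return 1.0 / (2.0 * n)

#: floor applied inside logs only, never added as mass
_LOG_FLOOR = 1e-300


def resampling_weights(phi_selected: np.ndarray, phi_neutral: np.ndarray) -> np.ndarray:
    """Per-frequency resampling weights w_i = P(i|gamma,n) / P(i|0,n).

    Both spectra are normalized over segregating bins before the ratio is
    taken, so the overall mutation rate cancels.  The two spectra must share
    the sample size (equal length) and, for the approximation to be
    meaningful, the demography.
    """
    ps = np.asarray(phi_selected, dtype=float)
    pn = np.asarray(phi_neutral, dtype=float)
    if ps.shape != pn.shape:
        raise ValidationError("selected and neutral spectra must share the sample size")
    if np.any(pn <= 0):
        raise ValidationError("neutral spectrum has empty bins; weight ratio undefined")
    if np.any(ps < 0):
        raise ValidationError("selected spectrum has negative entries")
    return (ps / ps.sum()) / (pn / pn.sum())


def neutral_resampling_age_density(weights: np.ndarray,
                                   neutral_conditional_ages: np.ndarray,
                                   n: int | None = None,
                                   gamma: float | None = None) -> AgeDensity:
    """Weighted mixture of neutral conditional age densities.

    ``neutral_conditional_ages`` is the (Tmax, 2n-1) column-stochastic array
    of neutral age densities conditional on each sample count (e.g. from
    ``JointAgeFrequency.conditional_matrix()``).  The mixture
    ``C^{-1} sum_i w_i P(a | i, gamma=0)`` with ``C = sum_i w_i`` is the age
    distribution implied by the resampling procedure; at gamma = 0 all
    weights are 1 and it collapses to the neutral unconditional density.
    """
    w = np.asarray(weights, dtype=float)
    P0 = np.asarray(neutral_conditional_ages, dtype=float)
    if P0.ndim != 2 or P0.shape[1] != w.shape[0]:
        raise ValidationError("weights and conditional-age matrix have mismatched "
                              f"shapes {w.shape} vs {P0.shape}")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    mix = P0 @ w
    if n is None:
        n = (w.shape[0] + 1) // 2
    return _normalize(mix, n=n, i=None, gamma=gamma)


def _as_prob(p) -> np.ndarray:
    arr = p.p if isinstance(p, AgeDensity) else np.asarray(p, dtype=float)
    return arr


def kl_divergence_base10(p, q) -> float:
    """Base-10 KL divergence ``sum_a p_a log10(p_a / q_a)``.

    A value of k means the data are 10^k times more likely per site under p
    than under q.  Terms with p_a = 0 contribute 0; any age with p_a > 0 but
    q_a = 0 makes the divergence infinite (returned as ``inf``, not raised).
    Probabilities that are positive but denormal are floored at 1e-300
    inside the logarithm only; no pseudo-mass is ever added.
    """
    pa, qa = _as_prob(p), _as_prob(q)
    if pa.shape != qa.shape:
        raise ValidationError("distributions must share the age grid")
    mask = pa > 0
    if np.any(qa[mask] == 0.0):
        return float("inf")
    pm = pa[mask]
    qm = np.maximum(qa[mask], _LOG_FLOOR)
    return float(np.sum(pm * (np.log10(np.maximum(pm, _LOG_FLOOR)) - np.log10(qm))))


def total_variation(p, q) -> float:
    """Total variation distance, half the l1 norm; bounded in [0, 1]."""
    pa, qa = _as_prob(p), _as_prob(q)
    if pa.shape != qa.shape:
        raise ValidationError("distributions must share the age grid")
    return float(0.5 * np.abs(pa - qa).sum())


def resampling_comparison(joint_selected: JointAgeFrequency,
                          joint_neutral: JointAgeFrequency) -> dict:
    """Exact vs neutral-resampling unconditional age distributions, with
    divergences.

    The exact density pools the normalized conditional age densities with
    equal weight per frequency class; the approximation pools the *neutral*
    conditionals with the resampling-ratio weights w_i (the two coincide
    when gamma = 0).  The KL divergence is evaluated with the resampling
    approximation as the sampling distribution,
    ``sum_a q(a) log10(q(a)/p(a))``: it measures how strongly ages drawn
    under the resampling picture are contradicted by the exact model, and it
    is the variant whose growth is dominated by the approximation's excess
    old-age mass (the regime in which the approximation fails).

    Returns a dict with keys ``exact`` and ``approx`` (AgeDensity),
    ``kl`` (base-10) and ``tv``.
    """
    if joint_selected.m.shape != joint_neutral.m.shape:
        raise ValidationError("joint matrices must share sample size and Tmax")
    w = resampling_weights(joint_selected.phi0, joint_neutral.phi0)
    Pn = joint_neutral.conditional_matrix()
    approx = neutral_resampling_age_density(w, Pn, n=joint_selected.n,
                                            gamma=joint_selected.gamma)
    # equal-class-weight pooling of the selected conditionals; frequency
    # classes whose expected counts underflowed to zero carry no information
    Ps = joint_selected.m / np.where(joint_selected.phi0 > 0,
                                     joint_selected.phi0, 1.0)
    exact = _normalize(Ps.sum(axis=1), n=joint_selected.n, i=None,
                       gamma=joint_selected.gamma)
    return {
        "exact": exact,
        "approx": approx,
        "kl": kl_divergence_base10(approx, exact),
        "tv": total_variation(approx, exact),
    }
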