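"""Demographic, selection and mutation histories on a per-generation grid.

A model is specified as a list of epochs (most ancient first).  Each epoch has
a duration in generations, start/end diploid population sizes (interpolated
geometrically for exponential epochs), a per-site additive selection
coefficient ``s`` (h = 1/2; the scaled strength is ``gamma = 2*N*s``) and a
total mutation rate ``mu`` per generation across the site class.

Time is indexed by ``t`` counting down to 0 at the present: arrays ``N[t]``,
``s[t]``, ``mu[t]`` run from t = 0 (present) to t = Tmax (most ancient).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "EpochSpec",
    "PopulationModel",
    "expand_model",
    "default_tmax",
    "constant_model",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class EpochSpec:
    """One epoch of a piecewise demographic history.

    Parameters
    ----------
    duration
        Length of the epoch in generations (>= 1).
    N_start, N_end
        Diploid population size at the ancient and recent ends of the epoch.
        ``mode="constant"`` requires them to be equal; ``mode="exponential"``
        interpolates geometrically between them.
    s
        Additive selection coefficient of the derived allele per copy
        (heterozygote advantage s, homozygote 2s, i.e. h = 1/2).
    mu
        Total mutation rate across the site class, per generation.
    """

    duration: int
    N_start: float
    N_end: float
    mode: str = "constant"
    s: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if int(self.duration) != self.duration or self.duration < 1:
            raise ValidationError(f"epoch duration must be a positive integer, got {self.duration}")
        if self.N_start <= 0 or self.N_end <= 0:
            raise ValidationError("population sizes must be positive")
        if self.mode not in ("constant", "exponential"):
            raise ValidationError(f"unknown epoch mode {self.mode!r}")
        if self.mode == "constant" and self.N_start != self.N_end:
            raise ValidationError("constant epochs require N_start == N_end")
        if self.mu < 0:
            raise ValidationError("mutation rate must be nonnegative")


@dataclass
class PopulationModel:
    """Per-generation arrays of population size, selection and mutation.

    ``N``, ``s`` and ``mu`` have length ``Tmax + 1`` and are indexed by
    generations before present (0 = present).  The scaled selection
    coefficient ``gamma[t] = 2 N[t] s[t]`` is derived, not stored.
    """

    n: int
    N: np.ndarray
    s: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if int(self.n) != self.n or self.n < 1:
            raise ValidationError(f"sample size n must be a positive integer, got {self.n}")
        self.n = int(self.n)
        if not (len(self.N) == len(self.s) == len(self.mu)):
            raise ValidationError("N, s, mu arrays must have equal length Tmax+1")
        if len(self.N) < 2:
            raise ValidationError("model must span at least one generation")
        if np.any(self.N <= 0):
            raise ValidationError("all N[t] must be positive")
        if np.any(self.mu < 0):
            raise ValidationError("all mu[t] must be nonnegative")

    @property
    def Tmax(self) -> int:
        return len(self.N) - 1

    @property
    def K(self) -> int:
        """Number of sampled chromosomes, 2n."""
        return 2 * self.n

    @property
    def gamma(self) -> np.ndarray:
        """Scaled selection coefficient 2*N[t]*s[t] per generation."""
        return 2.0 * self.N * self.s

    def is_constant(self) -> bool:
        """True if N, s and mu are constant over the generations actually
        stepped through (t = 1..Tmax)."""
        return bool(
            np.all(self.N[1:] == self.N[1])
            and np.all(self.s[1:] == self.s[1])
            and np.all(self.mu[1:] == self.mu[1])
        )

    def with_selection(self, s: float) -> "PopulationModel":
        """Copy of the model with a single selection coefficient everywhere."""
        return replace(self, s=np.full_like(self.s, float(s)))

    def with_mu_scaled(self, factor: float) -> "PopulationModel":
        return replace(self, mu=self.mu * float(factor))


def expand_model(epochs: list[EpochSpec], n: int) -> PopulationModel:
    """Expand an epoch specification (most ancient first) into per-generation
    arrays.

    Exponential epochs interpolate N geometrically: an epoch of duration d
    from ``N_start`` to ``N_end`` assigns ``N_start * (N_end/N_start)**(k/d)``
    at the k-th generation step into the epoch.  The most ancient grid point
    (t = Tmax) carries the first epoch's ``N_start``; each epoch's recent
    boundary carries its ``N_end`` exactly.
    """
    if not epochs:
        raise ValidationError("epochs must be nonempty")
    durations = [int(e.duration) for e in epochs]
    Tmax = int(sum(durations))
    N = np.empty(Tmax + 1)
    s = np.empty(Tmax + 1)
    mu = np.empty(Tmax + 1)
    # boundaries B_0=Tmax > B_1 > ... > B_E=0, epoch e covers (B_e .. B_{e-1}]
    B = [Tmax]
    for d in durations:
        B.append(B[-1] - d)
    for e, ep in enumerate(epochs):
        hi, lo, d = B[e], B[e + 1], durations[e]
        # epoch 0 additionally owns the ancient grid point t = Tmax
        t_top = hi if e == 0 else hi - 1
        ts = np.arange(lo, t_top + 1)
        if ep.mode == "exponential":
            frac = (hi - ts) / d
            N[ts] = ep.N_start * (ep.N_end / ep.N_start) ** frac
        else:
            N[ts] = ep.N_start
        s[ts] = ep.s
        mu[ts] = ep.mu
    return PopulationModel(n=n, N=N, s=s, mu=mu)


def default_tmax(epochs: list[EpochSpec] | None = None, *, N: float | None = None,
                 tolerance: float = 1e-4) -> int:
    """Horizon in generations beyond which surviving mutations are negligible.

    With an epoch list, the model's own total duration is the horizon.  With a
    (constant, ancestral) population size ``N``, the conservative rule
    ``10 * N`` is used: a neutral allele still segregating after 10 N
    generations is vanishingly improbable.
    """
    if not (0 < tolerance < 1):
        raise ValidationError("tolerance must be in (0, 1)")
    if epochs:
        return int(sum(int(e.duration) for e in epochs))
    if N is None:
        raise ValidationError("provide either epochs or a population size N")
    if N <= 0:
        raise ValidationError("N must be positive")
    return int(np.ceil(10 * N))


def constant_model(n: int, N: float, s: float = 0.0, mu: float = 1.0,
                   Tmax: int | None = None) -> PopulationModel:
    """Convenience constructor for a constant-size, constant-selection model.

    ``Tmax`` defaults to 10*N generations, long enough to reach approximate
    equilibrium of the expected spectrum from an empty start.
    """
    if Tmax is None:
        Tmax = default_tmax(N=N)
    return expand_model(
        [EpochSpec(duration=int(Tmax), N_start=N, N_end=N, mode="constant", s=s, mu=mu)], n=n
    )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def _epoch_from_dict(d: dict) -> EpochSpec:
    try:
        return EpochSpec(
            duration=int(d["duration"]),
            N_start=float(d["N_start"]),
            N_end=float(d.get("N_end", d["N_start"])),
            mode=str(d.get("mode", "constant")),
            s=float(d.get("s", 0.0)),
            mu=float(d.get("mu", 0.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"epoch config missing key {exc}") from exc


def load_config(path) -> PopulationModel:
    """Read a demography config (JSON or YAML) into a PopulationModel.

    Expected structure::

        {"sample_size_n": 100,
         "epochs": [{"duration": ..., "N_start": ..., "N_end": ...,
                     "mode": "constant"|"exponential", "s": ..., "mu": ...},
                    ...]}   # most ancient first
    """
    import yaml

    with open(path) as fh:
        text = fh.read()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"could not parse demography config {path}")
    try:
        n = int(cfg["sample_size_n"])
        epochs = [_epoch_from_dict(d) for d in cfg["epochs"]]
    except KeyError as exc:
        raise ValidationError(f"demography config missing key {exc}") from exc
    return expand_model(epochs, n=n)


def dump_config(epochs: list[EpochSpec], n: int, path) -> None:
    cfg = {
        "sample_size_n": int(n),
        "epochs": [
            {"duration": int(e.duration), "N_start": e.N_start, "N_end": e.N_end,
             "mode": e.mode, "s": e.s, "mu": e.mu}
            for e in epochs
        ],
    }
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=1)
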