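"""Exception types shared across the package.

``ValidationError`` maps to CLI exit code 2, ``StabilityError`` (and its
subclass ``DegenerateHistoryError``) to exit code 3.
"""


class ValidationError(ValueError):
    """Invalid user input: model parameters, site tables, or configuration."""


class StabilityError(RuntimeError):
    """Numerical breakdown of the moment recursion (e.g. the jackknife
    closure producing substantially negative expected counts)."""


class DegenerateHistoryError(StabilityError):
    """A history in which mutations are injected while the expected singleton
    count is zero, making the age accounting ill-defined."""
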