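"""Error families raised across the pipeline.

Each family maps to a distinct nonzero CLI exit code (see :mod:`dyadcausal.cli`).
"""


class DyadCausalError(Exception):
    """Base class for all package-specific errors."""


class StabilityError(DyadCausalError, ValueError):
    """A VAR specification is not stationary (companion spectral radius >= 1)."""

    def __init__(self, spectral_radius: float, message: str | None = None):
        self.spectral_radius = float(spectral_radius)
        super().__init__(
            message
            or f"VAR specification is unstable: companion spectral radius "
            f"{self.spectral_radius:.6f} >= 1"
        )


class DegenerateDataError(DyadCausalError, ValueError):
    """Zero-variance channel or vanishing regression residuals."""


class EmptyResultError(DyadCausalError, ValueError):
    """An operation that requires at least one matched/valid item found none."""


class TapParseError(DyadCausalError, ValueError):
    """A tap-train file line could not be parsed as a timestamp."""

    def __init__(self, path, lineno: int, line: str):
        self.path = str(path)
        self.lineno = int(lineno)
        super().__init__(f"{path}: line {lineno}: cannot parse tap time from {line!r}")
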