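"""Exception hierarchy shared across the package."""


class InterdigitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(InterdigitError, ValueError):
    """A numeric parameter violates its domain (non-positive dt, a=0, ...)."""


class StabilityError(InterdigitError, ValueError):
    """An explicit-Euler step size violates the stability bound."""


class ConfigurationError(InterdigitError, ValueError):
    """A configuration is internally inconsistent (unknown model, stable
    kinetics passed to a pattern-forming run, unknown config key, ...)."""


class FormatError(InterdigitError, ValueError):
    """An input file does not conform to the expected dialect."""


class OverhangError(InterdigitError, ValueError):
    """A boundary polyline is not a single-valued function of chord position."""

    def __init__(self, segment_id, message=None):
        self.segment_id = segment_id
        super().__init__(message or f"segment {segment_id!r} is overhung")


class DegenerateInputError(InterdigitError, ValueError):
    """Input is formally valid but the requested statistic is undefined on it
    (zero chord, flat profiles, identical samples, all-zero spectrum)."""
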