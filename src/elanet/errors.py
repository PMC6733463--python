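"""Exception types shared across the package."""


class ElanetError(Exception):
    """Base class for package-specific errors."""


class ValidationError(ElanetError, ValueError):
    """An input violates a documented precondition."""


class EnumerationLimitError(ElanetError, ValueError):
    """The system is too large for exact 2**N enumeration (N > 20)."""


class DegenerateMomentError(ElanetError, ValueError):
    """A target moment sits on the boundary of the feasible polytope."""


class UndefinedRatioError(ElanetError, ZeroDivisionError):
    """A fit-quality ratio has a vanishing denominator."""
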