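"""Exception hierarchy.

All package-specific failures derive from :class:`StericDsError` so callers can
catch one base class; subclasses are named for the contract they enforce.
"""


class StericDsError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(StericDsError):
    """A structure file violates its declared dialect (bad counts line,
    truncated atom/bond block, index out of range...)."""


class UnsupportedElementError(StericDsError):
    """An element symbol outside the supported set was encountered."""


class UnsupportedDialectError(ParseError):
    """The file is a recognizable format but an unsupported dialect
    (e.g. MOL V3000)."""


class ClashError(StericDsError):
    """Two atoms closer than the hard-sphere limit (0.4 A)."""


class UnparameterizedPatternError(StericDsError):
    """A bond/angle/torsion/element pattern has no entry in the parameter set.

    The offending pattern is stored in ``pattern``.
    """

    def __init__(self, pattern: str, message: str | None = None):
        self.pattern = pattern
        super().__init__(message or f"no parameters for pattern {pattern!r}")


class SingularGeometryError(StericDsError):
    """Coincident atoms (or otherwise singular geometry) in an energy call."""


class DivergenceError(StericDsError):
    """Non-finite energy encountered during minimization."""


class IntegrationBlowupError(StericDsError):
    """Non-finite forces or coordinates during dynamics; carries the step."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"dynamics blew up at step {step}")


class ComplexationFailureError(StericDsError):
    """Every sampled pose failed to produce a finite complex energy."""


class UndefinedIndexError(StericDsError):
    """Stability index undefined: |E_host + E_guest| is numerically zero."""


class CollinearityError(StericDsError):
    """Predictor matrix is numerically collinear; names offending columns."""

    def __init__(self, columns, message: str | None = None):
        self.columns = list(columns)
        super().__init__(
            message or f"collinear predictor columns: {', '.join(self.columns)}"
        )
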