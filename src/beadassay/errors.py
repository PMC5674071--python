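"""Exception types shared across the package.

Exit-code mapping used by the CLI: :class:`InputError` (and
:class:`ParameterError`) exit with status 1, :class:`CalibrationError`
with status 2.
"""


class BeadAssayError(Exception):
    """Base class for all package errors."""


class ParameterError(BeadAssayError, ValueError):
    """An argument is outside its documented domain."""


class InputError(BeadAssayError):
    """An input file is missing, malformed or of an unsupported kind."""


class CalibrationError(BeadAssayError):
    """Calibration could not satisfy its contract.

    ``best_mismatch`` carries the best achievable relative signal
    mismatch when signal-equivalence matching fails, else ``None``.
    """

    def __init__(self, message: str, best_mismatch: float | None = None):
        super().__init__(message)
        self.best_mismatch = best_mismatch
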