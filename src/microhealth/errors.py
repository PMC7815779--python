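"""Exception types shared across the package."""


class MicrohealthError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MicrohealthError):
    """A parameter file, covariate name or model block is invalid."""


class ValidationError(MicrohealthError):
    """Input data violate a structural invariant.

    Carries per-row diagnostics when the offending input is tabular.
    """

    def __init__(self, message: str, rows: list[str] | None = None):
        self.rows = rows or []
        if self.rows:
            message = message + "\n" + "\n".join(self.rows)
        super().__init__(message)
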