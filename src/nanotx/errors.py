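"""Exception types shared across the package."""


class NanotxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NanotxError):
    """Invalid parameter values or configuration documents.

    ``errors`` carries the full list of violations when a configuration
    document is validated, so callers see every problem at once.
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors) if errors else [str(message)]

    def __str__(self):
        base = super().__str__()
        if self.errors == [base]:
            return base
        return "\n".join([f"{base}:"] + [f"  - {e}" for e in self.errors])


class NumericalError(NanotxError):
    """NaN/negative concentrations or violated stability guards."""


class CellOutsideDomainError(NanotxError):
    """A cell center does not map to any voxel of the grid."""
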