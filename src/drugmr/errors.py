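"""Exception hierarchy shared across the package."""


class DrugMRError(Exception):
    """Base class for package errors."""


class ConfigError(DrugMRError):
    """A configuration problem: missing column, bad threshold, bad mapping."""


class DataError(DrugMRError):
    """Input data violates a contract (empty table, out-of-range value)."""


class FormatError(DrugMRError):
    """A file is structurally malformed (non-square LD block, bad header)."""


class InsufficientDataError(DrugMRError):
    """Too few SNPs/studies for the requested method.

    Carries ``n`` (what was available) and ``required`` so pipeline code can
    route to a fallback (e.g. the Egger-intercept test when MR-PRESSO needs
    more than 3 SNPs).
    """

    def __init__(self, message: str, n: int | None = None, required: int | None = None):
        super().__init__(message)
        self.n = n
        self.required = required


class StateError(DrugMRError):
    """An operation was applied in an invalid state (e.g. double orientation)."""
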