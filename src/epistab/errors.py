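"""Exception types shared across the pipeline stages."""


class EpistabError(Exception):
    """Base class for all package errors."""


class SchemaError(EpistabError):
    """A required column is absent or a column has unexpected levels."""


class ConfigurationError(EpistabError):
    """An invalid configuration value (distribution spec, sentinel clash)."""


class DegenerateDataError(EpistabError):
    """The data cannot support the requested fit (constant outcome, etc.)."""


class ConvergenceError(EpistabError):
    """An iterative fit failed to converge within its iteration budget."""


class SeparationError(ConvergenceError):
    """Perfect separation detected in a logistic fit."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"perfect separation detected for term {term!r}")
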