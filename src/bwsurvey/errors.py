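"""Exception hierarchy shared across the package."""


class BwsurveyError(Exception):
    """Base class for all package errors."""


class SchemaError(BwsurveyError):
    """A table violates its on-disk schema (bad header, duplicate ids, unknown tokens)."""


class ValidationError(BwsurveyError):
    """A value or record violates a domain invariant."""


class InfeasibleDesignError(BwsurveyError):
    """Requested block-design parameters admit no equal-replication design."""


class BalanceSearchError(BwsurveyError):
    """The design search exhausted its budget before reaching near-balance."""

    def __init__(self, message: str, best_objective: int, best_spread: int):
        super().__init__(message)
        self.best_objective = best_objective
        self.best_spread = best_spread


class ConsistencyError(BwsurveyError):
    """Two artifacts that must agree (catalog, design, responses) do not."""
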