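"""Exception hierarchy shared across the package."""


class SoilstoreError(Exception):
    """Base class for all package errors."""


class SchemaError(SoilstoreError):
    """A table is missing mandatory columns or has an unusable header."""


class ValidationError(SoilstoreError):
    """A value violates a domain invariant (e.g. negative concentration)."""


class EmptyDataError(SoilstoreError):
    """An operation was asked to summarise a field with no usable values."""


class DegenerateDesignError(SoilstoreError):
    """A statistical design is rank deficient or has a constant predictor."""


class ModelConsistencyError(SoilstoreError):
    """The flux solver produced a state violating mass balance or sign rules."""
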