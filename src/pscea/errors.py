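"""Exception hierarchy shared across the package."""


class CeaModelError(Exception):
    """Base class for all model errors."""


class SchemaError(CeaModelError):
    """A configuration document is structurally invalid (missing/unknown field)."""


class ValidationError(CeaModelError):
    """A value violates a typed invariant (range, sign, consistency)."""


class FittingError(CeaModelError):
    """Survival fitting cannot proceed (no events, bad data)."""


class ConvergenceError(FittingError):
    """The likelihood optimiser failed to converge."""


class ConsistencyError(CeaModelError):
    """Internally inconsistent curves reached the trace (PFS above OS)."""


class PsaError(CeaModelError):
    """Probabilistic sensitivity analysis failed at run level."""


class TruncationWarning(UserWarning):
    """The time horizon truncates non-negligible residual survival."""
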