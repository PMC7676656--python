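"""Exception hierarchy for tmbsim.

All package-specific failures derive from :class:`TmbSimError` so callers can
catch domain errors without masking programming errors.
"""


class TmbSimError(Exception):
    """Base class for all tmbsim errors."""


class SchemaError(TmbSimError):
    """A table is missing mandatory columns or has an unusable layout."""


class ValidationError(TmbSimError):
    """Row-level content violates an invariant (negative TMB, duplicate id, ...)."""


class ConfigurationError(TmbSimError):
    """An unknown preset, option value, or inconsistent parameter set."""


class InsufficientDataError(TmbSimError):
    """Too few records to perform the requested estimation."""


class DegenerateDataError(TmbSimError):
    """Data has no usable variation (all responders, zero variance, ...)."""


class ZeroSelectionError(TmbSimError):
    """No patient is selected for treatment; ORR is undefined."""


class SolverError(TmbSimError):
    """A root-finding target is unreachable on the search interval."""
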