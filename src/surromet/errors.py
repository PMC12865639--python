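"""Exception types shared across the package."""


class SurrometError(Exception):
    """Base class for all package-specific errors."""


class TrialDataError(SurrometError, ValueError):
    """A trial table or record violates the data model (row-addressed where possible)."""


class InsufficientTrialsError(SurrometError, ValueError):
    """Too few trials survive the eligibility filter for the requested analysis."""


class DegenerateInputError(SurrometError, ValueError):
    """An input has zero variance (or an equivalent degeneracy) so the statistic is undefined."""
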