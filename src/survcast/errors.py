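"""Exception hierarchy for survcast."""


class SurvcastError(Exception):
    """Base class for all survcast errors."""


class InputError(SurvcastError):
    """Invalid user-supplied data or configuration."""


class GridError(SurvcastError):
    """Violation of an interval-survival-grid invariant."""


class FitError(SurvcastError):
    """Model fitting failed (non-convergence, rank deficiency, ...)."""
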