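"""Exception hierarchy.

``ValidationError`` covers malformed inputs (exit code 2 at the CLI);
everything else is an internal error (exit code 1).
"""


class CnithError(Exception):
    """Base class for all package errors."""


class ValidationError(CnithError, ValueError):
    """Input data violates a documented invariant."""


class NoSignalError(CnithError, ValueError):
    """Genomic distance does not discriminate intra- from inter-patient pairs."""


class DegenerateOutcomeError(CnithError, ValueError):
    """All outcomes identical; a logistic model cannot be fitted."""
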