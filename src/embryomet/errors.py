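"""Exception hierarchy.

All embryomet-specific failures derive from :class:`EmbryometError` so that
callers (and the CLI) can distinguish configuration problems, I/O problems
and statistical degeneracies from programming errors.
"""


class EmbryometError(Exception):
    """Base class for all embryomet errors."""


class ConfigurationError(EmbryometError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class InsufficientDataError(EmbryometError, ValueError):
    """Too few observations to run a statistical procedure."""


class InsufficientVarianceError(InsufficientDataError):
    """A metabolite vector is (within a group) constant."""


class DegenerateLabelsError(EmbryometError, ValueError):
    """Outcome labels contain fewer than two classes."""


class UndefinedFoldChangeError(EmbryometError, ValueError):
    """Fold change undefined because a group mean is non-positive."""


class PairingError(EmbryometError, ValueError):
    """Two call vectors share no samples."""


class UnitMismatchError(EmbryometError, ValueError):
    """Frozen cutoffs cannot be transferred across measurement units."""


class UndefinedTestError(EmbryometError, ValueError):
    """All strata of a stratified test are degenerate."""
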