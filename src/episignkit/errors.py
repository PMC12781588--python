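"""Exception hierarchy for episignkit.

All package-specific failures derive from :class:`EpisignError` so callers
can catch one base class at pipeline boundaries.
"""


class EpisignError(Exception):
    """Base class for all episignkit errors."""


class ConfigurationError(EpisignError):
    """Invalid simulation or run configuration."""


class FormatError(EpisignError):
    """Malformed input file (ragged rows, non-numeric cells, bad ranges)."""


class AlignmentError(EpisignError):
    """Probe or sample identifiers do not line up between inputs."""


class MatchingError(EpisignError):
    """No eligible control could be found for one or more cases."""


class DesignError(EpisignError):
    """Rank-deficient or otherwise unusable design matrix."""


class DegenerateDataError(EpisignError):
    """Data carry no usable signal (e.g. all residual variances zero)."""


class SelectionError(EpisignError):
    """Probe-selection funnel produced an empty candidate set."""


class TrainingError(EpisignError):
    """Classifier training preconditions violated."""

class ValidationError(EpisignError):
    """Value-level validation failure (e.g. p-values outside [0, 1])."""
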