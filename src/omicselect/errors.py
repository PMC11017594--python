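"""Exception and warning types shared across the package."""


class OmicselectError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdError(OmicselectError):
    """A sample or feature identifier occurs more than once."""


class ParseError(OmicselectError):
    """A table cell could not be parsed as a number.

    Carries the offending row/column coordinates in the message.
    """


class AlignmentError(OmicselectError):
    """Sample or feature spaces cannot be reconciled."""


class DegenerateLabelsError(OmicselectError):
    """A binary-label operation received fewer than two classes."""


class ValueDomainError(OmicselectError):
    """Values fall outside the domain an operation requires."""


class MissingTaxonomyError(OmicselectError):
    """An ASV has no genus assignment in the taxonomy map."""


class ZeroSampleError(OmicselectError):
    """A sample has zero total count where a positive total is required."""


class PairingError(OmicselectError):
    """No subject has a complete day-0/day-10 pair."""


class ConfigError(OmicselectError):
    """A configuration value is invalid."""


class DegenerateFeatureError(OmicselectError):
    """A feature has zero variance where variation is required."""


class DegenerateScoreError(OmicselectError):
    """A score vector has zero variance."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped at its iteration cap.

    Carried inside fit objects (``converged=False``) rather than raised.
    """
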