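"""Exception hierarchy and warning categories."""


class NephQCError(Exception):
    """Base class for all errors raised by nephqc."""


class FormatError(NephQCError):
    """A file does not conform to the documented CSV dialect."""


class InputError(NephQCError):
    """Input values violate a precondition (empty, non-positive, out of range)."""


class AlignmentError(NephQCError):
    """Two instrument series share no timestamps within tolerance."""


class WindowError(NephQCError):
    """An averaging window contains no data points."""


class FitError(NephQCError):
    """A regression cannot be fit (too few points, degenerate design)."""


class ModelValidityError(NephQCError):
    """A stored model evaluates to a physically impossible value (CF <= 0)."""


class FoldError(NephQCError):
    """A cross-validation fold failed to fit; the message names the fold."""


class ConfigError(NephQCError):
    """A pipeline configuration file is invalid; the message names the key."""


class RangeWarning(UserWarning):
    """Prediction requested outside the calibrated concentration range."""
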