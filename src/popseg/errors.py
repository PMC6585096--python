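"""Exception hierarchy for the popseg pipeline.

Every stage raises a subclass of :class:`PopsegError` so callers (and the
CLI) can distinguish bad configuration from bad data from model failures.
"""


class PopsegError(Exception):
    """Base class for all popseg errors."""


class ConfigError(PopsegError):
    """A configuration object violates one of its invariants."""


class DataIntegrityError(PopsegError):
    """Input records are internally inconsistent (duplicates, missing keys)."""


class FormatError(PopsegError):
    """A file on disk does not conform to the expected CSV dialect."""


class ModelError(PopsegError):
    """A statistical model could not be specified or fitted."""


class EstimationError(PopsegError):
    """An estimator was given input it cannot estimate from (e.g. empty)."""
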