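"""Exception hierarchy for circsc."""


class CircscError(Exception):
    """Base class for all circsc errors."""


class BsjParseError(CircscError):
    """A per-cell BSJ table could not be parsed (message names the line)."""


class ConsistencyError(CircscError):
    """The same circRNA id carries conflicting annotation across inputs."""


class MatrixFormatError(CircscError):
    """A matrix file violates its format contract (labels, bounds, dtype)."""


class ConfigError(CircscError):
    """A run configuration contains unknown or invalid keys."""
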