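"""Exception hierarchy.

Every error raised by the library derives from :class:`PlantarsegError`, so
callers (and the CLI, which maps them to exit code 2) can catch one type.
"""


class PlantarsegError(Exception):
    """Base class for all plantarseg errors."""


class FormatError(PlantarsegError):
    """A file on disk does not have the expected layout or bit depth."""


class ParameterError(PlantarsegError):
    """A parameter value violates its contract."""


class ConfigError(PlantarsegError):
    """A configuration file or object is invalid."""


class DegenerateInputError(PlantarsegError):
    """Input is too small or too uniform for the operation to be defined."""


class NoPlaneError(PlantarsegError):
    """RANSAC failed to produce an acceptable plane."""


class UndefinedMetricError(PlantarsegError):
    """A metric's denominator is zero; the value is undefined, not 0."""


class UndefinedTestError(PlantarsegError):
    """A statistical test is undefined on the given data (e.g. no non-zero
    paired differences for the signed-rank test)."""
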