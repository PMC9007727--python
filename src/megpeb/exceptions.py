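"""Exception hierarchy.

``ConfigError`` and ``DataError`` map onto the CLI exit codes 2 and 3.
"""


class MegpebError(Exception):
    """Base class for all package errors."""


class ConfigError(MegpebError):
    """Invalid or inconsistent configuration."""


class DataError(MegpebError):
    """Invalid, inconsistent or degenerate data."""


class GeometryError(DataError):
    """Geometric precondition violated (dipole outside sphere, sensor inside, ...)."""


class SingularGeometryError(GeometryError):
    """Degenerate geometry that makes the forward field singular."""
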