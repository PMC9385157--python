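"""Exception hierarchy for shellmea.

Errors are split into configuration problems (bad parameters, bad run
configs), data problems (non-finite samples, corrupt files) and boundary
conditions (a waveform window falling off the edge of a recording).  The
CLI maps ConfigError to exit code 2 and DataError to exit code 3.
"""


class ShellMEAError(Exception):
    """Base class for all shellmea errors."""


class ConfigError(ShellMEAError, ValueError):
    """Invalid parameter or run configuration."""


class DataError(ShellMEAError, ValueError):
    """Invalid or corrupt data (non-finite samples, inconsistent tables)."""


class FormatError(DataError):
    """A file does not conform to the documented on-disk format."""


class CorruptionError(FormatError):
    """A binary payload is inconsistent with its sidecar metadata."""


class BoundaryError(ShellMEAError, IndexError):
    """A requested waveform window crosses a recording boundary."""
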