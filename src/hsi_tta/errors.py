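"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (config -> 2, data -> 3,
stage -> 4), so library code should raise the most specific one.
"""


class HsiTtaError(Exception):
    """Base class for all package errors."""


class ConfigError(HsiTtaError):
    """Invalid or inconsistent configuration."""


class DataError(HsiTtaError):
    """Malformed, out-of-range or missing data."""


class StageError(HsiTtaError):
    """A pipeline stage failed; message names the stage and scene."""
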