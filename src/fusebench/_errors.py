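"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, data 3, stage 4).
"""


class FuseBenchError(Exception):
    """Base class for all package errors."""


class ConfigError(FuseBenchError):
    """Invalid configuration (bad field value, unknown key, inconsistent spec)."""


class DataError(FuseBenchError):
    """Input data violates a contract (empty table, missing column, mismatch)."""


class StageError(FuseBenchError):
    """A pipeline stage failed at run time."""
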