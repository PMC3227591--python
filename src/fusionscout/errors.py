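"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: InputError -> 2, ConfigError -> 3.
"""


class FusionScoutError(Exception):
    """Base class for all package errors."""


class InputError(FusionScoutError):
    """Malformed or inconsistent input data (files, records, sequences)."""


class ConfigError(FusionScoutError):
    """Invalid configuration or parameter combination."""
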