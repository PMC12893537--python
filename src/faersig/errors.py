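"""Exception hierarchy mapped onto CLI exit codes."""


class FaersigError(Exception):
    """Base class; exit code 1."""

    exit_code = 1


class ConfigError(FaersigError):
    """Invalid configuration (unknown table, bad option combination); exit code 2."""

    exit_code = 2


class DataFormatError(FaersigError):
    """Malformed input data (missing header, conflicting vocabulary); exit code 3."""

    exit_code = 3


class StageError(FaersigError):
    """A pipeline stage failed; exit code 4."""

    exit_code = 4
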