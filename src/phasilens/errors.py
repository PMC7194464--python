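"""Exception hierarchy shared by all stages."""


class PhasilensError(Exception):
    """Base class for all package errors."""


class ConfigError(PhasilensError):
    """Invalid configuration (maps to CLI exit code 2)."""


class FormatError(PhasilensError):
    """Malformed input file or sequence."""


class NoCleavageEvidenceError(PhasilensError):
    """Queried T-plot position has a zero count; no category is defined."""


class UnanchoredReadError(PhasilensError):
    """Read lacks a genome-templated prefix long enough to anchor tail calling."""
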