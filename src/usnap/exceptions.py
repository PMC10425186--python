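"""Exception hierarchy for usnap."""


class UsnapError(Exception):
    """Base class for all usnap-specific errors."""


class ConfigError(UsnapError, ValueError):
    """Invalid run parameters (k, gamma, u out of range, too few snapshots, ...)."""


class InputError(UsnapError, ValueError):
    """Malformed input file; the message names the file and, where known, the line."""
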