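"""Exception taxonomy shared across the package.

The CLI maps these onto distinct exit codes, so library code should raise
the most specific class that applies.
"""


class FourcatError(Exception):
    """Base class for all package-specific errors."""


class InputError(FourcatError, ValueError):
    """Malformed or out-of-contract input data (sequences, counts, sizes)."""


class CoordinateError(InputError):
    """A genomic coordinate outside the chromosome or fragment map."""


class ConfigError(FourcatError, ValueError):
    """A configuration value that does not resolve against the data."""


class CapacityError(FourcatError):
    """A request beyond an operation's stated size cap (e.g. exact tests)."""
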