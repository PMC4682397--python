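"""Exception hierarchy.

All package-specific failures derive from :class:`BenchmarkError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class BenchmarkError(Exception):
    """Base class for all tfpairbench errors."""


class InvalidPairError(BenchmarkError, ValueError):
    """A TF pair violates pair semantics (e.g. a self-pair)."""


class ParseError(BenchmarkError, ValueError):
    """A text input could not be parsed; message names file and line."""


class EmptyListError(BenchmarkError, ValueError):
    """A prediction list contained zero valid pairs."""


class ConsistencyError(BenchmarkError, ValueError):
    """Conflicting duplicate entries in a score table."""


class BundleError(BenchmarkError, ValueError):
    """A reference bundle is incomplete or unusable."""


class ConfigError(BenchmarkError, ValueError):
    """An infeasible or contradictory configuration."""


class UsageError(BenchmarkError, ValueError):
    """An invalid request to the comparison pipeline (e.g. no indices)."""
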