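"""Exception hierarchy shared across the pipeline stages.

Exit-code mapping used by the command line interface:
configuration errors -> 2, data-integrity errors -> 3, numerical failures -> 4.
"""


class NodewalkError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(NodewalkError):
    """Invalid or inconsistent configuration (weights, windows, grids)."""

    exit_code = 2


class DataIntegrityError(NodewalkError):
    """Input data violate a cohort invariant (e.g. more involved nodes than examined)."""

    exit_code = 3


class NumericalError(NodewalkError):
    """A numerical procedure failed (no events, degenerate design, no series)."""

    exit_code = 4


class DegenerateDesignError(NumericalError):
    """A covariate column carries no contrast (constant across subjects)."""
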