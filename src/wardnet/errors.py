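"""Exception hierarchy for the wardnet pipeline.

Every stage raises a subclass of :class:`WardnetError` so the CLI can tag
failures with the stage that produced them.
"""


class WardnetError(Exception):
    """Base class for all wardnet errors."""


class ConfigurationError(WardnetError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(WardnetError):
    """Malformed input records (bad columns, namespaces, enum values)."""


class GraphError(WardnetError):
    """An operation was asked of a graph that cannot support it."""


class UndefinedModularityError(GraphError):
    """Modularity requested on a graph with no edges."""


class UndefinedStatisticError(WardnetError):
    """A statistic (cv, correlation) is undefined for the given series."""


class FitError(WardnetError):
    """A distribution fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace
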