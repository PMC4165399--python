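"""Exception hierarchy shared across the package."""


class NetprioError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NetprioError, ValueError):
    """A parameter violates an operation's contract (e.g. threshold <= 1)."""


class InvalidInputError(NetprioError, ValueError):
    """Input data violates a structural requirement (e.g. negative intensity)."""


class InputFormatError(NetprioError, ValueError):
    """A file could not be parsed in the declared dialect."""


class UnknownGeneError(NetprioError, KeyError):
    """A gene/protein symbol is absent from the structure being queried."""


class UndefinedMetricError(NetprioError, ValueError):
    """A metric is undefined for the given input (e.g. density of one node)."""
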