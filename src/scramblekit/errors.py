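"""Exception hierarchy.

All errors raised by scramblekit derive from :class:`ScramblekitError` so
callers can catch the package's failures with a single except clause while
still distinguishing parameter problems from malformed inputs.
"""


class ScramblekitError(Exception):
    """Base class for all scramblekit errors."""


class ParameterError(ScramblekitError, ValueError):
    """A model or generator parameter violates its invariants."""


class ConfigError(ScramblekitError, ValueError):
    """A detector / run configuration violates its invariants."""


class TopologyError(ScramblekitError, ValueError):
    """A lipid topology references beads absent from the trajectory."""


class InputError(ScramblekitError, ValueError):
    """An input object (trace, event list, ...) is unusable as given."""


class RangeError(ScramblekitError, ValueError):
    """A requested value lies outside the attainable range."""
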