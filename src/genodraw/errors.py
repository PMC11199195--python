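"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`GenodrawError`, so callers (and the CLI) can catch one type.
"""


class GenodrawError(Exception):
    """Base class for all errors raised by genodraw."""


class ParseError(GenodrawError):
    """A sequence, cache, or tabular file could not be parsed."""


class ConfigError(GenodrawError):
    """A project / display configuration or parameter value is invalid."""


class LayoutError(GenodrawError):
    """Layout cannot be computed (e.g. no active sequences)."""


class SearchError(GenodrawError):
    """A homology search failed (missing executable, nonzero exit, ...)."""
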