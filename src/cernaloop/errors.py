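"""Exception hierarchy shared across the pipeline.

Stage code raises the most specific class available; the command-line
layer maps :class:`CernaLoopError` subclasses to exit code 2 (data error)
and everything else user-facing to exit code 1.
"""


class CernaLoopError(Exception):
    """Base class for all pipeline-domain errors."""


class FormatError(CernaLoopError):
    """A table on disk does not match the expected dialect (missing
    column, non-numeric cell, unparseable value)."""


class IntegrityError(CernaLoopError):
    """Referential integrity between tables is broken (e.g. a sponge
    edge names a circRNA absent from the annotation)."""


class ConfigError(CernaLoopError):
    """A simulation or run configuration is internally inconsistent."""


class StratificationError(CernaLoopError):
    """A requested stratum is empty after filtering; names the filter."""


class UndefinedResultError(CernaLoopError):
    """The requested statistic is undefined on the given input
    (too few points, zero variance, degenerate table)."""
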