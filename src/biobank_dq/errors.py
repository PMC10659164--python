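"""Exception hierarchy for the data-quality pipeline.

Every failure mode that a caller can reasonably branch on gets its own
class; all inherit from :class:`BiobankDQError` so ``except BiobankDQError``
catches anything raised deliberately by this package.
"""


class BiobankDQError(Exception):
    """Base class for all errors raised by biobank_dq."""


class SchemaError(BiobankDQError):
    """Malformed schema definition (bad value class, duplicate field, ...)."""


class StructureError(BiobankDQError):
    """A dataset file does not match the schema structurally (missing table
    file, header mismatch).  Value-level defects never raise this — they are
    the rule engine's job."""


class ReviewError(BiobankDQError):
    """An expert-review decision references an unknown rule."""


class EngineError(BiobankDQError):
    """The rule engine met a predicate it cannot evaluate."""


class ExportError(BiobankDQError):
    """A rule's predicate cannot be expressed as a single SQL SELECT."""


class StatsError(BiobankDQError):
    """Degenerate input to a statistical routine (zero margin, too few rows)."""


class UndefinedCorrelationError(StatsError):
    """Correlation requested on a constant vector — undefined, not zero."""


class ConfigError(BiobankDQError):
    """Invalid generator configuration."""


class InjectionError(BiobankDQError):
    """Requested error injections exceed the available injection sites."""
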