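"""Exception hierarchy.

Every error raised by this package derives from :class:`DietFootprintError`
so callers can catch the package's failures with a single except clause.
"""


class DietFootprintError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DietFootprintError):
    """A generator or run specification is invalid; the message names the field."""


class DataError(DietFootprintError):
    """Input data violate a documented invariant (negative intake, zero energy, ...)."""


class CategoryLookupError(DietFootprintError, KeyError):
    """An LCA category id is absent from the database."""


class LinkageError(DietFootprintError):
    """An FFQ item cannot be resolved through the link table."""


class CompositionError(DietFootprintError):
    """Declared ingredient percentages are infeasible under the labelling constraints."""


class ClassificationError(DietFootprintError):
    """Diet-group screening answers are missing or unreadable."""


class AlignmentError(DietFootprintError):
    """Cohort intake columns do not align with the draw matrix item set."""


class RegistryError(DietFootprintError, KeyError):
    """Unknown CO2-equivalence metric name."""
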