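"""Exception hierarchy.

Every error raised by the library derives from :class:`StarCohortError`,
so callers can catch one type at an API boundary (the CLI does exactly
that and converts to a non-zero exit code).
"""


class StarCohortError(Exception):
    """Base class for all library errors."""


class SchemaConflictError(StarCohortError):
    """Target database already holds tables incompatible with the star schema."""


class PlanError(StarCohortError):
    """A query plan references a dimension or selector the schema does not know."""


class UnsupportedInitializationError(StarCohortError):
    """A condition class was initialized with a mode it does not support
    (e.g. a clinical code for a description-only class)."""


class AmbiguityError(StarCohortError):
    """More than one initialization mode was given for a single condition."""


class ArityError(StarCohortError):
    """A Boolean combinator received fewer than two operands."""


class DomainError(StarCohortError, ValueError):
    """A numeric argument is outside its legal domain (negative age,
    inverted window, series too short, ...)."""


class ClassMismatchError(StarCohortError):
    """A value extraction was requested for a condition class that carries
    no numeric values (e.g. ``values_for`` on a Diagnosis condition)."""


class ConfigError(StarCohortError):
    """A generator or pivot configuration is invalid."""


class SchemaVersionError(StarCohortError):
    """A serialized document declares an unknown version or condition class."""


class ConditionParseError(StarCohortError):
    """A serialized condition document is structurally malformed."""
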