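"""Exception hierarchy shared by all pipeline stages."""


class GallwaspError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GallwaspError, ValueError):
    """An input table or record violates its documented schema."""


class CoverageError(GallwaspError, ValueError):
    """A requested date falls outside the coverage of a daily series."""


class DomainError(GallwaspError, ValueError):
    """An operation was called with arguments outside its mathematical domain."""


class LookupError_(GallwaspError, KeyError):
    """A (locality, cohort/year, ...) key selects no records."""
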