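"""Exception hierarchy shared across the package."""


class GfrConcordError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GfrConcordError, ValueError):
    """A numeric input is outside its physical/mathematical domain."""


class InputError(GfrConcordError, ValueError):
    """A required input (e.g. a filtration marker) is missing."""


class ConfigurationError(GfrConcordError, ValueError):
    """An unknown identifier, unit tag, or invalid configuration value."""


class SchemaError(GfrConcordError, ValueError):
    """An input table violates the expected column schema."""


class EmptySeriesError(GfrConcordError, ValueError):
    """A statistic was requested on an empty paired series."""
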