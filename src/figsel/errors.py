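"""Exception hierarchy shared across the pipeline stages."""


class FigselError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(FigselError):
    """An input table is missing a required column or mapping."""


class IntegrityError(FigselError):
    """A structural invariant is violated (e.g. duplicate accession ids)."""


class DomainError(FigselError, ValueError):
    """A value lies outside the physically meaningful domain."""


class EmptySelectionError(FigselError):
    """A selection stage eliminated every candidate accession."""


class ConfigError(FigselError):
    """A run configuration is invalid or inconsistent."""


class NotSupportedError(FigselError):
    """The requested operation is undefined for the given model family."""
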