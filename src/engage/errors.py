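"""Exception hierarchy shared across the package."""


class EngageError(Exception):
    """Base class for all package errors."""


class ConfigError(EngageError):
    """A catalog or simulation configuration is malformed."""


class CatalogLookupError(ConfigError, KeyError):
    """A cohort/school pair or activity name does not resolve in the catalog."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ValidationError(EngageError, ValueError):
    """An input value violates a declared invariant (counts, percentiles, thresholds)."""
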