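"""Exception hierarchy shared across the package."""


class GreyscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GreyscanError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DomainError(GreyscanError, ValueError):
    """An operation was called outside its mathematical domain."""


class PanelLookupError(GreyscanError, KeyError):
    """A district or year referenced by an operation is absent from the panel."""


class ValidationError(GreyscanError, ValueError):
    """Input files failed referential-integrity checks.

    ``violations`` lists every problem found, not only the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "input validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
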