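"""Exception hierarchy for metsel.

All errors carry enough context (field, cell, trait) to locate the offending
input without re-running the stage.
"""


class MetselError(Exception):
    """Base class for all metsel errors."""


class ConfigurationError(MetselError):
    """Invalid simulation or pipeline configuration; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class BalanceError(MetselError):
    """A dataset is not fully balanced; lists the missing cells."""

    def __init__(self, missing, message: str = "dataset is not balanced"):
        self.missing = list(missing)
        shown = ", ".join(map(str, self.missing[:10]))
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"{message}; missing cells: {shown}{more}")


class DomainError(MetselError):
    """A value is outside the mathematical domain of an operation."""


class FormatError(MetselError):
    """A file does not conform to the expected layout."""


class ConsistencyError(MetselError):
    """Two inputs that must describe the same experiment disagree."""
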