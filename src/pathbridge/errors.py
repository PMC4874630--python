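"""Exception hierarchy shared across the package."""


class PathbridgeError(Exception):
    """Base class for all package errors."""


class ParseError(PathbridgeError):
    """Malformed input that could not be read at all (bad JSON, bad XML)."""


class ValidationError(PathbridgeError):
    """Input read successfully but violates the data-model contract."""


class ReferentialIntegrityError(ValidationError):
    """An identifier reference does not resolve within its document."""


class ContractError(PathbridgeError):
    """An operation was called outside its contract (caller bug)."""


class CriterionError(PathbridgeError):
    """Criterion expression failed to parse or references unknown columns."""


class DomainError(PathbridgeError):
    """Numeric precondition violated (e.g. impossible enrichment counts)."""


class LookupError_(PathbridgeError):
    """Unknown complex or component identifier in a lookup."""
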