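"""Exception hierarchy."""


class PlantregError(Exception):
    """Base class for all package errors."""


class RuleSyntaxError(PlantregError):
    """Malformed rule-language expression.

    Carries the 0-based character offset at which parsing failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class RuleTableError(PlantregError):
    """Structurally invalid rule table (missing column, duplicate family, ...)."""


class FastaError(PlantregError):
    """Unreadable or malformed FASTA input."""


class AnnotationError(PlantregError):
    """Malformed domain-annotation table."""


class ScannerError(PlantregError):
    """External domain-scanner invocation failed."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message if not stderr else f"{message}\n--- scanner stderr ---\n{stderr}")
        self.stderr = stderr
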