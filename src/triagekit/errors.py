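"""Exception hierarchy.

``TriageError`` is the base for every data/contract failure the package
raises deliberately; the CLI maps it to exit status 2.
"""


class TriageError(Exception):
    """Base class for data and contract errors."""


class ConfigurationError(TriageError):
    """Invalid or incomplete run-time configuration."""


class SchemaError(TriageError):
    """A record violates the knowledge-base or case schema."""


class ReferentialIntegrityError(SchemaError):
    """An association references an id that does not exist in the KB."""

    def __init__(self, unresolved: list[str]):
        self.unresolved = list(unresolved)
        super().__init__(f"unresolved ids: {', '.join(self.unresolved)}")


class VocabularyError(TriageError):
    """A value falls outside a closed vocabulary."""


class LookupError_(TriageError):
    """An id was not found where the contract requires it to resolve."""


class EmptyCaseError(TriageError):
    """A patient case resolved to zero usable findings."""


class DegenerateCaseError(TriageError):
    """Every diagnosis scored zero; the differential cannot be normalized."""


class ContractError(TriageError):
    """An internal pre/post-condition between pipeline stages failed."""


class UndefinedKappaError(TriageError):
    """Chance agreement is 1: kappa is undefined for this matrix."""
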