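"""Exception hierarchy and the shared violation record.

Validation operations throughout the package report problems as
:class:`Violation` values (data, never exceptions); exceptions are reserved
for hard failures such as malformed input, dangling identifiers at write
time, or configuration errors detected before any output is produced.
"""

from __future__ import annotations

from dataclasses import dataclass


class OdmFhirError(Exception):
    """Base class for all package errors."""


class OdmParseError(OdmFhirError):
    """Malformed XML input; carries the source line where known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class OdmStructureError(OdmFhirError):
    """Well-formed XML that is not a usable ODM 1.3 document."""


class OdmVocabularyError(OdmFhirError):
    """A token outside the supported ODM vocabulary (e.g. unknown datatype)."""


class DanglingOidError(OdmFhirError):
    """Refusal to serialize a study whose OID references do not resolve."""


class MappingConfigError(OdmFhirError):
    """A mapping configuration names OIDs absent from the study metadata."""


class ProtocolMetaError(OdmFhirError):
    """Protocol metadata is missing a mandatory field (e.g. status)."""


class InvestigationMixError(OdmFhirError):
    """A native-path visit mixes investigation kinds (choice-of-one rule)."""


class SerializationRefusedError(OdmFhirError):
    """Refusal to serialize a bundle that fails validation."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.path}: {v.message}" for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"bundle has {len(self.violations)} violation(s): {lines}{more}")


@dataclass(frozen=True)
class Violation:
    """One validation finding: where it is and what is wrong."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.path}: {self.message}"
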