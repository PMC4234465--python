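"""Core record types shared across the ingestion and build pipeline.

A *raw record* is one assertion taken verbatim from a source database: it
links a compound descriptor to a target descriptor and carries the evidence
payload (activity type/value/units, evidence class, reference text) exactly
as the source stated it.  Everything downstream — compound unification,
gene mapping, evidence standardization — consumes streams of these records.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: identifier classes a compound descriptor may carry
IDENTIFIER_CLASSES = frozenset({"inchi", "inchikey", "smiles", "cas", "formula"})
#: name classes, from most to least specific
NAME_CLASSES = ("systematic", "brand", "synonym")
#: broad classes a source target entry may declare
TARGET_CLASSES = frozenset(
    {"protein", "nucleotide", "pseudogene", "pathway", "disease", "other"}
)
#: provenance classes of an evidence
EVIDENCE_CLASSES = frozenset({"predicted", "measured", "curated", "textual"})


@dataclass
class CompoundDescriptor:
    """How one source record describes its compound.

    At least one of ``structure_text`` (a molfile block), ``identifiers`` or
    ``names`` must be populated.  ``local_id`` is the compound's id inside
    its source database; the cross-reference table joins on
    ``(source_db, local_id)`` pairs.
    """

    structure_text: str | None = None
    identifiers: dict[str, str] = field(default_factory=dict)
    names: list[tuple[str, str]] = field(default_factory=list)
    xrefs: list[tuple[str, str]] = field(default_factory=list)
    local_id: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.identifiers) - IDENTIFIER_CLASSES
        if bad:
            raise ValueError(f"unknown identifier class(es): {sorted(bad)}")
        for cls, _ in self.names:
            if cls not in NAME_CLASSES:
                raise ValueError(f"unknown name class: {cls!r}")
        if not (self.structure_text or self.identifiers or self.names):
            raise ValueError(
                "compound descriptor needs a structure, an identifier or a name"
            )


@dataclass
class TargetDescriptor:
    """How one source record describes its target."""

    namespace: str
    foreign_id: str
    label: str = ""
    target_class: str = "protein"
    organism: str = ""

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target class: {self.target_class!r}")


@dataclass
class EvidencePayload:
    """The evidence carried by one source record, untouched.

    ``activity_value_raw`` without ``activity_type_raw`` is rejected: a bare
    number with no stated measurement type is meaningless.
    """

    activity_type_raw: str | None = None
    activity_value_raw: float | None = None
    activity_units_raw: str | None = None
    evidence_class: str = "measured"
    reference: str = ""
    assay_description: str = ""

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(f"unknown evidence class: {self.evidence_class!r}")
        if self.activity_value_raw is not None and self.activity_type_raw is None:
            raise ValueError("activity value without an activity type")


@dataclass
class RawRecord:
    """One source-database assertion linking a compound and a target."""

    source_db: str
    source_relation_id: str
    compound: CompoundDescriptor
    target: TargetDescriptor
    evidence: EvidencePayload
    #: evidence context: does this assertion refer to inhibition?  Drives the
    #: "Inhibitory Concentration"/"AC" -> IC50 normalization downstream.
    refers_to_inhibition: bool = False

    def __post_init__(self) -> None:
        if not self.source_db or not self.source_relation_id:
            raise ValueError("source_db and source_relation_id must be non-empty")

    @property
    def ref(self) -> tuple[str, str]:
        """Globally unique key of this record: (source_db, source_relation_id)."""
        return (self.source_db, self.source_relation_id)

    @property
    def compound_ref(self) -> tuple[str, str]:
        """Key the cross-reference table joins on: (source_db, local compound id).

        Falls back to the relation id when the source gave no compound id.
        """
        return (self.source_db, self.compound.local_id or self.source_relation_id)


@dataclass
class Diagnostic:
    """A skipped or problematic input item, with enough context to find it."""

    source: str
    ordinal: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.source}[{self.ordinal}]: {self.message}"
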