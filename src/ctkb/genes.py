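"""Gene index and target mapping.

Every target descriptor must be traced unambiguously to one gene in a
common gene index (namespace/foreign-id -> gene id, emulating an
Entrez-style index) before its relations enter the knowledge base.  Targets
that are not genes or gene products — pathways, diseases, pseudogenes — or
whose key is ambiguous or unknown are rejected with a machine-readable
reason; nothing is ever guessed.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .records import TargetDescriptor

logger = logging.getLogger(__name__)

GENE_TYPES = frozenset({"protein_coding", "nucleotide", "pseudogene", "other"})
#: target classes that may enter the knowledge base
IMPORTABLE_TARGET_CLASSES = frozenset({"protein", "nucleotide"})

_REQUIRED_COLUMNS = ("namespace", "foreign_id", "gene_id", "symbol", "organism", "gene_type")


@dataclass(frozen=True)
class GeneEntry:
    gene_id: str
    symbol: str
    organism: str
    gene_type: str


@dataclass
class GeneIndex:
    """Lookup from (namespace, foreign_id) keys to unique gene ids."""

    lookup: dict[tuple[str, str], str] = field(default_factory=dict)
    genes: dict[str, GeneEntry] = field(default_factory=dict)
    ambiguous: set[tuple[str, str]] = field(default_factory=set)

    def resolve(self, namespace: str, foreign_id: str) -> str | None:
        # the reserved "ctkb" namespace addresses genes by their own id, so
        # exported relations re-ingest against the same index
        if namespace == "ctkb":
            return foreign_id if foreign_id in self.genes else None
        key = (namespace, foreign_id)
        if key in self.ambiguous:
            return None
        return self.lookup.get(key)


def load_gene_index(path: str | Path) -> GeneIndex:
    """Load a gene-index TSV (namespace, foreign_id, gene_id, symbol, organism,
    gene_type).  A key listed for two different gene ids is flagged ambiguous
    and will never resolve."""
    idx = GeneIndex()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"gene index missing column(s): {sorted(missing)}")
        for row in reader:
            gene_id = row["gene_id"].strip()
            gene_type = row["gene_type"].strip()
            if gene_type not in GENE_TYPES:
                raise ValueError(f"unknown gene_type {gene_type!r} for gene {gene_id}")
            entry = GeneEntry(
                gene_id=gene_id,
                symbol=row["symbol"].strip(),
                organism=row["organism"].strip(),
                gene_type=gene_type,
            )
            existing = idx.genes.get(gene_id)
            if existing is not None and existing != entry:
                raise ValueError(f"conflicting gene rows for gene_id {gene_id!r}")
            idx.genes[gene_id] = entry
            key = (row["namespace"].strip(), row["foreign_id"].strip())
            if key in idx.lookup and idx.lookup[key] != gene_id:
                idx.ambiguous.add(key)
            else:
                idx.lookup[key] = gene_id
    return idx


@dataclass(frozen=True)
class MappingOutcome:
    """Result of mapping one target descriptor: mapped, or rejected with why."""

    status: str  # mapped | rejected_class | rejected_ambiguous | rejected_unknown
    gene_id: str | None = None
    reason: str = ""


def map_target(
    t: TargetDescriptor, idx: GeneIndex, strict_organism: bool = False
) -> MappingOutcome:
    """Map a target descriptor to a unique gene, or reject it.

    Mapped only when the declared class is protein or nucleotide, the
    (namespace, foreign_id) key resolves unambiguously, and the resolved
    gene is not a pseudogene.  A pure function of (descriptor, index):
    identical inputs always give identical outcomes.
    """
    if t.target_class not in IMPORTABLE_TARGET_CLASSES:
        return MappingOutcome(
            "rejected_class", reason=f"target class {t.target_class!r} is not importable"
        )
    key = (t.namespace, t.foreign_id)
    if key in idx.ambiguous:
        return MappingOutcome(
            "rejected_ambiguous", reason=f"key {key} maps to multiple genes"
        )
    gene_id = idx.resolve(t.namespace, t.foreign_id)
    if gene_id is None:
        return MappingOutcome("rejected_unknown", reason=f"key {key} not in gene index")
    gene = idx.genes[gene_id]
    if gene.gene_type == "pseudogene":
        return MappingOutcome(
            "rejected_class", reason=f"gene {gene_id} is a pseudogene"
        )
    if t.organism and gene.organism and t.organism != gene.organism:
        msg = (
            f"organism mismatch for {key}: descriptor says {t.organism!r}, "
            f"index says {gene.organism!r}"
        )
        if strict_organism:
            return MappingOutcome("rejected_unknown", reason=msg)
        logger.warning(msg)
    return MappingOutcome("mapped", gene_id=gene_id)
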