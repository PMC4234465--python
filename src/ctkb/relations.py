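"""Collapse standardized records into unique (compound entry, gene) relations.

Every surviving record contributes exactly one evidence; records that refer
to the same unified compound and the same gene collapse onto one relation,
which aggregates its evidences' strengths (strongest wins) and reliability
scores (highest wins).  Relation ids are stable hashes of the pair, so a
rebuild from shuffled input reproduces identical relations.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .evidence import (
    StandardEvidence,
    aggregate_relation_score,
    aggregate_relation_strength,
)


@dataclass
class Relation:
    """A unique (compound, gene) pair with its evidences and aggregates."""

    relation_id: str
    compound_entry_id: str
    gene_id: str
    evidences: list[StandardEvidence] = field(default_factory=list)
    relation_strength: str = "unclassified"
    relation_score: int | None = None
    homology_inferred: bool = False
    # (parent relation id, percent identity, homolog organism) when inferred
    homology_meta: tuple[str, float, str] | None = None
    source_dbs: frozenset[str] = frozenset()
    # crowd-sourcing style annotation hook: optional (flag, comment)
    flag: tuple[bool, str] | None = None

    def __post_init__(self) -> None:
        if self.homology_inferred:
            if self.homology_meta is None or self.evidences:
                raise ValueError(
                    "an inferred relation carries homology_meta and no evidences"
                )
        elif not self.evidences:
            raise ValueError("a direct relation needs at least one evidence")


def relation_id_for(compound_entry_id: str, gene_id: str, inferred: bool = False) -> str:
    tag = "H" if inferred else "R"
    digest = hashlib.sha1(f"{compound_entry_id}\x1f{gene_id}".encode()).hexdigest()
    return f"{tag}{digest[:12]}"


def build_relations(
    records: list[tuple[str, str, StandardEvidence]],
) -> list[Relation]:
    """Group (compound_entry_id, gene_id, evidence) triples into relations.

    Evidences within a relation are ordered by (source_db, source_relation_id)
    so the output is independent of input order.
    """
    grouped: dict[tuple[str, str], list[StandardEvidence]] = {}
    for entry_id, gene_id, ev in records:
        grouped.setdefault((entry_id, gene_id), []).append(ev)

    relations = []
    for (entry_id, gene_id) in sorted(grouped):
        evs = sorted(
            grouped[(entry_id, gene_id)],
            key=lambda e: (e.source_db, e.source_relation_id),
        )
        relations.append(
            Relation(
                relation_id=relation_id_for(entry_id, gene_id),
                compound_entry_id=entry_id,
                gene_id=gene_id,
                evidences=evs,
                relation_strength=aggregate_relation_strength(evs),
                relation_score=aggregate_relation_score(evs),
                source_dbs=frozenset(e.source_db for e in evs),
            )
        )
    return relations
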