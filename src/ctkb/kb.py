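"""The knowledge base: build pipeline, container, and on-disk form.

``build_kb`` runs the full construction pipeline over parsed raw records:
compound unification, target mapping, evidence standardization, relation
building, and homology inference.  The resulting ``KnowledgeBase`` is an
in-memory container that also round-trips losslessly through a directory
of JSON files, so a built corpus can be queried and exported later without
re-running construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .chem import DEFAULT_RULES, PurgeRules
from .evidence import (
    DEFAULT_RELIABILITY,
    DEFAULT_STRENGTH_RULE,
    ReliabilityMap,
    StandardEvidence,
    StrengthRule,
    standardize_evidence,
)
from .genes import GeneEntry, GeneIndex, map_target
from .homology import DEFAULT_THRESHOLD, HomologyGroup, infer_relations
from .records import Diagnostic, RawRecord
from .relations import Relation, build_relations
from .unify import DEFAULT_PRIORITY, CompoundEntry, MergePriority, prepare_refs, unify_compounds


@dataclass
class KnowledgeBase:
    compounds: dict[str, CompoundEntry] = field(default_factory=dict)
    genes: dict[str, GeneEntry] = field(default_factory=dict)
    relations: dict[str, Relation] = field(default_factory=dict)
    #: (source_db, source_relation_id, status, reason) for rejected targets
    rejections: list[tuple[str, str, str, str]] = field(default_factory=list)
    diagnostics: list[Diagnostic] = field(default_factory=list)

    # ---------------------------------------------------------- queries --
    def relation_list(self) -> list[Relation]:
        return [self.relations[rid] for rid in sorted(self.relations)]

    def compound_for(self, relation: Relation) -> CompoundEntry:
        return self.compounds[relation.compound_entry_id]

    def gene_for(self, relation: Relation) -> GeneEntry:
        return self.genes[relation.gene_id]

    # ------------------------------------------------------ persistence --
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        comp = {
            eid: {
                "canonical_key": e.canonical_key,
                "members": [list(m) for m in e.members],
                "merge_edges": [[list(a), list(b), m] for a, b, m in e.merge_edges],
                "identifiers": e.identifiers,
                "names": [list(n) for n in e.names],
                "unification_confidence": e.unification_confidence,
                "purged_molblock": e.purged_molblock,
            }
            for eid, e in sorted(self.compounds.items())
        }
        genes = {
            gid: {"symbol": g.symbol, "organism": g.organism, "gene_type": g.gene_type}
            for gid, g in sorted(self.genes.items())
        }
        rels = {
            rid: {
                "compound_entry_id": r.compound_entry_id,
                "gene_id": r.gene_id,
                "relation_strength": r.relation_strength,
                "relation_score": r.relation_score,
                "homology_inferred": r.homology_inferred,
                "homology_meta": list(r.homology_meta) if r.homology_meta else None,
                "source_dbs": sorted(r.source_dbs),
                "evidences": [
                    {
                        "source_db": e.source_db,
                        "source_relation_id": e.source_relation_id,
                        "activity_type": e.activity_type,
                        "value_si": e.value_si,
                        "converted_flag": e.converted_flag,
                        "original": list(e.original),
                        "strength": e.strength,
                        "reliability": e.reliability,
                        "evidence_class": e.evidence_class,
                        "reference": e.reference,
                        "assay_description": e.assay_description,
                        "refers_to_inhibition": e.refers_to_inhibition,
                    }
                    for e in r.evidences
                ],
            }
            for rid, r in sorted(self.relations.items())
        }
        (directory / "compounds.json").write_text(json.dumps(comp, indent=1))
        (directory / "genes.json").write_text(json.dumps(genes, indent=1))
        (directory / "relations.json").write_text(json.dumps(rels, indent=1))
        (directory / "rejections.tsv").write_text(
            "source_db\tsource_relation_id\tstatus\treason\n"
            + "".join("\t".join(row) + "\n" for row in self.rejections)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "KnowledgeBase":
        directory = Path(directory)
        kb = cls()
        comp = json.loads((directory / "compounds.json").read_text())
        for eid, d in comp.items():
            kb.compounds[eid] = CompoundEntry(
                entry_id=eid,
                canonical_key=d["canonical_key"],
                members=[tuple(m) for m in d["members"]],
                merge_edges=[(tuple(a), tuple(b), m) for a, b, m in d["merge_edges"]],
                identifiers=d["identifiers"],
                names=[tuple(n) for n in d["names"]],
                unification_confidence=d["unification_confidence"],
                purged_molblock=d["purged_molblock"],
            )
        genes = json.loads((directory / "genes.json").read_text())
        for gid, d in genes.items():
            kb.genes[gid] = GeneEntry(gene_id=gid, **d)
        rels = json.loads((directory / "relations.json").read_text())
        for rid, d in rels.items():
            evs = [
                StandardEvidence(
                    source_db=e["source_db"],
                    source_relation_id=e["source_relation_id"],
                    activity_type=e["activity_type"],
                    value_si=e["value_si"],
                    converted_flag=e["converted_flag"],
                    original=tuple(e["original"]),
                    strength=e["strength"],
                    reliability=e["reliability"],
                    evidence_class=e["evidence_class"],
                    reference=e["reference"],
                    assay_description=e["assay_description"],
                    refers_to_inhibition=e.get("refers_to_inhibition", False),
                )
                for e in d["evidences"]
            ]
            kb.relations[rid] = Relation(
                relation_id=rid,
                compound_entry_id=d["compound_entry_id"],
                gene_id=d["gene_id"],
                evidences=evs,
                relation_strength=d["relation_strength"],
                relation_score=d["relation_score"],
                homology_inferred=d["homology_inferred"],
                homology_meta=tuple(d["homology_meta"]) if d["homology_meta"] else None,
                source_dbs=frozenset(d["source_dbs"]),
            )
        return kb


def build_kb(
    records: list[RawRecord],
    gene_index: GeneIndex,
    xref_pairs: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    homology_groups: list[HomologyGroup] | None = None,
    homology_threshold: float = DEFAULT_THRESHOLD,
    purge_rules: PurgeRules = DEFAULT_RULES,
    priority: MergePriority = DEFAULT_PRIORITY,
    strength_rule: StrengthRule = DEFAULT_STRENGTH_RULE,
    reliability_map: ReliabilityMap = DEFAULT_RELIABILITY,
) -> KnowledgeBase:
    """Run the full construction pipeline and return the knowledge base."""
    kb = KnowledgeBase()

    refs, ref_diags = prepare_refs(records, purge_rules)
    kb.diagnostics.extend(Diagnostic(f"{db}:{cid}", 0, msg) for (db, cid), msg in ref_diags)

    # cross-references from the table plus those embedded in the records
    pairs = list(xref_pairs or [])
    for rec in records:
        for db, fid in rec.compound.xrefs:
            pairs.append((rec.compound_ref, (db, fid)))

    entries = unify_compounds(refs, pairs, priority)
    entry_of: dict[tuple[str, str], str] = {}
    for e in entries:
        kb.compounds[e.entry_id] = e
        for m in e.members:
            entry_of[m] = e.entry_id

    kb.genes = dict(gene_index.genes)

    triples: list[tuple[str, str, StandardEvidence]] = []
    for rec in records:
        outcome = map_target(rec.target, gene_index)
        if outcome.status != "mapped":
            kb.rejections.append(
                (rec.source_db, rec.source_relation_id, outcome.status, outcome.reason)
            )
            continue
        ev = standardize_evidence(
            rec.source_db,
            rec.source_relation_id,
            rec.evidence,
            refers_to_inhibition=rec.refers_to_inhibition,
            strength_rule=strength_rule,
            reliability_map=reliability_map,
        )
        triples.append((entry_of[rec.compound_ref], outcome.gene_id, ev))

    for rel in build_relations(triples):
        kb.relations[rel.relation_id] = rel

    if homology_groups:
        inferred, diags = infer_relations(
            kb.relation_list(), homology_groups, gene_index, homology_threshold
        )
        kb.diagnostics.extend(diags)
        for rel in inferred:
            kb.relations[rel.relation_id] = rel
    return kb
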