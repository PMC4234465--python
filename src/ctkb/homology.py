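"""Homology-inferred relations.

If a gene in an existing relation has a homolog (ortholog or paralog)
whose encoded protein is more than 80% identical in amino-acid sequence,
the same compound plausibly binds the homolog too.  This module consumes
homology groups — gene sets with pairwise percent identities, either
supplied precomputed or derived from member protein sequences by global
alignment — and emits flagged, evidence-free inferred relations for every
qualifying (compound, homolog) pair that is not already covered by a
direct relation.

Inference is single-pass: inferred relations never seed further inference.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .genes import GeneIndex
from .records import Diagnostic
from .relations import Relation, relation_id_for

DEFAULT_THRESHOLD = 80.0


def _make_aligner() -> Align.PairwiseAligner:
    # fixed global scoring: match +1, mismatch 0, gap -1 (open = extend)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two protein sequences.

    Identity = identical aligned positions / alignment length x 100, taken
    from an optimal global alignment under the fixed scoring above.  The
    measure is symmetric; identical sequences score 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _make_aligner().align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length * 100.0


@dataclass
class HomologyGroup:
    """Genes presumed homologous, with pairwise protein identities."""

    group_id: str
    members: list[str] = field(default_factory=list)
    # unordered pair (sorted tuple) -> percent identity
    identity: dict[tuple[str, str], float] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def get_identity(self, a: str, b: str) -> float | None:
        if a == b:
            return 100.0
        return self.identity.get((min(a, b), max(a, b)))

    def complete_identities(self) -> None:
        """Fill missing pairs by aligning member sequences (the fallback)."""
        for i, a in enumerate(self.members):
            for b in self.members[i + 1 :]:
                pair = (min(a, b), max(a, b))
                if pair in self.identity:
                    continue
                if a in self.sequences and b in self.sequences:
                    self.identity[pair] = pairwise_identity(
                        self.sequences[a], self.sequences[b]
                    )


def load_homology_table(path: str | Path) -> list[HomologyGroup]:
    """Load the homology TSV.

    Row dialect (first column is the record type):

    - ``member    <group_id> <gene_id> [protein sequence]``
    - ``identity  <group_id> <gene_a> <gene_b> <percent>``

    Missing pair identities are computed from sequences where available.
    """
    groups: dict[str, HomologyGroup] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "record_type":
            raise ValueError("homology table must start with a 'record_type' header")
        for ordinal, row in enumerate(reader, start=1):
            if not row or not row[0].strip():
                continue
            kind = row[0].strip()
            if kind == "member":
                if len(row) < 3:
                    raise ValueError(f"row {ordinal}: member row needs group_id and gene_id")
                gid, gene = row[1].strip(), row[2].strip()
                g = groups.setdefault(gid, HomologyGroup(group_id=gid))
                if gene not in g.members:
                    g.members.append(gene)
                if len(row) > 3 and row[3].strip():
                    g.sequences[gene] = row[3].strip()
            elif kind == "identity":
                if len(row) < 5:
                    raise ValueError(f"row {ordinal}: identity row needs two genes and a percent")
                gid, a, b = row[1].strip(), row[2].strip(), row[3].strip()
                pct = float(row[4])
                if not 0 <= pct <= 100:
                    raise ValueError(f"row {ordinal}: identity {pct} outside [0, 100]")
                g = groups.setdefault(gid, HomologyGroup(group_id=gid))
                g.identity[(min(a, b), max(a, b))] = pct
            else:
                raise ValueError(f"row {ordinal}: unknown record type {kind!r}")
    out = [groups[g] for g in sorted(groups)]
    for g in out:
        g.complete_identities()
    return out


def infer_relations(
    relations: list[Relation],
    groups: list[HomologyGroup],
    gene_index: GeneIndex,
    threshold_percent: float = DEFAULT_THRESHOLD,
) -> tuple[list[Relation], list[Diagnostic]]:
    """Emit homology-inferred relations for qualifying homolog pairs.

    For each direct relation (c, g) and homolog h of g with identity
    strictly above the threshold, an inferred relation (c, h) is created —
    unless a direct (c, h) exists.  When several parents qualify for one
    (c, h), the highest-identity parent wins (ties: lexicographically
    smaller parent gene id).  Genes missing from the gene index are
    skipped with a diagnostic.
    """
    if not 0 < threshold_percent <= 100:
        raise ValueError("threshold must be in (0, 100]")

    diagnostics: list[Diagnostic] = []
    homologs: dict[str, list[tuple[str, float]]] = {}
    for g in groups:
        for gene in g.members:
            if gene not in gene_index.genes:
                diagnostics.append(
                    Diagnostic(f"homology group {g.group_id}", 0, f"gene {gene} not in gene table")
                )
        for i, a in enumerate(g.members):
            for b in g.members[i + 1 :]:
                pct = g.get_identity(a, b)
                if pct is None or pct <= threshold_percent:
                    continue
                if a in gene_index.genes and b in gene_index.genes:
                    homologs.setdefault(a, []).append((b, pct))
                    homologs.setdefault(b, []).append((a, pct))

    direct_pairs = {
        (r.compound_entry_id, r.gene_id) for r in relations if not r.homology_inferred
    }
    # (compound, homolog) -> (identity, parent gene id, parent relation id)
    best: dict[tuple[str, str], tuple[float, str, str]] = {}
    for rel in relations:
        if rel.homology_inferred:
            continue
        for h, pct in homologs.get(rel.gene_id, []):
            pair = (rel.compound_entry_id, h)
            if pair in direct_pairs:
                continue
            cand = (pct, rel.gene_id, rel.relation_id)
            prev = best.get(pair)
            if prev is None or cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
                best[pair] = cand
    inferred = []
    for (entry_id, h) in sorted(best):
        pct, _, parent_id = best[(entry_id, h)]
        organism = gene_index.genes[h].organism
        inferred.append(
            Relation(
                relation_id=relation_id_for(entry_id, h, inferred=True),
                compound_entry_id=entry_id,
                gene_id=h,
                evidences=[],
                relation_strength="unclassified",
                relation_score=None,
                homology_inferred=True,
                homology_meta=(parent_id, pct, organism),
                source_dbs=frozenset(),
            )
        )
    return inferred, diagnostics
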