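"""Compound entity resolution.

Source databases describe the same chemical under different names, ids and
structure drawings.  Unification partitions all source compound references
into unified entries by an exhaustive search in a strict hierarchy:

1. *structure* — equal canonical keys of the purged structures;
2. *xref*      — explicit cross-references between source entries;
3. *identifier / name* equality, in configurable priority order
   (InChI > InChIKey > CAS > systematic name > brand name > synonym;
   formula matching exists but is off by default — formulas collide
   across constitutional isomers).

A lower-tier criterion never merges two references whose canonical keys
both exist and differ (the structure-conflict veto), so no unified entry
ever contains two distinct structures.  Every merge records the method
that joined the pair, and the entry's unification confidence is the tier
of its weakest merge edge: structure/InChI-backed merges are high
confidence, cross-reference merges medium, name merges low.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from .chem import DEFAULT_RULES, PurgeRules, key_for_structure_text
from .records import RawRecord

#: merge criteria in default priority order, tier 3 of the hierarchy
DEFAULT_IDENTIFIER_PRIORITY: tuple[str, ...] = (
    "inchi",
    "inchikey",
    "cas",
    "name:systematic",
    "name:brand",
    "name:synonym",
)
#: formula matching is available but disabled by default
FORMULA_CRITERION = "formula"

#: confidence tier of each merge-edge method (weakest edge wins per entry)
EDGE_CONFIDENCE = {
    "structure": "high",
    "identifier:inchi": "high",
    "identifier:inchikey": "high",
    "xref": "medium",
    "identifier:cas": "medium",
    "identifier:formula": "low",
    "name": "low",
}
_CONF_RANK = {"high": 0, "medium": 1, "low": 2}


@dataclass
class MergePriority:
    """Ordered tier-3 criteria.  Structure and xref tiers always run first."""

    criteria: tuple[str, ...] = DEFAULT_IDENTIFIER_PRIORITY

    def __post_init__(self) -> None:
        if len(set(self.criteria)) != len(self.criteria):
            raise ValueError("each merge criterion may appear only once")


DEFAULT_PRIORITY = MergePriority()


@dataclass
class CompoundRef:
    """One source compound reference, prepared for unification."""

    ref: tuple[str, str]  # (source_db, local compound id)
    canonical_key: str | None = None
    purged_molblock: str | None = None
    identifiers: dict[str, str] = field(default_factory=dict)
    names: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CompoundEntry:
    """A unified compound: members, merge provenance, confidence."""

    entry_id: str
    canonical_key: str | None
    members: list[tuple[str, str]]
    merge_edges: list[tuple[tuple[str, str], tuple[str, str], str]]
    identifiers: dict[str, list[str]]
    names: list[tuple[str, str]]
    unification_confidence: str = "not_applicable"
    purged_molblock: str | None = None

    @property
    def display_name(self) -> str:
        for wanted in ("systematic", "brand", "synonym"):
            for cls, name in self.names:
                if cls == wanted:
                    return name
        return self.entry_id


def _norm_name(name: str) -> str:
    """Names match case-insensitively with internal whitespace collapsed."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def _norm_identifier(cls: str, value: str) -> str:
    return value.strip().upper() if cls == "inchikey" else value.strip()


def prepare_refs(
    records: list[RawRecord], purge_rules: PurgeRules = DEFAULT_RULES
) -> tuple[list[CompoundRef], list[tuple[tuple[str, str], str]]]:
    """Collapse raw records into one ``CompoundRef`` per source compound.

    Returns the refs plus diagnostics for structures that failed to purge
    or canonicalize (those refs keep their other identifiers and stay
    mergeable through lower tiers).
    """
    by_ref: dict[tuple[str, str], CompoundRef] = {}
    diagnostics: list[tuple[tuple[str, str], str]] = []
    for rec in records:
        cref = by_ref.get(rec.compound_ref)
        if cref is None:
            cref = CompoundRef(ref=rec.compound_ref)
            by_ref[rec.compound_ref] = cref
        d = rec.compound
        if d.structure_text and cref.canonical_key is None:
            try:
                key = key_for_structure_text(d.structure_text, purge_rules)
            except ValueError as exc:
                key = None
                diagnostics.append((rec.compound_ref, str(exc)))
            if key is not None:
                cref.canonical_key = key
                from .chem import mol_from_molblock, mol_to_molblock, purge_structure

                mol = mol_from_molblock(d.structure_text)
                cref.purged_molblock = mol_to_molblock(purge_structure(mol, purge_rules))
            elif cref.purged_molblock is None:
                diagnostics.append((rec.compound_ref, "unparseable structure block"))
        for cls, v in d.identifiers.items():
            cref.identifiers.setdefault(cls, v)
        for cls, name in d.names:
            if (cls, name) not in cref.names:
                cref.names.append((cls, name))
    return sorted(by_ref.values(), key=lambda r: r.ref), diagnostics


class _DSU:
    """Union-find with per-component canonical key and merge-edge log."""

    def __init__(self, refs: list[CompoundRef]):
        self.parent = {r.ref: r.ref for r in refs}
        self.key = {r.ref: r.canonical_key for r in refs}
        self.edges: list[tuple[tuple[str, str], tuple[str, str], str]] = []

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b, method: str) -> bool:
        """Merge the components of a and b unless the structure veto applies."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        ka, kb = self.key[ra], self.key[rb]
        if ka is not None and kb is not None and ka != kb:
            return False  # structure conflict: lower tiers may never bridge it
        if rb < ra:
            ra, rb = rb, ra
            ka, kb = kb, ka
        self.parent[rb] = ra
        self.key[ra] = ka if ka is not None else kb
        self.edges.append((a, b, method))
        return True


def _criterion_groups(refs: list[CompoundRef], criterion: str) -> list[list[tuple[str, str]]]:
    """Refs sharing the criterion's normalized value, grouped and sorted."""
    groups: dict[str, list[tuple[str, str]]] = {}
    if criterion.startswith("name:"):
        wanted = criterion.split(":", 1)[1]
        for r in refs:
            for cls, name in r.names:
                if cls == wanted and name:
                    groups.setdefault(_norm_name(name), []).append(r.ref)
    else:
        for r in refs:
            v = r.identifiers.get(criterion)
            if v:
                groups.setdefault(_norm_identifier(criterion, v), []).append(r.ref)
    out = []
    for value in sorted(groups):
        members = sorted(set(groups[value]))
        if len(members) > 1:
            out.append(members)
    return out


def unify_compounds(
    refs: list[CompoundRef],
    xref_pairs: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    priority: MergePriority = DEFAULT_PRIORITY,
) -> list[CompoundEntry]:
    """Partition compound refs into unified entries (hierarchy + veto).

    The result is invariant under permutation of the input: all grouping
    and pair application happens in sorted order.  Refs not matched by any
    criterion become singleton entries with confidence ``not_applicable``.
    """
    refs = sorted(refs, key=lambda r: r.ref)
    by_ref = {r.ref: r for r in refs}
    dsu = _DSU(refs)

    # tier 1: identical purged structures
    by_key: dict[str, list[tuple[str, str]]] = {}
    for r in refs:
        if r.canonical_key is not None:
            by_key.setdefault(r.canonical_key, []).append(r.ref)
    for key in sorted(by_key):
        members = sorted(by_key[key])
        for other in members[1:]:
            dsu.union(members[0], other, "structure")

    # tier 2: cross-references (table rows plus per-record xref fields)
    links: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    for a, b in xref_pairs or []:
        if a in by_ref and b in by_ref and a != b:
            links.add((min(a, b), max(a, b)))
    for a, b in sorted(links):
        dsu.union(a, b, "xref")

    # tier 3: identifiers and names in priority order
    for criterion in priority.criteria:
        method = "name" if criterion.startswith("name:") else f"identifier:{criterion}"
        for members in _criterion_groups(refs, criterion):
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    dsu.union(members[i], members[j], method)

    # assemble entries
    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for r in refs:
        components.setdefault(dsu.find(r.ref), []).append(r.ref)
    edges_by_root: dict[tuple[str, str], list] = {}
    for a, b, method in dsu.edges:
        edges_by_root.setdefault(dsu.find(a), []).append((a, b, method))

    entries = []
    for root in sorted(components):
        members = sorted(components[root])
        edges = edges_by_root.get(root, [])
        identifiers: dict[str, set[str]] = {}
        names: list[tuple[str, str]] = []
        key = None
        molblock = None
        for m in members:
            r = by_ref[m]
            if r.canonical_key is not None:
                key = r.canonical_key
                if molblock is None:
                    molblock = r.purged_molblock
            for cls, v in r.identifiers.items():
                identifiers.setdefault(cls, set()).add(v)
            for cls, name in r.names:
                if (cls, name) not in names:
                    names.append((cls, name))
        digest = hashlib.sha1("\x1f".join(f"{db}\x1e{i}" for db, i in members).encode()).hexdigest()
        entry = CompoundEntry(
            entry_id=f"C{digest[:12]}",
            canonical_key=key,
            members=members,
            merge_edges=edges,
            identifiers={cls: sorted(vals) for cls, vals in sorted(identifiers.items())},
            names=names,
            purged_molblock=molblock,
        )
        entry.unification_confidence = assign_confidence(entry)
        entries.append(entry)
    return entries


def assign_confidence(entry: CompoundEntry) -> str:
    """Confidence tier of an entry: the weakest of its merge edges.

    Singletons (no merging happened) are ``not_applicable``.
    """
    if not entry.merge_edges:
        return "not_applicable"
    worst = "high"
    for _, _, method in entry.merge_edges:
        tier = EDGE_CONFIDENCE.get(method)
        if tier is None:
            raise ValueError(f"unknown merge method {method!r}")
        if _CONF_RANK[tier] > _CONF_RANK[worst]:
            worst = tier
    return worst
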