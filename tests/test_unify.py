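"""Compound unification: hierarchy, veto, confidence, and oracle equivalence."""
import itertools
import random

import pytest

from ctkb.chem import canonical_key, mol_from_smiles, purge_structure
from ctkb.unify import (
    DEFAULT_PRIORITY,
    CompoundEntry,
    CompoundRef,
    assign_confidence,
    unify_compounds,
)


def ref(refid, key=None, inchikey=None, cas=None, names=(), source="S"):
    identifiers = {}
    if inchikey:
        identifiers["inchikey"] = inchikey
    if cas:
        identifiers["cas"] = cas
    return CompoundRef(
        ref=(source, refid), canonical_key=key, identifiers=identifiers, names=list(names)
    )


def partition_of(entries):
    return {frozenset(e.members) for e in entries}


# ------------------------------------------------------------ examples ----

def test_identical_structures_merge_with_structure_edge():
    entries = unify_compounds([ref("a", key="K1", names=[("brand", "X")]),
                               ref("b", key="K1", names=[("brand", "Y")])])
    assert len(entries) == 1
    assert {m for _, _, m in entries[0].merge_edges} == {"structure"}
    assert entries[0].unification_confidence == "high"


def test_xref_merges_structureless_name_onto_structured_entry():
    # "aspirin" has no structure but is cross-referenced to the structured
    # "acetylsalicylic acid" entry of another source
    refs = [
        ref("asa", key="K1", names=[("systematic", "acetylsalicylic acid")], source="A"),
        ref("asp", names=[("brand", "aspirin")], source="B"),
    ]
    entries = unify_compounds(refs, xref_pairs=[(("B", "asp"), ("A", "asa"))])
    assert len(entries) == 1
    assert {m for _, _, m in entries[0].merge_edges} == {"xref"}
    assert entries[0].unification_confidence == "medium"


def test_shared_synonym_merges_at_low_confidence():
    entries = unify_compounds([ref("a", names=[("synonym", "Painex")]),
                               ref("b", names=[("synonym", "painex")])])  # case-insensitive
    assert len(entries) == 1
    assert entries[0].unification_confidence == "low"
    assert {m for _, _, m in entries[0].merge_edges} == {"name"}


def test_structure_conflict_vetoes_name_merge():
    entries = unify_compounds([ref("a", key="K1", names=[("brand", "Same")]),
                               ref("b", key="K2", names=[("brand", "Same")])])
    assert len(entries) == 2


def test_conflict_veto_confirmed_by_canonical_key_oracle():
    k1 = canonical_key(purge_structure(mol_from_smiles("CCCC")))
    k2 = canonical_key(purge_structure(mol_from_smiles("CC(C)C")))
    assert k1 != k2
    entries = unify_compounds([ref("a", key=k1, names=[("brand", "Twin")]),
                               ref("b", key=k2, names=[("brand", "Twin")])])
    assert len(entries) == 2


def test_unmatched_refs_become_singletons():
    entries = unify_compounds([ref("a", names=[("brand", "X")]),
                               ref("b", names=[("brand", "Y")])])
    assert len(entries) == 2
    assert all(e.unification_confidence == "not_applicable" for e in entries)


def _entry(edges):
    return CompoundEntry(entry_id="E", canonical_key=None, members=[("S", "a"), ("S", "b")],
                         merge_edges=[(("S", "a"), ("S", "b"), m) for m in edges],
                         identifiers={}, names=[])


@pytest.mark.parametrize(
    "edges,expected",
    [
        (["structure", "structure"], "high"),
        (["structure", "xref"], "medium"),
        (["xref", "xref"], "medium"),
        (["structure", "name"], "low"),
        (["xref", "name"], "low"),
        (["name", "name"], "low"),
        (["identifier:inchikey", "structure"], "high"),
        (["identifier:cas", "structure"], "medium"),
        ([], "not_applicable"),
    ],
)
def test_confidence_is_weakest_edge(edges, expected):
    assert assign_confidence(_entry(edges)) == expected


def test_unknown_edge_method_is_error():
    with pytest.raises(ValueError, match="unknown merge method"):
        assign_confidence(_entry(["teleportation"]))


# ---------------------------------------------------- brute-force oracle ----

def oracle_partition(refs, xref_pairs, priority=DEFAULT_PRIORITY):
    """Naive transitive closure respecting the hierarchy and the veto.

    O(n^2) pair scans with explicit component bookkeeping — no union-find,
    no grouping — applied in the same deterministic sorted order.
    """
    import re

    comp = {r.ref: {r.ref} for r in refs}
    key_of = {r.ref: r.canonical_key for r in refs}

    def component_key(c):
        keys = {key_of[m] for m in c if key_of[m] is not None}
        assert len(keys) <= 1
        return next(iter(keys)) if keys else None

    def merge(a, b):
        ca, cb = comp[a], comp[b]
        if ca is cb:
            return
        ka, kb = component_key(ca), component_key(cb)
        if ka is not None and kb is not None and ka != kb:
            return
        union = ca | cb
        for m in union:
            comp[m] = union

    def norm_name(n):
        return re.sub(r"\s+", " ", n.strip()).casefold()

    by_ref = {r.ref: r for r in refs}
    ordered = sorted(by_ref)

    def tier_pairs(match):
        for a, b in itertools.combinations(ordered, 2):
            if match(by_ref[a], by_ref[b]):
                merge(a, b)

    # tier 1: equal canonical keys
    tier_pairs(lambda x, y: x.canonical_key is not None and x.canonical_key == y.canonical_key)
    # tier 2: xrefs
    links = sorted({(min(a, b), max(a, b)) for a, b in xref_pairs
                    if a in by_ref and b in by_ref and a != b})
    for a, b in links:
        merge(a, b)
    # tier 3: identifiers/names in priority order
    for criterion in priority.criteria:
        if criterion.startswith("name:"):
            cls = criterion.split(":", 1)[1]

            def match(x, y, cls=cls):
                xs = {norm_name(n) for c, n in x.names if c == cls}
                ys = {norm_name(n) for c, n in y.names if c == cls}
                return bool(xs & ys)
        else:
            def match(x, y, crit=criterion):
                a, b = x.identifiers.get(crit), y.identifiers.get(crit)
                if a is None or b is None:
                    return False
                if crit == "inchikey":
                    a, b = a.upper(), b.upper()
                return a.strip() == b.strip()
        tier_pairs(match)

    return {frozenset(c) for c in comp.values()}


def random_instance(rng, n):
    keys = [f"K{i}" for i in range(3)]
    sources = ["A", "B"]
    refs = []
    for i in range(n):
        r = CompoundRef(ref=(rng.choice(sources), f"c{i}"))
        if rng.random() < 0.5:
            r.canonical_key = rng.choice(keys)
        if rng.random() < 0.4:
            r.identifiers["inchikey"] = rng.choice(["IKA", "IKB", "ika"])
        if rng.random() < 0.3:
            r.identifiers["cas"] = rng.choice(["1-1", "2-2"])
        for _ in range(rng.randint(0, 2)):
            cls = rng.choice(["systematic", "brand", "synonym"])
            r.names.append((cls, rng.choice(["alpha", " Alpha ", "beta", "gamma"])))
        refs.append(r)
    xrefs = []
    for _ in range(rng.randint(0, n // 2)):
        a, b = rng.sample(refs, 2)
        xrefs.append((a.ref, b.ref))
    return refs, xrefs


def test_matches_brute_force_oracle_on_small_instances():
    rng = random.Random(42)
    for trial in range(60):
        n = rng.randint(2, 12)
        refs, xrefs = random_instance(rng, n)
        entries = unify_compounds(refs, xrefs)
        assert partition_of(entries) == oracle_partition(refs, xrefs), f"trial {trial}"


def test_partition_order_invariance_and_idempotence():
    rng = random.Random(7)
    for _ in range(20):
        refs, xrefs = random_instance(rng, 10)
        entries = unify_compounds(refs, xrefs)
        # partition: every ref in exactly one entry
        all_members = [m for e in entries for m in e.members]
        assert sorted(all_members) == sorted(r.ref for r in refs)
        assert len(set(all_members)) == len(all_members)
        # order invariance (entry ids included, since they hash sorted members)
        shuffled = refs[:]
        rng.shuffle(shuffled)
        entries2 = unify_compounds(shuffled, list(reversed(xrefs)))
        assert {e.entry_id for e in entries} == {e.entry_id for e in entries2}
        assert partition_of(entries) == partition_of(entries2)
        # structure safety: no entry holds two distinct keys
        for e in entries:
            keys = {r.canonical_key for r in refs if r.ref in set(e.members)
                    and r.canonical_key is not None}
            assert len(keys) <= 1
        # idempotence: re-unifying the merged entries reproduces the partition
        merged_refs = []
        for e in entries:
            member_refs = [r for r in refs if r.ref in set(e.members)]
            for r in member_refs:
                merged_refs.append(r)
        assert partition_of(unify_compounds(merged_refs, xrefs)) == partition_of(entries)
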