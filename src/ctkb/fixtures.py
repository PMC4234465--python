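"""Synthetic multi-source fixture generation with known ground truth.

The generator emulates what makes real source-database integration hard:
the same compound shows up in several sources under different local ids,
with cosmetically different structures (counterions, hydrate water,
isotope labels, stereo flags, scrambled atom numbering, duplicated
units), or with the structure dropped entirely and only names,
identifiers or cross-references left.  Every structural perturbation is
reversible by the purge rules, so when structures are present the true
partition is exactly recoverable.  Targets occasionally point at
pathways, pseudogenes or unknown keys to exercise the rejection path.

What it deliberately does *not* emulate: name collisions between distinct
compounds, conflicting cross-references, or realistic chemistry-space
sampling — each true compound has globally unique names, so name-tier
merging is never ambiguous here.

All randomness flows from one integer seed; the same config produces
byte-identical files on every run.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdmolops

from .chem import canonical_key, mol_from_smiles, purge_structure

#: small-molecule library backing the true compounds (all neutral, distinct)
STRUCTURE_LIBRARY: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",   # naproxen
    "Cc1ccccc1",                      # toluene
    "Oc1ccccc1",                      # phenol
    "Nc1ccccc1",                      # aniline
    "CN1CCCC1c1cccnc1",               # nicotine
    "CCO",                            # ethanol
    "OCC(O)CO",                       # glycerol
    "OCC1OC(O)C(O)C(O)C1O",           # a hexose
    "OC(=O)CC(O)(C(=O)O)CC(=O)O",     # citric acid
    "NC(N)=O",                        # urea
    "OC(=O)c1ccccc1O",                # salicylic acid
    "OC(=O)c1ccccc1",                 # benzoic acid
    "CC(C)=O",                        # acetone
    "c1ccncc1",                       # pyridine
    "c1cnc[nH]1",                     # imidazole
    "c1ccc2[nH]ccc2c1",               # indole
    "c1ccc2ccccc2c1",                 # naphthalene
    "c1ccc2cc3ccccc3cc2c1",           # anthracene
    "c1ccoc1",                        # furan
    "c1ccsc1",                        # thiophene
    "C1COCCN1",                       # morpholine
    "C1CCNCC1",                       # piperidine
    "C1CNCCN1",                       # piperazine
    "C1CCCCC1",                       # cyclohexane
    "Nc1ncnc2[nH]cnc12",              # adenine
    "Nc1nc2[nH]cnc2c(=O)[nH]1",       # guanine
    "Cc1c[nH]c(=O)[nH]c1=O",          # thymine
    "Nc1cc[nH]c(=O)n1",               # cytosine
    "O=c1cc[nH]c(=O)[nH]1",           # uracil
    "Oc1ccc(C=CC(=O)O)cc1O",          # caffeic acid
    "COc1cc(C=O)ccc1O",               # vanillin
    "CC(C)C1CCC(C)CC1O",              # menthol
    "CC1(C)C2CCC1(C)C(=O)C2",         # camphor
    "CC(=C)C1CCC(C)=CC1",             # limonene
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",  # warfarin
    "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1",      # diazepam
    "CN(C)C(=N)NC(=N)N",              # metformin
    "Nc1ccc(cc1)S(N)(=O)=O",          # sulfanilamide
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",     # procaine
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",     # lidocaine
    "NCCc1c[nH]c2ccc(O)cc12",         # serotonin
    "NCCc1ccc(O)c(O)c1",              # dopamine
    "NCCc1c[nH]cn1",                  # histamine
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",  # melatonin
    "CCCCCCCCC(=O)O",                 # a fatty acid
    "CCCCCCCCO",                      # an alcohol
)

COUNTERIONS = ("[Na+]", "[Cl-]", "[K+]", "[Br-]")
ORGANISMS = ("Homo sapiens", "Mus musculus", "Rattus norvegicus")
_ACTIVITY_RAWS = (  # (raw type string, needs inhibition context)
    ("IC50", False),
    ("IC 50", False),
    ("Inhibitory Concentration", True),
    ("Ki", False),
    ("Kd", False),
    ("EC50", False),
    ("percent inhibition", False),
)
_MOLAR_UNITS = ("nM", "uM", "µM", "mM", "M", "pM")


@dataclass
class FixtureConfig:
    seed: int = 0
    n_true_compounds: int = 50
    n_sources: int = 3
    p_structure: float = 0.8
    p_xref: float = 0.6
    p_salt: float = 0.2
    p_water: float = 0.15
    p_stereo: float = 0.15
    p_isotope: float = 0.15
    p_polymer: float = 0.1
    p_bad_target: float = 0.05
    p_nonmolar_units: float = 0.1
    n_genes: int = 40
    n_homology_groups: int = 6
    homology_group_size: tuple[int, int] = (2, 4)
    identity_range: tuple[float, float] = (60.0, 99.5)
    homology_threshold: float = 80.0
    max_relations_per_record: int = 2
    log_molar_range: tuple[float, float] = (-9.5, -3.5)
    evidence_class_weights: dict[str, float] = field(
        default_factory=lambda: {"measured": 0.6, "predicted": 0.2, "curated": 0.1, "textual": 0.1}
    )

    def __post_init__(self) -> None:
        for name in ("p_structure", "p_xref", "p_salt", "p_water", "p_stereo",
                     "p_isotope", "p_polymer", "p_bad_target", "p_nonmolar_units"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_true_compounds < 1 or self.n_sources < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.p_xref > 0 and self.n_sources < 2:
            raise ValueError("cross-references need at least two sources")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    #: compound ref (source_db, local_id) -> true compound index
    partition: dict[tuple[str, str], int] = field(default_factory=dict)
    #: (true compound index, gene_id) pairs from surviving (mappable) records
    direct_pairs: set[tuple[int, str]] = field(default_factory=set)
    #: expected homology-inferred pairs at the configured threshold
    inferred_pairs: set[tuple[int, str]] = field(default_factory=set)
    #: number of emitted source records whose target is mappable
    n_mappable_records: int = 0
    #: total emitted source records
    n_records: int = 0


def _structures(n: int) -> list[Chem.Mol]:
    """n distinct neutral structures: the library plus simple homolog series."""
    keys: set[str] = set()
    mols: list[Chem.Mol] = []
    candidates = list(STRUCTURE_LIBRARY)
    # overflow: branched secondary alcohols CH3(CH2)i-CH(OH)-(CH2)j-H, one
    # molecule per unordered branch-length pair — thousands of distinct
    # skeletons while staying small
    for i in range(1, 81):
        if len(candidates) >= n * 2:
            break
        for j in range(i, 81):
            candidates.append(f"{'C' * i}C({'C' * j})O")
            if len(candidates) >= n * 2:
                break
    for smi in candidates:
        mol = mol_from_smiles(smi)
        if mol is None:
            continue
        key = canonical_key(purge_structure(mol))
        if key in keys:
            continue
        keys.add(key)
        mols.append(mol)
        if len(mols) == n:
            return mols
    raise ValueError(f"cannot supply {n} distinct structures")


def _perturb(mol: Chem.Mol, cfg: FixtureConfig, rng: random.Random) -> Chem.Mol:
    """Apply purge-reversible noise to a structure."""
    mol = Chem.Mol(mol)
    if rng.random() < cfg.p_isotope:
        atoms = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
        if atoms:
            rng.choice(atoms).SetIsotope(13)
    if rng.random() < cfg.p_stereo:
        atoms = [a for a in mol.GetAtoms() if a.GetDegree() >= 3]
        if atoms:
            rng.choice(atoms).SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    if rng.random() < cfg.p_polymer:
        mol = Chem.CombineMols(mol, mol)
    if rng.random() < cfg.p_salt:
        ion = mol_from_smiles(rng.choice(COUNTERIONS))
        mol = Chem.CombineMols(mol, ion)
    if rng.random() < cfg.p_water:
        mol = Chem.CombineMols(mol, mol_from_smiles("O"))
    perm = list(range(mol.GetNumAtoms()))
    rng.shuffle(perm)
    return rdmolops.RenumberAtoms(mol, perm)


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    items = sorted(weights.items())
    return rng.choices([k for k, _ in items], [w for _, w in items])[0]


def generate_fixture(cfg: FixtureConfig, out_dir: str | Path) -> GroundTruth:
    """Write a complete fixture corpus and return its ground truth.

    Emits source files in the three dialects (cycling sdf/tsv/xml across
    sources), the gene index, the compound cross-reference table, the
    homology table, a build config for the CLI, and the ground truth
    (partition TSV plus a JSON summary).
    """
    rng = random.Random(cfg.seed)
    out = Path(out_dir)
    (out / "sources").mkdir(parents=True, exist_ok=True)

    mols = _structures(cfg.n_true_compounds)
    truth = GroundTruth()

    # ---- genes -----------------------------------------------------------
    gene_ids = [f"G{j:04d}" for j in range(cfg.n_genes)]
    organisms = {g: ORGANISMS[j % len(ORGANISMS)] for j, g in enumerate(gene_ids)}
    sources = [f"SRC{s}" for s in range(cfg.n_sources)]
    gene_rows = []
    for j, g in enumerate(gene_ids):
        for src in sources:
            gene_rows.append((f"NS_{src}", f"{src}_g{j}", g, f"GENE{j}", organisms[g], "protein_coding"))
    # a handful of traps: a pseudogene, and one ambiguous key per fixture
    gene_rows.append(("NS_SRC0", "SRC0_pseudo", "GP999", "PSEUDO1", ORGANISMS[0], "pseudogene"))
    gene_rows.append(("NS_SRC0", "SRC0_ambig", "G0000", "GENE0", organisms["G0000"], "protein_coding"))
    gene_rows.append(("NS_SRC0", "SRC0_ambig", "G0001", "GENE1", organisms["G0001"], "protein_coding"))
    with open(out / "gene_index.tsv", "w", encoding="utf-8") as fh:
        fh.write("namespace\tforeign_id\tgene_id\tsymbol\torganism\tgene_type\n")
        for row in gene_rows:
            fh.write("\t".join(row) + "\n")

    # ---- homology groups -------------------------------------------------
    pool = gene_ids[:]
    rng.shuffle(pool)
    groups: list[tuple[str, list[str], dict[tuple[str, str], float]]] = []
    lo, hi = cfg.homology_group_size
    for gi in range(cfg.n_homology_groups):
        size = rng.randint(lo, hi)
        if len(pool) < size:
            break
        members = sorted(pool[:size])
        pool = pool[size:]
        ident = {}
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pct = round(rng.uniform(*cfg.identity_range), 1)
                ident[(members[i], members[j])] = pct
        groups.append((f"HG{gi:03d}", members, ident))
    with open(out / "homology.tsv", "w", encoding="utf-8") as fh:
        fh.write("record_type\tgroup_id\tgene_or_pair\tgene_b_or_seq\tpercent\n")
        for gid, members, ident in groups:
            for g in members:
                fh.write(f"member\t{gid}\t{g}\t\t\n")
            for (a, b), pct in sorted(ident.items()):
                fh.write(f"identity\t{gid}\t{a}\t{b}\t{pct:g}\n")
    homolog_pairs: dict[str, list[tuple[str, float]]] = {}
    for _, members, ident in groups:
        for (a, b), pct in ident.items():
            if pct > cfg.homology_threshold:
                homolog_pairs.setdefault(a, []).append((b, pct))
                homolog_pairs.setdefault(b, []).append((a, pct))

    # ---- compound records ------------------------------------------------
    names = {
        i: {
            "systematic": f"compound-{i:04d}",
            "brand": f"Brand{i}",
            "synonym": f"cmpd {i} alias",
        }
        for i in range(cfg.n_true_compounds)
    }
    inchikeys = {}
    for i, mol in enumerate(mols):
        try:
            inchikeys[i] = Chem.MolToInchiKey(purge_structure(mol))
        except Exception:
            inchikeys[i] = ""
    cas = {i: f"{10000 + i}-{i % 100:02d}-{i % 10}" for i in range(cfg.n_true_compounds)}

    per_source_records: dict[str, list[dict]] = {src: [] for src in sources}
    xref_rows: list[tuple[str, str, str, str]] = []
    rel_counter = {src: 0 for src in sources}

    for i in range(cfg.n_true_compounds):
        k = rng.randint(1, cfg.n_sources)
        chosen = sorted(rng.sample(sources, k))
        emitted_refs: list[tuple[tuple[str, str], bool]] = []  # (ref, has_structure)
        for src in chosen:
            local_id = f"{src}_c{i}"
            ref = (src, local_id)
            has_structure = rng.random() < cfg.p_structure
            truth.partition[ref] = i

            compound: dict = {"local_id": local_id}
            if has_structure:
                compound["mol"] = _perturb(mols[i], cfg, rng)
                compound["names"] = {"systematic": names[i]["systematic"]}
            else:
                structured = [r for r, s in emitted_refs if s]
                linked = False
                if structured and rng.random() < cfg.p_xref:
                    other = rng.choice(structured)
                    xref_rows.append((src, local_id, other[0], other[1]))
                    linked = True
                compound["names"] = dict(names[i]) if rng.random() < 0.7 else {
                    "synonym": names[i]["synonym"]
                }
                if not linked and rng.random() < 0.5 and inchikeys[i]:
                    compound["inchikey"] = inchikeys[i]
                if rng.random() < 0.3:
                    compound["cas"] = cas[i]
            emitted_refs.append((ref, has_structure))

            n_rel = rng.randint(1, cfg.max_relations_per_record)
            genes = rng.sample(gene_ids, n_rel)
            for g in genes:
                rel_counter[src] += 1
                rid = f"{src}-r{rel_counter[src]:05d}"
                j = gene_ids.index(g)
                target = {
                    "namespace": f"NS_{src}",
                    "foreign_id": f"{src}_g{j}",
                    "label": f"GENE{j}",
                    "target_class": "protein",
                    "organism": organisms[g],
                }
                mappable = True
                if rng.random() < cfg.p_bad_target:
                    trap = rng.choice(["pathway", "disease", "unknown", "pseudo", "ambig"])
                    mappable = False
                    if trap in ("pathway", "disease"):
                        target["target_class"] = trap
                    elif trap == "unknown":
                        target["foreign_id"] = f"{src}_missing{rng.randint(0, 999)}"
                    elif trap == "pseudo":
                        target = dict(target, namespace="NS_SRC0", foreign_id="SRC0_pseudo")
                    else:
                        target = dict(target, namespace="NS_SRC0", foreign_id="SRC0_ambig")

                raw_type, needs_inhibition = rng.choice(_ACTIVITY_RAWS)
                evidence: dict = {
                    "evidence_class": _weighted_choice(rng, cfg.evidence_class_weights),
                    "reference": f"PMID:{rng.randint(10_000_000, 29_999_999)}",
                    "inhibition": needs_inhibition or rng.random() < 0.3,
                }
                if raw_type == "percent inhibition":
                    evidence.update(activity_type=raw_type,
                                    activity_value=round(rng.uniform(1, 100), 1),
                                    activity_units="%")
                elif rng.random() < 0.85:  # some evidences carry no value at all
                    log_molar = rng.uniform(*cfg.log_molar_range)
                    if rng.random() < cfg.p_nonmolar_units:
                        units = "mg/mL"
                        value = round(10 ** rng.uniform(-3, 1), 4)
                    else:
                        units = rng.choice(_MOLAR_UNITS)
                        factor = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "mM": 1e-3,
                                  "M": 1.0, "pM": 1e-12}[units]
                        value = round(10 ** log_molar / factor, 6)
                        if value <= 0:
                            value = 1e-6
                    evidence.update(activity_type=raw_type, activity_value=value,
                                    activity_units=units)

                per_source_records[src].append(
                    {"relation_id": rid, "compound": compound, "target": target,
                     "evidence": evidence}
                )
                truth.n_records += 1
                if mappable:
                    truth.n_mappable_records += 1
                    truth.direct_pairs.add((i, g))

    # ---- expected homology inference ------------------------------------
    by_compound: dict[int, set[str]] = {}
    for c, g in truth.direct_pairs:
        by_compound.setdefault(c, set()).add(g)
    for c, gset in by_compound.items():
        for g in gset:
            for h, pct in homolog_pairs.get(g, []):
                if h not in gset:
                    truth.inferred_pairs.add((c, h))

    # ---- write source files in the three dialects ------------------------
    source_cfgs = []
    for s, src in enumerate(sources):
        fmt = ("sdf", "tsv", "xml")[s % 3]
        path = out / "sources" / f"{src.lower()}.{fmt}"
        recs = per_source_records[src]
        if fmt == "sdf":
            _write_sdf(path, recs)
        elif fmt == "tsv":
            _write_tsv(path, recs)
        else:
            _write_xml(path, src, recs)
        source_cfgs.append({"path": f"sources/{path.name}", "format": fmt, "source_db": src})

    with open(out / "xrefs.tsv", "w", encoding="utf-8") as fh:
        fh.write("source_db_a\tcompound_id_a\tsource_db_b\tcompound_id_b\n")
        for row in sorted(xref_rows):
            fh.write("\t".join(row) + "\n")

    _write_build_config(out / "build_config.yaml", source_cfgs, cfg)

    with open(out / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("source_db\tlocal_id\ttrue_compound\n")
        for (db, lid), i in sorted(truth.partition.items()):
            fh.write(f"{db}\t{lid}\t{i}\n")
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "n_records": truth.n_records,
                "n_mappable_records": truth.n_mappable_records,
                "n_true_compounds": cfg.n_true_compounds,
                "direct_pairs": sorted([c, g] for c, g in truth.direct_pairs),
                "inferred_pairs": sorted([c, g] for c, g in truth.inferred_pairs),
            },
            indent=1,
        )
    )
    return truth


_SDF_FIELDS = {
    "relation_id": "RELATION_ID",
    "compound_id": "COMPOUND_ID",
    "name_systematic": "NAME",
    "name_brand": "NAME_BRAND",
    "name_synonym": "NAME_SYNONYM",
    "inchikey": "INCHIKEY",
    "cas": "CAS",
    "target_namespace": "TARGET_NS",
    "target_id": "TARGET_ID",
    "target_label": "TARGET_NAME",
    "target_class": "TARGET_CLASS",
    "organism": "ORGANISM",
    "activity_type": "ACTIVITY_TYPE",
    "activity_value": "ACTIVITY_VALUE",
    "activity_units": "ACTIVITY_UNITS",
    "evidence_class": "EVIDENCE_CLASS",
    "inhibition": "INHIBITION",
    "reference": "REFERENCE",
}


def _record_fields(rec: dict) -> dict[str, str]:
    c, t, e = rec["compound"], rec["target"], rec["evidence"]
    out = {
        "relation_id": rec["relation_id"],
        "compound_id": c["local_id"],
        "target_namespace": t["namespace"],
        "target_id": t["foreign_id"],
        "target_label": t["label"],
        "target_class": t["target_class"],
        "organism": t["organism"],
        "evidence_class": e["evidence_class"],
        "inhibition": "true" if e.get("inhibition") else "false",
        "reference": e.get("reference", ""),
    }
    for cls, fieldname in (("systematic", "name_systematic"), ("brand", "name_brand"),
                           ("synonym", "name_synonym")):
        if cls in c.get("names", {}):
            out[fieldname] = c["names"][cls]
    for ident in ("inchikey", "cas"):
        if ident in c:
            out[ident] = c[ident]
    if "activity_type" in e:
        out["activity_type"] = e["activity_type"]
        out["activity_value"] = f"{e['activity_value']:.6g}"
        out["activity_units"] = e["activity_units"]
    return out


def _write_sdf(path: Path, recs: list[dict]) -> None:
    chunks = []
    for rec in recs:
        mol = rec["compound"].get("mol")
        block = Chem.MolToMolBlock(mol if mol is not None else Chem.Mol(), kekulize=True)
        buf = [block.rstrip("\n")]
        fields = _record_fields(rec)
        for logical, value in fields.items():
            buf.append(f">  <{_SDF_FIELDS[logical]}>\n{value}\n")
        chunks.append("\n".join(buf) + "\n$$$$\n")
    path.write_text("".join(chunks), encoding="utf-8")


def _write_tsv(path: Path, recs: list[dict]) -> None:
    columns = ["relation_id", "compound_id", "structure", "name_systematic", "name_brand",
               "name_synonym", "inchikey", "cas", "target_namespace", "target_id",
               "target_label", "target_class", "organism", "activity_type",
               "activity_value", "activity_units", "evidence_class", "inhibition",
               "reference"]
    lines = ["\t".join(columns)]
    for rec in recs:
        fields = _record_fields(rec)
        mol = rec["compound"].get("mol")
        if mol is not None:
            fields["structure"] = Chem.MolToSmiles(mol, canonical=False)
        lines.append("\t".join(fields.get(c, "") for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_xml(path: Path, src: str, recs: list[dict]) -> None:
    from lxml import etree

    root = etree.Element("relations")
    for rec in recs:
        c, t, e = rec["compound"], rec["target"], rec["evidence"]
        rel = etree.SubElement(root, "relation", source_db=src, id=rec["relation_id"])
        c_el = etree.SubElement(rel, "compound", local_id=c["local_id"])
        mol = c.get("mol")
        if mol is not None:
            s = etree.SubElement(c_el, "structure")
            s.text = etree.CDATA("\n" + Chem.MolToMolBlock(mol, kekulize=True))
        for cls, name in c.get("names", {}).items():
            n_el = etree.SubElement(c_el, "name")
            n_el.set("class", cls)
            n_el.text = name
        for ident in ("inchikey", "cas"):
            if ident in c:
                i_el = etree.SubElement(c_el, "identifier")
                i_el.set("class", ident)
                i_el.text = c[ident]
        t_el = etree.SubElement(rel, "target", namespace=t["namespace"],
                                foreign_id=t["foreign_id"], organism=t["organism"])
        t_el.set("class", t["target_class"])
        t_el.text = t["label"]
        ev = etree.SubElement(rel, "evidence")
        ev.set("class", e["evidence_class"])
        ev.set("inhibition", "true" if e.get("inhibition") else "false")
        if "activity_type" in e:
            etree.SubElement(ev, "activity", type=e["activity_type"],
                             value=f"{e['activity_value']:.6g}", units=e["activity_units"])
        if e.get("reference"):
            etree.SubElement(ev, "reference").text = e["reference"]
    path.write_bytes(etree.tostring(root, pretty_print=True))


def _write_build_config(path: Path, source_cfgs: list[dict], cfg: FixtureConfig) -> None:
    import yaml

    sdf_fields = {tag: logical for logical, tag in _SDF_FIELDS.items()}
    tsv_fields = {c: c for c in
                  ["relation_id", "compound_id", "structure", "name_systematic", "name_brand",
                   "name_synonym", "inchikey", "cas", "target_namespace", "target_id",
                   "target_label", "target_class", "organism", "activity_type",
                   "activity_value", "activity_units", "evidence_class", "inhibition",
                   "reference"]}
    doc = {
        "sources": [
            dict(sc, fields=(sdf_fields if sc["format"] == "sdf"
                             else tsv_fields if sc["format"] == "tsv" else {}))
            for sc in source_cfgs
        ],
        "gene_index": "gene_index.tsv",
        "xrefs": "xrefs.tsv",
        "homology": "homology.tsv",
        "homology_threshold": cfg.homology_threshold,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ------------------------------------------------------------- scoring ----

def score_resolution(
    result: dict[tuple[str, str], object], truth: dict[tuple[str, str], object]
) -> tuple[float, float]:
    """Pairwise precision/recall of a predicted partition against truth.

    Both arguments map record refs to cluster labels and must cover the
    same refs.  Precision is 1.0 when no pairs are predicted; recall is
    1.0 when the truth has no pairs.  Both are 1.0 iff the partitions are
    identical as partitions.
    """
    if set(result) != set(truth):
        raise ValueError("partitions cover different record sets")
    refs = sorted(result)
    tp = fp = fn = 0
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            a, b = refs[i], refs[j]
            same_pred = result[a] == result[b]
            same_true = truth[a] == truth[b]
            if same_pred and same_true:
                tp += 1
            elif same_pred:
                fp += 1
            elif same_true:
                fn += 1
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall
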