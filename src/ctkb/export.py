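"""Serialize query results: TSV, relation XML, SDF, and per-compound mol files.

The XML dialect written here is the same one :mod:`ctkb.ingest` reads, so
an exported result set can be re-imported losslessly (round trip).  SDF
export writes one record per *distinct compound* among the selected
relations, with the relation and evidence data attached as SDF data
fields; TSV writes one row per relation with a configurable column set.
Homology-inferred relations are flagged explicitly (a ``*`` suffix on the
relation id, mirroring the asterisk convention of relation browsers, plus
the selectable "Homology Inferred" column).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

from lxml import etree
from rdkit import Chem

from .chem import mol_from_molblock
from .kb import KnowledgeBase
from .records import Diagnostic
from .relations import Relation

#: the default result-table columns
DEFAULT_COLUMNS = (
    "Relation ID",
    "Compound",
    "Gene Symbol",
    "Organism Name",
    "Relation Strength",
    "Evidences",
)

_COLUMN_GETTERS = {
    "Relation ID": lambda r, kb: r.relation_id + ("*" if r.homology_inferred else ""),
    "Compound": lambda r, kb: kb.compound_for(r).display_name,
    "Compound Entry ID": lambda r, kb: r.compound_entry_id,
    "SMILES": lambda r, kb: kb.compound_for(r).canonical_key or "",
    "InChIKey": lambda r, kb: ";".join(kb.compound_for(r).identifiers.get("inchikey", [])),
    "Entrez Gene ID": lambda r, kb: r.gene_id,
    "Gene Symbol": lambda r, kb: kb.gene_for(r).symbol,
    "Organism Name": lambda r, kb: kb.gene_for(r).organism,
    "Relation Strength": lambda r, kb: r.relation_strength,
    "Relation Score": lambda r, kb: "" if r.relation_score is None else str(r.relation_score),
    "Source Database": lambda r, kb: ";".join(sorted(r.source_dbs)),
    "Homology Inferred": lambda r, kb: "true" if r.homology_inferred else "false",
    "Homolog Similarity": lambda r, kb: f"{r.homology_meta[1]:g}" if r.homology_meta else "",
    "Unification Confidence": lambda r, kb: kb.compound_for(r).unification_confidence,
    "Evidences": None,  # handled specially below
}


@dataclass
class ColumnSelection:
    columns: tuple[str, ...] = DEFAULT_COLUMNS

    def __post_init__(self) -> None:
        unknown = [c for c in self.columns if c not in _COLUMN_GETTERS]
        if unknown:
            raise ValueError(f"unknown column name(s): {unknown}")


def _evidence_summary(r: Relation) -> str:
    """One-cell summary: standardized SI value first, original behind it."""
    if r.homology_inferred and r.homology_meta:
        parent, pct, org = r.homology_meta
        return f"homology-inferred from {parent} ({pct:g}% identity, {org})"
    parts = []
    for e in r.evidences:
        t_raw, v_raw, u_raw = e.original
        bits = [e.activity_type]
        if e.value_si is not None:
            si = f"{e.value_si:g} M"
            if e.converted_flag:
                si = f"SI:{si} (orig {v_raw:g} {u_raw})"
            bits.append(si)
        elif v_raw is not None:
            bits.append(f"{v_raw:g} {u_raw or ''}".strip())
        bits.append(f"strength={e.strength}")
        bits.append(f"score={e.reliability}")
        bits.append(f"src={e.source_db}:{e.source_relation_id}")
        parts.append(" ".join(bits))
    return " | ".join(parts)


def _cell(column: str, r: Relation, kb: KnowledgeBase) -> str:
    if column == "Evidences":
        return _evidence_summary(r)
    return _COLUMN_GETTERS[column](r, kb)


def _write(path: Path, text: str, compress: bool) -> None:
    if compress:
        with gzip.open(str(path) + ".gz", "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        path.write_text(text, encoding="utf-8")


# ----------------------------------------------------------------- TSV ----

def export_tsv(
    relation_ids: list[str],
    kb: KnowledgeBase,
    path: str | Path,
    columns: ColumnSelection | None = None,
    compress: bool = False,
) -> None:
    columns = columns or ColumnSelection()
    lines = ["\t".join(columns.columns)]
    for rid in relation_ids:
        r = kb.relations[rid]
        lines.append("\t".join(_cell(c, r, kb).replace("\t", " ") for c in columns.columns))
    _write(Path(path), "\n".join(lines) + "\n", compress)


# ----------------------------------------------------------------- XML ----

def relation_to_xml_element(r: Relation, kb: KnowledgeBase, evidence_index: int = 0):
    """One exported ``<relation>`` element per evidence of a relation."""
    e = r.evidences[evidence_index]
    comp = kb.compound_for(r)
    gene = kb.gene_for(r)
    rel = etree.Element("relation", source_db=e.source_db, id=e.source_relation_id)
    c_el = etree.SubElement(rel, "compound")
    c_el.set("local_id", f"{r.compound_entry_id}")
    if comp.purged_molblock:
        s = etree.SubElement(c_el, "structure")
        s.text = etree.CDATA("\n" + comp.purged_molblock)
    for cls, vals in comp.identifiers.items():
        for v in vals:
            i_el = etree.SubElement(c_el, "identifier")
            i_el.set("class", cls)
            i_el.text = v
    for cls, name in comp.names:
        n_el = etree.SubElement(c_el, "name")
        n_el.set("class", cls)
        n_el.text = name
    t_el = etree.SubElement(
        rel,
        "target",
        namespace="ctkb",
        foreign_id=r.gene_id,
        organism=gene.organism,
    )
    t_el.set("class", "protein" if gene.gene_type == "protein_coding" else "nucleotide")
    t_el.text = gene.symbol
    ev_el = etree.SubElement(rel, "evidence")
    ev_el.set("class", e.evidence_class)
    if e.refers_to_inhibition:
        ev_el.set("inhibition", "true")
    t_raw, v_raw, u_raw = e.original
    if t_raw is not None:
        act = etree.SubElement(ev_el, "activity", type=t_raw)
        if v_raw is not None:
            act.set("value", repr(v_raw))
        if u_raw is not None:
            act.set("units", u_raw)
        if e.value_si is not None:
            act.set("value_si", repr(e.value_si))
            act.set("converted", "true" if e.converted_flag else "false")
    if e.reference:
        etree.SubElement(ev_el, "reference").text = e.reference
    if e.assay_description:
        etree.SubElement(ev_el, "assay").text = e.assay_description
    if r.homology_inferred and r.homology_meta:
        parent, pct, org = r.homology_meta
        etree.SubElement(
            rel, "homology", parent=parent, identity=f"{pct:g}", organism=org
        )
    return rel


def export_xml(
    relation_ids: list[str],
    kb: KnowledgeBase,
    path: str | Path,
    compress: bool = False,
) -> None:
    """Write the relation XML dialect (re-ingestable by ``read_xml_source``).

    Direct relations emit one ``<relation>`` element per evidence — each
    element is one source assertion, exactly what the reader expects.
    Inferred relations (no evidences) emit a single element flagged with a
    ``<homology>`` child and an ``inferred`` attribute.
    """
    root = etree.Element("relations")
    for rid in relation_ids:
        r = kb.relations[rid]
        if r.evidences:
            for i in range(len(r.evidences)):
                root.append(relation_to_xml_element(r, kb, i))
        else:
            rel = etree.SubElement(root, "relation", source_db="ctkb", id=r.relation_id)
            rel.set("inferred", "true")
            comp = kb.compound_for(r)
            c_el = etree.SubElement(rel, "compound", local_id=r.compound_entry_id)
            for cls, name in comp.names:
                n_el = etree.SubElement(c_el, "name")
                n_el.set("class", cls)
                n_el.text = name
            if not comp.names and comp.canonical_key:
                i_el = etree.SubElement(c_el, "identifier")
                i_el.set("class", "smiles")
                i_el.text = comp.canonical_key
            gene = kb.gene_for(r)
            t_el = etree.SubElement(
                rel, "target", namespace="ctkb", foreign_id=r.gene_id, organism=gene.organism
            )
            t_el.text = gene.symbol
            ev_el = etree.SubElement(rel, "evidence")
            ev_el.set("class", "predicted")
            if r.homology_meta:
                parent, pct, org = r.homology_meta
                etree.SubElement(
                    rel, "homology", parent=parent, identity=f"{pct:g}", organism=org
                )
    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    _write(Path(path), text, compress)


# ----------------------------------------------------------------- SDF ----

def export_sdf(
    relation_ids: list[str],
    kb: KnowledgeBase,
    path: str | Path,
    include_structure: bool = True,
    compress: bool = False,
) -> list[Diagnostic]:
    """Write one SDF record per distinct compound among the relations.

    Relation/evidence data ride along as SDF data fields.  A structureless
    compound is emitted with an empty structure block and reported in the
    returned diagnostics.
    """
    by_compound: dict[str, list[Relation]] = {}
    for rid in relation_ids:
        r = kb.relations[rid]
        by_compound.setdefault(r.compound_entry_id, []).append(r)

    diagnostics: list[Diagnostic] = []
    chunks: list[str] = []
    for i, entry_id in enumerate(sorted(by_compound)):
        comp = kb.compounds[entry_id]
        mol = None
        if include_structure and comp.purged_molblock:
            mol = mol_from_molblock(comp.purged_molblock)
        if mol is None:
            mol = Chem.Mol()  # empty structure block
            if include_structure:
                diagnostics.append(
                    Diagnostic(str(path), i, f"compound {entry_id} has no structure")
                )
        mol.SetProp("_Name", comp.display_name)
        block = Chem.MolToMolBlock(mol, kekulize=True)
        fields = {
            "CTKB_COMPOUND_ID": entry_id,
            "CTKB_NAMES": " | ".join(f"{cls}:{n}" for cls, n in comp.names),
            "CTKB_CONFIDENCE": comp.unification_confidence,
            "CTKB_RELATIONS": " | ".join(
                f"{r.relation_id}{'*' if r.homology_inferred else ''}"
                f" gene={r.gene_id} strength={r.relation_strength}"
                for r in sorted(by_compound[entry_id], key=lambda x: x.relation_id)
            ),
            "CTKB_EVIDENCES": " | ".join(
                _evidence_summary(r)
                for r in sorted(by_compound[entry_id], key=lambda x: x.relation_id)
            ),
        }
        for cls, vals in comp.identifiers.items():
            fields[f"CTKB_{cls.upper()}"] = " | ".join(vals)
        buf = [block.rstrip("\n")]
        for tag, value in fields.items():
            if value:
                buf.append(f">  <{tag}>\n{value}\n")
        chunks.append("\n".join(buf) + "\n$$$$\n")
    _write(Path(path), "".join(chunks), compress)
    return diagnostics


def export_mol(entry) -> str:
    """V2000 molfile text of a unified compound's purged structure."""
    if not entry.purged_molblock:
        raise ValueError(f"compound {entry.entry_id} has no structure")
    return entry.purged_molblock


def export_results(
    relation_ids: list[str],
    kb: KnowledgeBase,
    path: str | Path,
    format: str = "tsv",
    columns: ColumnSelection | None = None,
    include_structure: bool = True,
    compress: bool = False,
) -> list[Diagnostic]:
    """Dispatch to the requested export format."""
    missing = [rid for rid in relation_ids if rid not in kb.relations]
    if missing:
        raise KeyError(f"relation id(s) not in knowledge base: {missing[:5]}")
    if format == "tsv":
        export_tsv(relation_ids, kb, path, columns, compress)
        return []
    if format == "xml":
        export_xml(relation_ids, kb, path, compress)
        return []
    if format == "sdf":
        return export_sdf(relation_ids, kb, path, include_structure, compress)
    raise ValueError(f"unknown export format {format!r}")
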