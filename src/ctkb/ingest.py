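"""Readers for the three source-database dialects plus the reference tables.

Heterogeneous source dumps arrive in one of three documented dialects —
SDF with data fields (V2000), delimited tables with a header row, or a
small relation XML schema — each with a per-source field-mapping config
that names which tag/column feeds which logical record field.  Every
reader yields ``RawRecord`` streams plus ``Diagnostic`` objects for items
it had to skip; record count + diagnostic count always equals the input
record count, and no reader ever invents a value.

Logical fields a mapping may target:

===================  ====================================================
``relation_id``       unique id of the assertion within its source
``compound_id``       the compound's local id in the source
``name_systematic`` / ``name_brand`` / ``name_synonym``
                      compound names ("|"-separated for multiple)
``inchi`` ``inchikey`` ``smiles`` ``cas`` ``formula``
                      compound identifiers
``xrefs``             cross-references, "db:id|db:id"
``structure``         (tables only) an inline SMILES parsed as structure
``target_namespace`` ``target_id`` ``target_label`` ``target_class``
``organism``          target descriptor fields
``activity_type`` ``activity_value`` ``activity_units``
``evidence_class``    predicted|measured|curated|textual
``inhibition``        "true"/"false": evidence refers to inhibition
``reference`` ``assay_description``
===================  ====================================================
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from lxml import etree

from .records import (
    CompoundDescriptor,
    Diagnostic,
    EvidencePayload,
    RawRecord,
    TargetDescriptor,
)

NAME_FIELDS = {"name_systematic": "systematic", "name_brand": "brand", "name_synonym": "synonym"}
IDENTIFIER_FIELDS = ("inchi", "inchikey", "smiles", "cas", "formula")


@dataclass
class SourceConfig:
    """Per-source dialect configuration.

    ``fields`` maps the tag/column name *in the file* to a logical field
    name from the table above.  Unmapped tags are ignored.
    """

    source_db: str
    format: str = "tsv"  # sdf | tsv | xml
    delimiter: str = "\t"
    fields: dict[str, str] = field(default_factory=dict)


def _fields_to_record(
    source_db: str, values: dict[str, str], structure_text: str | None
) -> RawRecord:
    """Assemble a RawRecord from logical-field values (already trimmed)."""
    relation_id = values.get("relation_id")
    if not relation_id:
        raise ValueError("record has no relation_id")

    identifiers = {cls: values[cls] for cls in IDENTIFIER_FIELDS if values.get(cls)}
    names: list[tuple[str, str]] = []
    for fld, cls in NAME_FIELDS.items():
        if values.get(fld):
            names.extend((cls, n.strip()) for n in values[fld].split("|") if n.strip())
    xrefs: list[tuple[str, str]] = []
    if values.get("xrefs"):
        for token in values["xrefs"].split("|"):
            token = token.strip()
            if not token:
                continue
            db, _, fid = token.partition(":")
            if not fid:
                raise ValueError(f"malformed xref token {token!r}, expected db:id")
            xrefs.append((db, fid))

    compound = CompoundDescriptor(
        structure_text=structure_text,
        identifiers=identifiers,
        names=names,
        xrefs=xrefs,
        local_id=values.get("compound_id"),
    )
    target = TargetDescriptor(
        namespace=values.get("target_namespace") or source_db,
        foreign_id=values.get("target_id") or "",
        label=values.get("target_label") or "",
        target_class=values.get("target_class") or "protein",
        organism=values.get("organism") or "",
    )
    value_raw = None
    if values.get("activity_value"):
        value_raw = float(values["activity_value"])
    evidence = EvidencePayload(
        activity_type_raw=values.get("activity_type"),
        activity_value_raw=value_raw,
        activity_units_raw=values.get("activity_units"),
        evidence_class=values.get("evidence_class") or "measured",
        reference=values.get("reference") or "",
        assay_description=values.get("assay_description") or "",
    )
    record = RawRecord(
        source_db=source_db,
        source_relation_id=relation_id,
        compound=compound,
        target=target,
        evidence=evidence,
    )
    # evidence context flag rides along for the standardization stage
    record.refers_to_inhibition = values.get("inhibition", "").lower() == "true"
    return record


def _map_values(raw: dict[str, str], cfg: SourceConfig) -> dict[str, str]:
    out: dict[str, str] = {}
    for file_key, logical in cfg.fields.items():
        v = raw.get(file_key)
        if v is not None:
            v = v.strip()
            if v:
                out[logical] = v
    return out


# ---------------------------------------------------------------- SDF ----

def _split_sdf_records(text: str) -> list[str]:
    """Frame an SDF into per-record chunks on the ``$$$$`` delimiter."""
    chunks, current = [], []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            chunks.append("\n".join(current) + "\n")
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        chunks.append("\n".join(current) + "\n")
    return chunks


def _parse_sdf_chunk(chunk: str) -> tuple[str, dict[str, str]]:
    """Split one SDF record into its molfile block and its data fields."""
    lines = chunk.splitlines()
    end = None
    for i, line in enumerate(lines):
        if line.strip() == "M  END":
            end = i
            break
    if end is None:
        raise ValueError("no 'M  END' terminator in molfile block")
    molblock = "\n".join(lines[: end + 1]) + "\n"

    props: dict[str, str] = {}
    i = end + 1
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            tag = line[line.find("<") + 1 : line.rfind(">")]
            i += 1
            value_lines = []
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            props[tag] = "\n".join(value_lines)
        i += 1
    return molblock, props


def read_sdf_source(
    path: str | Path, cfg: SourceConfig
) -> tuple[list[RawRecord], list[Diagnostic]]:
    """Read a V2000 SDF source file into raw records.

    The molfile block is preserved verbatim as ``structure_text``; a record
    whose molfile RDKit cannot parse is skipped with a diagnostic carrying
    its ordinal.  V3000 records are rejected the same way.
    """
    from .chem import mol_from_molblock

    text = Path(path).read_text(encoding="utf-8")
    records: list[RawRecord] = []
    diagnostics: list[Diagnostic] = []
    seen: set[tuple[str, str]] = set()
    for ordinal, chunk in enumerate(_split_sdf_records(text)):
        try:
            molblock, props = _parse_sdf_chunk(chunk)
            mol = mol_from_molblock(molblock)
            if mol is None:
                raise ValueError("malformed molfile block")
            # a zero-atom block is the dialect's way of saying "no structure"
            structure = molblock if mol.GetNumAtoms() > 0 else None
            record = _fields_to_record(cfg.source_db, _map_values(props, cfg), structure)
        except ValueError as exc:
            diagnostics.append(Diagnostic(str(path), ordinal, str(exc)))
            continue
        if record.ref in seen:
            raise ValueError(f"duplicate record id {record.ref} in {path}")
        seen.add(record.ref)
        records.append(record)
    return records, diagnostics


# -------------------------------------------------------------- tables ----

def read_table_source(
    path: str | Path, cfg: SourceConfig
) -> tuple[list[RawRecord], list[Diagnostic]]:
    """Read a delimited table source (header row required).

    Values are trimmed of surrounding whitespace; a row whose column count
    differs from the header becomes a diagnostic, and a duplicated
    (source_db, relation_id) key is an error.
    """
    records: list[RawRecord] = []
    diagnostics: list[Diagnostic] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=cfg.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row")
        for ordinal, row in enumerate(reader, start=1):
            if len(row) != len(header):
                diagnostics.append(
                    Diagnostic(
                        str(path),
                        ordinal,
                        f"expected {len(header)} columns, got {len(row)}",
                    )
                )
                continue
            raw = dict(zip(header, row))
            values = _map_values(raw, cfg)
            structure = None
            if values.get("structure"):
                from .chem import mol_from_smiles, mol_to_molblock

                mol = mol_from_smiles(values["structure"])
                if mol is None:
                    diagnostics.append(
                        Diagnostic(str(path), ordinal, "unparseable inline SMILES structure")
                    )
                    continue
                structure = mol_to_molblock(mol)
            try:
                record = _fields_to_record(cfg.source_db, values, structure)
            except ValueError as exc:
                diagnostics.append(Diagnostic(str(path), ordinal, str(exc)))
                continue
            if record.ref in seen:
                raise ValueError(f"duplicate record id {record.ref} in {path}")
            seen.add(record.ref)
            records.append(record)
    return records, diagnostics


# ----------------------------------------------------------------- XML ----

def _xml_error(elem, message: str) -> ValueError:
    return ValueError(f"{elem.getroottree().getpath(elem)}: {message}")


def _require(elem, attr: str) -> str:
    v = elem.get(attr)
    if v is None:
        raise _xml_error(elem, f"missing required attribute {attr!r}")
    return v


def parse_relation_element(rel) -> RawRecord:
    """Parse one ``<relation>`` element of the relation XML dialect."""
    source_db = _require(rel, "source_db")
    relation_id = _require(rel, "id")

    comp_el = rel.find("compound")
    if comp_el is None:
        raise _xml_error(rel, "missing <compound> child")
    structure = None
    struct_el = comp_el.find("structure")
    if struct_el is not None and struct_el.text and struct_el.text.strip():
        structure = struct_el.text
        # the writer prepends exactly one newline before the molfile block
        if structure.startswith("\n"):
            structure = structure[1:]
    identifiers = {}
    for ident in comp_el.findall("identifier"):
        identifiers[_require(ident, "class")] = (ident.text or "").strip()
    names = [((_require(n, "class")), (n.text or "").strip()) for n in comp_el.findall("name")]
    xrefs = [(_require(x, "db"), _require(x, "id")) for x in comp_el.findall("xref")]
    try:
        compound = CompoundDescriptor(
            structure_text=structure,
            identifiers=identifiers,
            names=names,
            xrefs=xrefs,
            local_id=comp_el.get("local_id"),
        )
    except ValueError as exc:
        raise _xml_error(comp_el, str(exc))

    tgt_el = rel.find("target")
    if tgt_el is None:
        raise _xml_error(rel, "missing <target> child")
    try:
        target = TargetDescriptor(
            namespace=_require(tgt_el, "namespace"),
            foreign_id=_require(tgt_el, "foreign_id"),
            label=(tgt_el.text or "").strip(),
            target_class=tgt_el.get("class", "protein"),
            organism=tgt_el.get("organism", ""),
        )
    except ValueError as exc:
        raise _xml_error(tgt_el, str(exc))

    ev_el = rel.find("evidence")
    if ev_el is None:
        raise _xml_error(rel, "missing <evidence> child")
    act_el = ev_el.find("activity")
    atype = avalue = aunits = None
    if act_el is not None:
        atype = act_el.get("type")
        aunits = act_el.get("units")
        if act_el.get("value") is not None:
            try:
                avalue = float(act_el.get("value"))
            except ValueError:
                raise _xml_error(act_el, f"non-numeric activity value {act_el.get('value')!r}")
    ref_el = ev_el.find("reference")
    assay_el = ev_el.find("assay")
    try:
        evidence = EvidencePayload(
            activity_type_raw=atype,
            activity_value_raw=avalue,
            activity_units_raw=aunits,
            evidence_class=ev_el.get("class", "measured"),
            reference=(ref_el.text or "").strip() if ref_el is not None else "",
            assay_description=(assay_el.text or "").strip() if assay_el is not None else "",
        )
    except ValueError as exc:
        raise _xml_error(ev_el, str(exc))

    record = RawRecord(
        source_db=source_db,
        source_relation_id=relation_id,
        compound=compound,
        target=target,
        evidence=evidence,
    )
    record.refers_to_inhibition = ev_el.get("inhibition", "").lower() == "true"
    return record


def read_xml_source(
    path: str | Path, cfg: SourceConfig | None = None
) -> tuple[list[RawRecord], list[Diagnostic]]:
    """Read a relation XML file.  Element order within a record is free;
    schema violations raise an error naming the offending element path."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "relations":
        raise ValueError(f"/{root.tag}: root element must be <relations>")
    records: list[RawRecord] = []
    seen: set[tuple[str, str]] = set()
    for rel in root.findall("relation"):
        record = parse_relation_element(rel)
        if record.ref in seen:
            raise ValueError(f"duplicate record id {record.ref} in {path}")
        seen.add(record.ref)
        records.append(record)
    return records, []


# ------------------------------------------------------------- dispatch ----

def read_source(path: str | Path, cfg: SourceConfig) -> tuple[list[RawRecord], list[Diagnostic]]:
    if cfg.format == "sdf":
        return read_sdf_source(path, cfg)
    if cfg.format == "tsv":
        return read_table_source(path, cfg)
    if cfg.format == "xml":
        return read_xml_source(path, cfg)
    raise ValueError(f"unknown source format {cfg.format!r}")


def load_xref_table(path: str | Path) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Load the compound cross-reference TSV
    (source_db_a, compound_id_a, source_db_b, compound_id_b)."""
    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"source_db_a", "compound_id_a", "source_db_b", "compound_id_b"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"xref table missing column(s): {sorted(missing)}")
        for row in reader:
            pairs.append(
                (
                    (row["source_db_a"].strip(), row["compound_id_a"].strip()),
                    (row["source_db_b"].strip(), row["compound_id_b"].strip()),
                )
            )
    return pairs
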