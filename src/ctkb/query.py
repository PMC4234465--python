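"""Boolean field-query language over the knowledge base.

Queries are sequences of field clauses joined left-to-right by the
connectors AND / OR / AND NOT, e.g.::

    "Organism Name" = "Homo sapiens" AND "Relation Strength" >= "Weak"

Each clause names an index, an operator, and a quoted value; text clauses
may append ``; strict`` (all terms must match — the default) or
``; fulltext`` (any term matches).  Numeric values accept any float
notation ("1E-09", "0.000000001", "0.1E-08", "10E-10" are the same value).

Semantics:

- text: case-insensitive substring match of each whitespace-separated term
  against the backing field(s);
- numeric clauses on evidence-level indices are existential — a relation
  matches if *any* of its evidences matches; only standardized (SI molar)
  values are compared;
- strength indices compare in the order no < weak < medium < strong;
  ``unclassified`` takes part in =/!= but never in ordered comparisons;
- absent values never match anything, ``!=`` included: for every clause,
  the clause and its negation together cover exactly the relations with a
  defined value for that index (three-valued semantics);
- connectors evaluate left-to-right without precedence: AND intersects,
  OR unions, AND NOT subtracts.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

from .evidence import STRENGTH_ORDER
from .kb import KnowledgeBase
from .relations import Relation

_ORDERED_RANK = {s: i for i, s in enumerate(("no", "weak", "medium", "strong"))}
OPERATORS = ("!=", ">=", "<=", "=", ">", "<")
CONNECTORS = ("AND NOT", "AND", "OR")


@dataclass(frozen=True)
class IndexDef:
    kind: str  # text | numeric | ordered_categorical | boolean
    getter: Callable[[Relation, KnowledgeBase], list]


def _compound(r: Relation, kb: KnowledgeBase):
    return kb.compounds[r.compound_entry_id]


def _identifier_values(cls):
    def get(r, kb):
        e = _compound(r, kb)
        vals = list(e.identifiers.get(cls, []))
        if cls == "smiles" and e.canonical_key:
            vals.append(e.canonical_key)
        return vals

    return get


DEFAULT_CATALOG: dict[str, IndexDef] = {
    "Relation ID": IndexDef("text", lambda r, kb: [r.relation_id]),
    "Compound Name": IndexDef("text", lambda r, kb: [n for _, n in _compound(r, kb).names]),
    "InChI": IndexDef("text", _identifier_values("inchi")),
    "InChIKey": IndexDef("text", _identifier_values("inchikey")),
    "SMILES": IndexDef("text", _identifier_values("smiles")),
    "Entrez Gene ID": IndexDef("text", lambda r, kb: [r.gene_id]),
    "Gene Symbol": IndexDef("text", lambda r, kb: [kb.genes[r.gene_id].symbol]),
    "Organism Name": IndexDef("text", lambda r, kb: [kb.genes[r.gene_id].organism]),
    "Activity Type": IndexDef(
        "text", lambda r, kb: [e.activity_type for e in r.evidences]
    ),
    "Activity Value": IndexDef(
        "numeric", lambda r, kb: [e.value_si for e in r.evidences if e.value_si is not None]
    ),
    "Activity Strength": IndexDef(
        "ordered_categorical", lambda r, kb: [e.strength for e in r.evidences]
    ),
    "Relation Strength": IndexDef(
        "ordered_categorical", lambda r, kb: [r.relation_strength] if r.evidences else []
    ),
    "Relation Score": IndexDef(
        "numeric", lambda r, kb: [r.relation_score] if r.relation_score is not None else []
    ),
    "Source Database": IndexDef("text", lambda r, kb: sorted(r.source_dbs)),
    "Evidence Class": IndexDef(
        "text", lambda r, kb: [e.evidence_class for e in r.evidences]
    ),
    "Unification Confidence": IndexDef(
        "text", lambda r, kb: [_compound(r, kb).unification_confidence]
    ),
    "Homolog Organism": IndexDef(
        "text", lambda r, kb: [r.homology_meta[2]] if r.homology_meta else []
    ),
    "Homolog Similarity": IndexDef(
        "numeric", lambda r, kb: [r.homology_meta[1]] if r.homology_meta else []
    ),
    "Homology Inferred": IndexDef("boolean", lambda r, kb: [r.homology_inferred]),
}

_LEGAL_OPS = {
    "text": {"=", "!="},
    "boolean": {"=", "!="},
    "numeric": {"=", "!=", ">", "<", ">=", "<="},
    "ordered_categorical": {"=", "!=", ">", "<", ">=", "<="},
}


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"at position {position}: {message}")
        self.position = position


@dataclass(frozen=True)
class Clause:
    index: str
    op: str
    value: str
    mode: str = "strict"  # strict | fulltext (text indices only)
    connector: str | None = None  # None on the first clause


@dataclass(frozen=True)
class QueryAST:
    clauses: tuple[Clause, ...]


# ------------------------------------------------------------- parsing ----

_TOKEN_RE = re.compile(
    r'\s*(?:(?P<quoted>"(?:[^"\\]|\\.)*")|(?P<op>!=|>=|<=|=|>|<)|(?P<semi>;)|(?P<word>[A-Za-z_][A-Za-z_]*))'
)


def _tokenize(q: str):
    tokens = []  # (kind, text, position)
    pos = 0
    while pos < len(q):
        m = _TOKEN_RE.match(q, pos)
        if m is None:
            if q[pos:].strip() == "":
                break
            raise QuerySyntaxError(f"unexpected character {q[pos]!r}", pos)
        if m.lastgroup == "quoted":
            text = m.group("quoted")[1:-1].replace('\\"', '"')
            tokens.append(("quoted", text, m.start("quoted")))
        elif m.lastgroup == "op":
            tokens.append(("op", m.group("op"), m.start("op")))
        elif m.lastgroup == "semi":
            tokens.append(("semi", ";", m.start("semi")))
        else:
            tokens.append(("word", m.group("word"), m.start("word")))
        pos = m.end()
    return tokens


def parse_query(q: str, catalog: dict[str, IndexDef] | None = None) -> QueryAST:
    """Parse a query string; raises ``QuerySyntaxError`` with the offending
    position on unknown indices, illegal operators, or dangling connectors."""
    if not q or not q.strip():
        raise QuerySyntaxError("empty query", 0)
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    tokens = _tokenize(q)
    clauses: list[Clause] = []
    i = 0
    connector: str | None = None
    while i < len(tokens):
        if clauses:
            # expect a connector
            kind, text, pos = tokens[i]
            if kind != "word" or text.upper() not in ("AND", "OR"):
                raise QuerySyntaxError(f"expected a connector, got {text!r}", pos)
            connector = text.upper()
            i += 1
            if (
                connector == "AND"
                and i < len(tokens)
                and tokens[i][0] == "word"
                and tokens[i][1].upper() == "NOT"
            ):
                connector = "AND NOT"
                i += 1
        if i >= len(tokens):
            raise QuerySyntaxError("dangling connector at end of query", len(q))
        kind, index_name, pos = tokens[i]
        if kind != "quoted":
            raise QuerySyntaxError(f"expected a quoted index name, got {index_name!r}", pos)
        if index_name not in catalog:
            raise QuerySyntaxError(f"unknown index {index_name!r}", pos)
        i += 1
        if i >= len(tokens) or tokens[i][0] != "op":
            raise QuerySyntaxError(f"expected an operator after {index_name!r}", pos)
        op = tokens[i][1]
        op_pos = tokens[i][2]
        idx_kind = catalog[index_name].kind
        if op not in _LEGAL_OPS[idx_kind]:
            raise QuerySyntaxError(
                f"operator {op!r} not allowed on {idx_kind} index {index_name!r}", op_pos
            )
        i += 1
        if i >= len(tokens) or tokens[i][0] != "quoted":
            raise QuerySyntaxError("expected a quoted value", op_pos)
        value = tokens[i][1]
        value_pos = tokens[i][2]
        i += 1
        mode = "strict"
        if i < len(tokens) and tokens[i][0] == "semi":
            i += 1
            if i >= len(tokens) or tokens[i][0] != "word" or tokens[i][1] not in (
                "strict",
                "fulltext",
            ):
                raise QuerySyntaxError("expected 'strict' or 'fulltext' after ';'", tokens[i - 1][2])
            mode = tokens[i][1]
            i += 1
        if idx_kind == "numeric":
            try:
                float(value)
            except ValueError:
                raise QuerySyntaxError(f"non-numeric value {value!r} for numeric index", value_pos)
        if idx_kind == "ordered_categorical" and value.casefold() not in STRENGTH_ORDER:
            raise QuerySyntaxError(f"unknown strength category {value!r}", value_pos)
        if idx_kind == "boolean" and value.casefold() not in ("true", "false"):
            raise QuerySyntaxError(f"boolean value must be 'true' or 'false', got {value!r}", value_pos)
        clauses.append(Clause(index_name, op, value, mode, connector))
    if not clauses:
        raise QuerySyntaxError("query contains no clause", 0)
    return QueryAST(tuple(clauses))


def render_query(ast: QueryAST) -> str:
    """Render an AST back to its canonical query string (reparses equal)."""
    parts = []
    for c in ast.clauses:
        if c.connector:
            parts.append(c.connector)
        escaped = c.value.replace('"', '\\"')
        clause = f'"{c.index}" {c.op} "{escaped}"'
        if c.mode == "fulltext":
            clause += " ; fulltext"
        parts.append(clause)
    return " ".join(parts)


# ----------------------------------------------------------- evaluation ----

def _clause_matches(c: Clause, r: Relation, kb: KnowledgeBase, catalog) -> bool:
    idx = catalog[c.index]
    values = idx.getter(r, kb)
    if idx.kind == "text":
        if not values:
            return False
        haystack = " | ".join(str(v) for v in values).casefold()
        terms = [t.casefold() for t in c.value.split()]
        if not terms:
            return False
        if c.mode == "fulltext":
            hit = any(t in haystack for t in terms)
        else:
            hit = all(t in haystack for t in terms)
        return hit if c.op == "=" else not hit
    if idx.kind == "boolean":
        if not values:
            return False
        want = c.value.casefold() == "true"
        hit = values[0] is want
        return hit if c.op == "=" else not hit
    if idx.kind == "numeric":
        if not values:
            return False
        target = float(c.value)
        if c.op == "=":
            return any(v == target for v in values)
        if c.op == "!=":
            return not any(v == target for v in values)
        cmp = {
            ">": lambda v: v > target,
            "<": lambda v: v < target,
            ">=": lambda v: v >= target,
            "<=": lambda v: v <= target,
        }[c.op]
        return any(cmp(v) for v in values)
    # ordered_categorical (strength)
    target = c.value.casefold()
    if c.op in ("=", "!="):
        if not values:
            return False
        hit = target in values
        return hit if c.op == "=" else not hit
    ordered = [v for v in values if v in _ORDERED_RANK]
    if not ordered or target not in _ORDERED_RANK:
        return False
    trank = _ORDERED_RANK[target]
    cmp = {
        ">": lambda rk: rk > trank,
        "<": lambda rk: rk < trank,
        ">=": lambda rk: rk >= trank,
        "<=": lambda rk: rk <= trank,
    }[c.op]
    return any(cmp(_ORDERED_RANK[v]) for v in ordered)


def evaluate(
    ast: QueryAST,
    kb: KnowledgeBase,
    universe: list[str] | None = None,
    catalog: dict[str, IndexDef] | None = None,
) -> list[str]:
    """Evaluate a query, returning matching relation ids in sorted order."""
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    ids = sorted(kb.relations) if universe is None else sorted(set(universe))
    result: set[str] | None = None
    for c in ast.clauses:
        matches = {rid for rid in ids if _clause_matches(c, kb.relations[rid], kb, catalog)}
        if result is None:
            result = matches
        elif c.connector == "AND":
            result &= matches
        elif c.connector == "OR":
            result |= matches
        elif c.connector == "AND NOT":
            result -= matches
        else:  # pragma: no cover - parser guarantees a connector
            raise ValueError("non-initial clause without connector")
    return sorted(result or set())


def filter_results(
    previous: list[str],
    ast: QueryAST,
    kb: KnowledgeBase,
    catalog: dict[str, IndexDef] | None = None,
) -> list[str]:
    """Apply a query to a previous result set only (the hit-list filter)."""
    return evaluate(ast, kb, universe=previous, catalog=catalog)
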