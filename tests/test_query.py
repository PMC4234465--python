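"""Query language: parsing, evaluation semantics, oracle equivalence."""
import random

import pytest

from ctkb.query import (
    DEFAULT_CATALOG,
    Clause,
    QueryAST,
    QuerySyntaxError,
    evaluate,
    filter_results,
    parse_query,
    render_query,
)

CASE_STUDY_QUERY = '"Organism Name" = "Homo sapiens" AND "Relation Strength" >= "Weak"'


# -------------------------------------------------------------- parsing --

def test_case_study_query_parses_to_two_clauses():
    ast = parse_query(CASE_STUDY_QUERY)
    assert len(ast.clauses) == 2
    first, second = ast.clauses
    assert first == Clause("Organism Name", "=", "Homo sapiens", "strict", None)
    assert second.index == "Relation Strength" and second.op == ">=" and second.connector == "AND"


@pytest.mark.parametrize("notation", ["1E-09", "0.000000001", "0.1E-08", "10E-10"])
def test_numeric_value_notations_are_equivalent(notation):
    ast = parse_query(f'"Activity Value" <= "{notation}"')
    assert float(ast.clauses[0].value) == pytest.approx(1e-9)


def test_ordering_operator_illegal_on_text_index():
    with pytest.raises(QuerySyntaxError, match="not allowed on text"):
        parse_query('"Compound Name" > "x"')


def test_unknown_index_and_dangling_connector_are_positional_errors():
    with pytest.raises(QuerySyntaxError, match="unknown index"):
        parse_query('"No Such Index" = "x"')
    with pytest.raises(QuerySyntaxError, match="dangling connector"):
        parse_query('"Compound Name" = "x" AND')
    with pytest.raises(QuerySyntaxError):
        parse_query("")


def test_fulltext_mode_and_quoted_spaces():
    ast = parse_query('"Compound Name" = "acetylsalicylic acid" ; fulltext')
    assert ast.clauses[0].mode == "fulltext"
    assert ast.clauses[0].value == "acetylsalicylic acid"


def test_render_parse_round_trip_is_stable():
    queries = [
        CASE_STUDY_QUERY,
        '"Activity Value" <= "1E-09" AND NOT "Homology Inferred" = "true"',
        '"Compound Name" = "aspirin" ; fulltext OR "Gene Symbol" = "GENE1"',
    ]
    for q in queries:
        ast = parse_query(q)
        assert parse_query(render_query(ast)) == ast


# ------------------------------------------------------------ evaluation --

def test_strength_equality_returns_exactly_matching_relations(query_fixture):
    kb, _ = query_fixture
    ids = evaluate(parse_query('"Relation Strength" = "strong"'), kb)
    expected = {rid for rid, r in kb.relations.items()
                if r.evidences and r.relation_strength == "strong"}
    assert set(ids) == expected and ids == sorted(ids)


def test_homology_inferred_clause_partitions_the_kb(query_fixture):
    kb, _ = query_fixture
    true_ids = set(evaluate(parse_query('"Homology Inferred" = "true"'), kb))
    false_ids = set(evaluate(parse_query('"Homology Inferred" = "false"'), kb))
    assert true_ids == {rid for rid, r in kb.relations.items() if r.homology_inferred}
    assert true_ids | false_ids == set(kb.relations)
    assert not (true_ids & false_ids)


def test_and_not_is_set_difference(query_fixture):
    kb, _ = query_fixture
    a = '"Organism Name" = "Homo sapiens"'
    b = '"Relation Strength" >= "medium"'
    combined = evaluate(parse_query(f"{a} AND NOT {b}"), kb)
    assert set(combined) == set(evaluate(parse_query(a), kb)) - set(evaluate(parse_query(b), kb))


def test_absent_values_never_match_even_negated(query_fixture):
    kb, _ = query_fixture
    # inferred relations have no evidences: no Activity Value is defined
    inferred = {rid for rid, r in kb.relations.items() if r.homology_inferred}
    eq = set(evaluate(parse_query('"Activity Value" = "1E-09"'), kb))
    ne = set(evaluate(parse_query('"Activity Value" != "1E-09"'), kb))
    defined = {rid for rid, r in kb.relations.items()
               if any(e.value_si is not None for e in r.evidences)}
    assert eq | ne == defined
    assert not (eq & inferred) and not (ne & inferred)


def test_filter_equals_conjunction_and_tautology_is_identity(query_fixture):
    kb, _ = query_fixture
    a, b = CASE_STUDY_QUERY.split(" AND ")
    first = evaluate(parse_query(a), kb)
    chained = filter_results(first, parse_query(b), kb)
    assert chained == evaluate(parse_query(CASE_STUDY_QUERY), kb)
    tautology = parse_query('"Homology Inferred" = "true" OR "Homology Inferred" = "false"')
    assert filter_results(first, tautology, kb) == first


# ---------------------------------------------------- row-scan oracle ----

def _oracle_clause(c, r, kb):
    """Independent naive clause check by direct field inspection."""
    idx = DEFAULT_CATALOG[c.index]
    values = idx.getter(r, kb)
    if idx.kind == "text":
        if not values:
            return False
        hay = " | ".join(map(str, values)).casefold()
        terms = c.value.casefold().split()
        hit = (any if c.mode == "fulltext" else all)(t in hay for t in terms)
        return hit if c.op == "=" else not hit
    if idx.kind == "boolean":
        return bool(values) and ((values[0] is (c.value.casefold() == "true")) == (c.op == "="))
    if idx.kind == "numeric":
        if not values:
            return False
        t = float(c.value)
        if c.op == "=":
            return t in values
        if c.op == "!=":
            return t not in values
        import operator

        op = {">": operator.gt, "<": operator.lt, ">=": operator.ge, "<=": operator.le}[c.op]
        return any(op(v, t) for v in values)
    order = ["no", "weak", "medium", "strong"]
    t = c.value.casefold()
    if c.op in ("=", "!="):
        return bool(values) and ((t in values) == (c.op == "="))
    vs = [order.index(v) for v in values if v in order]
    if t not in order or not vs:
        return False
    import operator

    op = {">": operator.gt, "<": operator.lt, ">=": operator.ge, "<=": operator.le}[c.op]
    return any(op(v, order.index(t)) for v in vs)


def _oracle_evaluate(ast, kb):
    result = None
    for c in ast.clauses:
        hits = {rid for rid, r in kb.relations.items() if _oracle_clause(c, r, kb)}
        if result is None:
            result = hits
        elif c.connector == "AND":
            result &= hits
        elif c.connector == "OR":
            result |= hits
        else:
            result -= hits
    return sorted(result)


def random_ast(rng, kb):
    clauses = []
    for i in range(rng.randint(1, 4)):
        name = rng.choice(sorted(DEFAULT_CATALOG))
        kind = DEFAULT_CATALOG[name].kind
        if kind == "text":
            value = rng.choice(["GENE1", "compound", "Homo sapiens", "SRC0", "alias 3",
                                "measured", "xyzzy"])
            op = rng.choice(["=", "!="])
            mode = rng.choice(["strict", "fulltext"])
        elif kind == "numeric":
            value = rng.choice(["1E-09", "5E-7", "0.0001", "9", "85.5"])
            op = rng.choice(["=", "!=", ">", "<", ">=", "<="])
            mode = "strict"
        elif kind == "ordered_categorical":
            value = rng.choice(["no", "weak", "medium", "strong", "unclassified"])
            op = rng.choice(["=", "!=", ">", "<", ">=", "<="])
            mode = "strict"
        else:
            value = rng.choice(["true", "false"])
            op = rng.choice(["=", "!="])
            mode = "strict"
        clauses.append(Clause(name, op, value, mode,
                              None if i == 0 else rng.choice(["AND", "OR", "AND NOT"])))
    return QueryAST(tuple(clauses))


def test_evaluation_matches_row_scan_oracle_on_random_queries(query_fixture):
    kb, _ = query_fixture
    assert len(kb.relations) >= 150
    rng = random.Random(23)
    for trial in range(100):
        ast = random_ast(rng, kb)
        assert evaluate(ast, kb) == _oracle_evaluate(ast, kb), f"trial {trial}: {render_query(ast)}"
        # purity: repeated evaluation identical
        assert evaluate(ast, kb) == evaluate(ast, kb)
        # render/parse stability on generated ASTs
        assert parse_query(render_query(ast)) == ast
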