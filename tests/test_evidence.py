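"""Activity-type normalization, SI conversion, strength, reliability."""
import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctkb.evidence import (
    DEFAULT_RELIABILITY,
    ReliabilityMap,
    StrengthRule,
    aggregate_relation_score,
    aggregate_relation_strength,
    assign_reliability,
    classify_strength,
    convert_to_si,
    normalize_activity_type,
    standardize_evidence,
    strength_rank,
)
from ctkb.records import EvidencePayload


# ------------------------------------------------------ type normalization

@pytest.mark.parametrize(
    "raw,inhibition,expected",
    [
        ("Inhibitory Concentration", True, "IC50"),
        ("AC", True, "IC50"),
        ("Inhibitory Concentration", False, "other"),
        ("AC", False, "other"),
        ("IC50", False, "IC50"),
        ("IC 50", False, "IC50"),
        ("ic_50", False, "IC50"),
        ("IC₅₀", False, "IC50"),
        ("Ki", False, "Ki"),
        ("kd", False, "Kd"),
        ("percent inhibition", False, "percent_inhibition"),
        ("frobnication index", True, "other"),
        (None, False, "other"),
    ],
)
def test_activity_type_normalization(raw, inhibition, expected):
    assert normalize_activity_type(raw, inhibition) == expected


# ------------------------------------------------------------ SI conversion

def test_micromolar_conversion_worked_example():
    value_si, converted = convert_to_si(207.2, "μM")
    assert value_si == pytest.approx(0.0002072, rel=1e-12)
    assert converted


@pytest.mark.parametrize(
    "value,units,expected_si,expected_flag",
    [
        (1.0, "M", 1.0, False),
        (3.0, "nM", 3e-9, True),
        (2.5, "mM", 2.5e-3, True),
        (7.0, "pM", 7e-12, True),
        (4.0, "uM", 4e-6, True),
        (5.0, "mg/mL", None, False),
        (50.0, "%", None, False),
        (1.0, None, None, False),
        (9.0, "parsecs", None, False),
    ],
)
def test_unit_conversion_table(value, units, expected_si, expected_flag):
    value_si, flag = convert_to_si(value, units)
    if expected_si is None:
        assert value_si is None
    else:
        assert value_si == pytest.approx(expected_si, rel=1e-12)
    assert flag is expected_flag


@pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
def test_nonpositive_values_are_errors(bad):
    with pytest.raises(ValueError):
        convert_to_si(bad, "nM")


@settings(derandomize=True, max_examples=200)
@given(
    value=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
    unit=st.sampled_from(["mM", "uM", "µM", "μM", "nM", "pM", "fM"]),
)
def test_conversion_is_exactly_multiplicative(value, unit):
    factors = {"mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "μM": 1e-6,
               "nM": 1e-9, "pM": 1e-12, "fM": 1e-15}
    value_si, flag = convert_to_si(value, unit)
    assert flag
    assert math.isclose(value_si, value * factors[unit], rel_tol=1e-12)


# -------------------------------------------------- strength classification

@pytest.mark.parametrize(
    "atype,value,expected",
    [
        ("IC50", 5e-9, "strong"),
        ("IC50", 1e-8, "strong"),      # boundary belongs to the stronger class
        ("IC50", 1.0000001e-8, "medium"),
        ("IC50", 1e-6, "medium"),
        ("IC50", 9e-6, "weak"),
        ("IC50", 1e-5, "weak"),
        ("IC50", 1.1e-5, "no"),
        ("Ki", 2.072e-4, "no"),        # the converted worked-example value
        ("Kd", 1e-9, "strong"),
        ("EC50", 5e-7, "medium"),
        ("AC50", 1e-3, "no"),
        ("percent_inhibition", 1e-9, "unclassified"),
        ("other", 1e-9, "unclassified"),
        ("Km", 1e-9, "unclassified"),
        ("IC50", None, "unclassified"),
    ],
)
def test_strength_classification(atype, value, expected):
    assert classify_strength(atype, value) == expected


def test_strength_is_monotone_in_value():
    values = [10 ** (-12 + i * 0.25) for i in range(40)]
    ranks = [strength_rank(classify_strength("IC50", v)) for v in values]
    assert ranks == sorted(ranks, reverse=True)


def test_custom_cutoffs_must_be_ordered():
    with pytest.raises(ValueError):
        StrengthRule(strong_max=1e-6, medium_max=1e-8, weak_max=1e-5)


# -------------------------------------------------------------- reliability

def test_reliability_scores_by_evidence_class():
    assert assign_reliability("predicted") == 4
    assert assign_reliability("measured") == 9
    assert assign_reliability("curated") == 10
    with pytest.raises(KeyError):
        assign_reliability("hearsay")
    with pytest.raises(ValueError):
        ReliabilityMap(scores={"predicted": 0})


# ------------------------------------------------------------- aggregation

def _mk(strength):
    from ctkb.evidence import StandardEvidence

    if strength == "unclassified":
        return StandardEvidence(source_db="S", source_relation_id="r")
    # value consistent with the declared strength bucket
    value = {"strong": 1e-9, "medium": 1e-7, "weak": 5e-6, "no": 1e-3}[strength]
    return StandardEvidence(source_db="S", source_relation_id="r",
                            activity_type="IC50", value_si=value, strength=strength)


@pytest.mark.parametrize(
    "strengths,expected",
    [
        (["weak", "strong"], "strong"),
        (["unclassified"], "unclassified"),
        (["no", "weak"], "weak"),
        (["no", "unclassified"], "no"),
        (["medium", "medium", "weak"], "medium"),
    ],
)
def test_relation_strength_inherits_strongest(strengths, expected):
    assert aggregate_relation_strength([_mk(s) for s in strengths]) == expected


def test_relation_score_is_maximum():
    from ctkb.evidence import StandardEvidence

    def ev(score):
        return StandardEvidence(source_db="S", source_relation_id="r", reliability=score)

    assert aggregate_relation_score([ev(4), ev(9)]) == 9
    assert aggregate_relation_score([ev(10)]) == 10
    assert aggregate_relation_score([ev(4), ev(4), ev(4)]) == 4
    with pytest.raises(ValueError):
        aggregate_relation_score([])
    with pytest.raises(ValueError):
        aggregate_relation_strength([])


def test_aggregations_are_a_max_semilattice():
    """Associative, commutative, idempotent — exhaustively over multisets <=3."""
    cats = ["unclassified", "no", "weak", "medium", "strong"]
    for combo in itertools.chain(
        itertools.product(cats, repeat=2), itertools.product(cats, repeat=3)
    ):
        evs = [_mk(s) for s in combo]
        result = aggregate_relation_strength(evs)
        # commutativity: any permutation agrees
        for perm in itertools.permutations(evs):
            assert aggregate_relation_strength(list(perm)) == result
        # associativity/idempotence: folding pairwise agrees with the n-ary max
        acc = combo[0]
        for s in combo[1:]:
            acc = aggregate_relation_strength([_mk(acc), _mk(s)])
        assert acc == result
        assert aggregate_relation_strength([_mk(result), _mk(result)]) == result


def test_standardization_preserves_originals():
    payload = EvidencePayload(
        activity_type_raw="IC 50", activity_value_raw=207.2, activity_units_raw="μM",
        evidence_class="measured", reference="PMID:1",
    )
    ev = standardize_evidence("S", "r1", payload)
    assert ev.original == ("IC 50", 207.2, "μM")
    assert ev.activity_type == "IC50"
    assert ev.value_si == pytest.approx(2.072e-4, rel=1e-12)
    assert ev.converted_flag
    assert ev.strength == "no"  # 207 uM is above the unspecific cutoff
    assert ev.reliability == 9
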