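"""Bioactivity standardization: activity types, SI units, strength, reliability.

Source databases report binding data in incompatible shapes — "IC 50" vs
"IC50", micromolar vs nanomolar, free-text activity names.  This module
normalizes activity types against a synonym table, converts molar-prefixed
values to plain molar (M), buckets affinity values into discrete binding
strength categories (strong/medium/weak/no), and attaches an integer
reliability score by evidence provenance class.  Originals are always kept
verbatim next to the standardized values.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

#: canonical activity types; the first five are the affinity set that is
#: strength-classifiable (molar concentrations where lower = stronger).
ACTIVITY_TYPES = ("IC50", "EC50", "AC50", "Ki", "Kd", "Km", "percent_inhibition", "other")
AFFINITY_TYPES = frozenset({"IC50", "EC50", "AC50", "Ki", "Kd"})

#: strength categories in increasing binding order; unclassified sits outside
#: the order (non-affinity or non-molar evidence).
STRENGTH_ORDER = ("unclassified", "no", "weak", "medium", "strong")
_STRENGTH_RANK = {s: i for i, s in enumerate(STRENGTH_ORDER)}

#: molar-prefixed units and their factors; everything else is non-molar and
#: never converted (mass concentrations would need a molecular weight).
MOLAR_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
    "fm": 1e-15,
}

_SUBSCRIPT_MAP = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def _squash(s: str) -> str:
    """Lowercase, fold subscripts to digits, drop spaces/underscores/hyphens."""
    return re.sub(r"[\s_\-]+", "", s.translate(_SUBSCRIPT_MAP).lower())


#: synonym table: squashed raw string -> canonical type.  Editable via config.
DEFAULT_TYPE_SYNONYMS: dict[str, str] = {
    "ic50": "IC50",
    "ec50": "EC50",
    "ac50": "AC50",
    "ki": "Ki",
    "kd": "Kd",
    "km": "Km",
    "percentinhibition": "percent_inhibition",
    "%inhibition": "percent_inhibition",
    "inhibition": "percent_inhibition",
}

#: raw names that resolve to IC50 only when the evidence refers to inhibition
INHIBITION_CONTEXT_SYNONYMS = {"inhibitoryconcentration", "ac", "activeconcentration"}


def normalize_activity_type(
    type_raw: str | None,
    refers_to_inhibition: bool = False,
    synonyms: dict[str, str] | None = None,
) -> str:
    """Map a raw activity-type string to its canonical type.

    Lookup is case-, space- and subscript-insensitive.  "Inhibitory
    Concentration" and "AC" map to IC50 only when the evidence refers to
    inhibition; unrecognized strings fall through to ``"other"`` (the raw
    string is preserved on the evidence, never here).
    """
    if type_raw is None:
        return "other"
    key = _squash(type_raw)
    if key in INHIBITION_CONTEXT_SYNONYMS:
        return "IC50" if refers_to_inhibition else "other"
    table = DEFAULT_TYPE_SYNONYMS if synonyms is None else synonyms
    return table.get(key, "other")


def convert_to_si(value: float, units_raw: str | None) -> tuple[float | None, bool]:
    """Convert a molar-prefixed value to molar units.

    Returns ``(value_si, converted_flag)``.  Already-molar input is returned
    unchanged with the flag False; non-molar or unparseable units yield
    ``(None, False)`` — the original stays queryable but is never compared
    against standardized molar values.  Conversion is exactly multiplicative.

    Raises ``ValueError`` for non-positive or non-finite values.
    """
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"activity value must be finite and > 0, got {value!r}")
    if units_raw is None:
        return None, False
    unit = _squash(units_raw)
    if unit not in MOLAR_FACTORS:
        return None, False
    factor = MOLAR_FACTORS[unit]
    if factor == 1.0:
        return value, False
    return value * factor, True


@dataclass(frozen=True)
class StrengthRule:
    """Molar cutoffs separating the binding-strength categories.

    Defaults follow pharma best practice: <=10 nM strong, (10 nM, 1 uM]
    medium, (1 uM, 10 uM] weak, above 10 uM unspecific ("no").  Boundaries
    belong to the stronger class.
    """

    strong_max: float = 1e-8
    medium_max: float = 1e-6
    weak_max: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.strong_max < self.medium_max < self.weak_max):
            raise ValueError("cutoffs must satisfy 0 < strong < medium < weak")


DEFAULT_STRENGTH_RULE = StrengthRule()


def classify_strength(
    activity_type: str,
    value_si: float | None,
    rule: StrengthRule = DEFAULT_STRENGTH_RULE,
) -> str:
    """Bucket a standardized molar affinity value into a strength category.

    Only the affinity types (IC50/EC50/AC50/Ki/Kd) with a molar value are
    classified; anything else is ``unclassified``.
    """
    if activity_type not in AFFINITY_TYPES or value_si is None:
        return "unclassified"
    if value_si <= rule.strong_max:
        return "strong"
    if value_si <= rule.medium_max:
        return "medium"
    if value_si <= rule.weak_max:
        return "weak"
    return "no"


@dataclass(frozen=True)
class ReliabilityMap:
    """Integer reliability score per evidence provenance class (1-10)."""

    scores: dict[str, int] = field(
        default_factory=lambda: {"predicted": 4, "measured": 9, "curated": 10, "textual": 5}
    )

    def __post_init__(self) -> None:
        for cls, s in self.scores.items():
            if not 1 <= s <= 10:
                raise ValueError(f"reliability score for {cls!r} out of [1,10]: {s}")


DEFAULT_RELIABILITY = ReliabilityMap()


def assign_reliability(evidence_class: str, rmap: ReliabilityMap = DEFAULT_RELIABILITY) -> int:
    if evidence_class not in rmap.scores:
        raise KeyError(f"no reliability score configured for class {evidence_class!r}")
    return rmap.scores[evidence_class]


@dataclass
class StandardEvidence:
    """One evidence after standardization, with originals preserved."""

    source_db: str
    source_relation_id: str
    activity_type: str = "other"
    value_si: float | None = None
    converted_flag: bool = False
    original: tuple[str | None, float | None, str | None] = (None, None, None)
    strength: str = "unclassified"
    reliability: int = 5
    evidence_class: str = "measured"
    reference: str = ""
    assay_description: str = ""
    #: whether the source assertion refers to inhibition (normalization context)
    refers_to_inhibition: bool = False

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(f"unknown activity type {self.activity_type!r}")
        if self.strength not in STRENGTH_ORDER:
            raise ValueError(f"unknown strength {self.strength!r}")
        if self.value_si is not None and self.value_si <= 0:
            raise ValueError("value_si must be positive when present")
        if self.strength != "unclassified" and (
            self.value_si is None or self.activity_type not in AFFINITY_TYPES
        ):
            raise ValueError("classified strength requires a molar affinity value")


def standardize_evidence(
    source_db: str,
    source_relation_id: str,
    payload,
    refers_to_inhibition: bool = False,
    strength_rule: StrengthRule = DEFAULT_STRENGTH_RULE,
    reliability_map: ReliabilityMap = DEFAULT_RELIABILITY,
    type_synonyms: dict[str, str] | None = None,
) -> StandardEvidence:
    """Standardize one raw evidence payload end to end."""
    activity_type = normalize_activity_type(
        payload.activity_type_raw, refers_to_inhibition, type_synonyms
    )
    value_si: float | None = None
    converted = False
    if payload.activity_value_raw is not None:
        value_si, converted = convert_to_si(
            payload.activity_value_raw, payload.activity_units_raw
        )
    return StandardEvidence(
        source_db=source_db,
        source_relation_id=source_relation_id,
        activity_type=activity_type,
        value_si=value_si,
        converted_flag=converted,
        original=(
            payload.activity_type_raw,
            payload.activity_value_raw,
            payload.activity_units_raw,
        ),
        strength=classify_strength(activity_type, value_si, strength_rule),
        reliability=assign_reliability(payload.evidence_class, reliability_map),
        evidence_class=payload.evidence_class,
        reference=payload.reference,
        assay_description=payload.assay_description,
        refers_to_inhibition=refers_to_inhibition,
    )


def strength_rank(strength: str) -> int:
    """Position in the total order unclassified < no < weak < medium < strong."""
    return _STRENGTH_RANK[strength]


def aggregate_relation_strength(evidences: list[StandardEvidence]) -> str:
    """A relation inherits the strongest strength among its evidences."""
    if not evidences:
        raise ValueError("cannot aggregate strength of zero evidences")
    return max((e.strength for e in evidences), key=strength_rank)


def aggregate_relation_score(evidences: list[StandardEvidence]) -> int:
    """A relation inherits the highest reliability score among its evidences."""
    if not evidences:
        raise ValueError("cannot aggregate score of zero evidences")
    return max(e.reliability for e in evidences)
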