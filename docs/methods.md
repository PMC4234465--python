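# Methods

`ctkb` builds a non-redundant compound–target relation knowledge base from
heterogeneous source-database dumps. This note describes the models and
procedures, the defaults that matter, the synthetic data the tests run on,
and the limits of what those tests show.

## The data model

One *raw record* is one source assertion: a compound descriptor (structure
block, identifiers, names, cross-references), a target descriptor
(namespace/foreign id, declared class, organism) and an evidence payload
(activity type/value/units as printed, provenance class, reference text).
Construction turns a stream of raw records into three unified spaces:

- **compound entries** — partitions of source compound references,
- **genes** — entries of a common gene index,
- **relations** — unique (compound entry, gene) pairs carrying all of
  their evidences plus two aggregates (strength, reliability score),
  extended by flagged, evidence-free *homology-inferred* relations.

## Compound unification

Structures are first purged: isotope labels and stereo flags erased,
free water components removed, small charged components (counterions)
dropped, and identical repeated components collapsed to one. A component
counts as a counterion when its net formal charge is non-zero and it has
at most `ion_max_heavy_atoms` (default 6) heavy atoms while a larger
component exists; a configurable counterion list can also name components
to strip. If every component would be purged away, the largest original
component is kept, so purging never empties a molecule. Entity resolution
is therefore at the level of the constitutional skeleton — stereoisomers
and isotopologues collapse deliberately, because that is how independent
source databases most often disagree about "the same" compound.
RDKit performs all structure handling; the canonical key is the RDKit
canonical SMILES of the purged molecule.

Merging is hierarchical:

1. **structure** — equal canonical keys;
2. **xref** — explicit cross-references between source entries;
3. **identifier/name** equality in priority order:
   InChI > InChIKey > CAS > systematic name > brand name > synonym.
   Formula matching is implemented but disabled by default: molecular
   formulas collide across constitutional isomers. A SMILES string that
   arrives without a parsable structure context is an identifier (tier 3);
   a SMILES parsed into a structure feeds tier 1.

Two design rules are this package's own resolutions of genuinely open
points. First, the *structure-conflict veto*: a lower-tier criterion never
merges two components whose canonical keys both exist and differ, so no
unified entry ever contains two distinct structures. Second, confidence
composition: each merge edge carries the tier that made it
(structure/InChI/InChIKey → high, xref/CAS → medium, names/formula → low)
and an entry's unification confidence is its **weakest** edge — a chain is
only as trustworthy as its sloppiest link. Singletons are
`not_applicable`. Within each tier, candidate pairs are applied in sorted
order, which makes the partition invariant under permutation of the input
stream; entry ids are hashes of the sorted member references, so rebuilds
reproduce identical ids.

Name matching is case-insensitive with internal whitespace collapsed;
InChIKeys are uppercased; all other identifiers match exactly.

## Target mapping

A target enters the knowledge base only when its declared class is protein
or nucleotide, its (namespace, foreign id) key resolves to exactly one
gene of the index, and the resolved gene is not a pseudogene. Everything
else — pathways, diseases, ambiguous keys, unknown namespaces — is
rejected with a machine-readable reason; there is no fuzzy symbol
matching, by design: precision beats recall when a wrong gene would
poison every downstream relation. An organism mismatch between descriptor
and index logs a warning by default (strict mode rejects); the index is
gene-level, so protein isoforms of one gene share one entry.

## Evidence standardization

Activity types are normalized against an editable synonym table,
insensitive to case, spacing and subscripts. "Inhibitory Concentration"
and "AC" normalize to IC50 *only* when the evidence refers to inhibition
(a per-record context flag). Values with molar-prefixed units
(fM…mM) are converted to molar by exact power-of-ten multiplication;
already-molar values pass through unconverted; non-molar units (mg/mL, %,
unitless) are never converted — mass-to-molar conversion would need a
molecular weight and is out of scope. The original (type, value, units)
triple survives verbatim on every standardized evidence.

Affinity values (IC50, EC50, AC50, Ki, Kd) are bucketed into binding
strengths with molar cutoffs `strong_max=1e-8`, `medium_max=1e-6`,
`weak_max=1e-5`: ≤10 nM strong, (10 nM, 1 µM] medium, (1 µM, 10 µM] weak,
above 10 µM unspecific ("no"). Boundaries belong to the stronger class;
only the strong boundary's inclusivity is conventionally fixed, so the
half-open-interval choice for the others is documented here and
configurable. The same cutoffs apply to all five affinity types.
Percent-inhibition and non-molar evidences stay `unclassified` and are
never strength-compared, though their fields remain queryable.

Reliability scores by evidence class default to predicted = 4,
measured = 9, curated = 10, textual = 5 (the textual score is a
configurable package default; scores live in [1, 10]). A relation
inherits the **strongest** strength and the **highest** score among its
evidences — both are max-semilattice aggregations (associative,
commutative, idempotent), verified exhaustively in the tests.

## Homology inference

If a gene in a direct relation has a homolog whose encoded protein is
*strictly* more than 80% identical, an inferred relation to the same
compound is created for the homolog, flagged and carrying the parent
relation id, the identity percentage and the homolog's organism — but no
evidences, and hence no strength or score: inferred relations are
deliberately excluded from strength filtering unless selected explicitly.
Pairs already covered by a direct relation are skipped; when several
parents qualify, the highest identity wins (ties broken by lexicographic
gene id). Inference is single-pass: inferred relations never seed further
inference. Identities come precomputed from the homology table or, as a
fallback, from global alignment of member protein sequences
(Needleman–Wunsch via Biopython; match +1, mismatch 0, gap −1, identity =
identical columns / alignment columns × 100).

## Query engine

Queries are left-associative sequences of field clauses joined by
AND / OR / AND NOT, without precedence or parentheses — mirroring a
sequential query-builder interface. Text clauses match each
whitespace-separated term as a case-insensitive substring of the backing
field, all terms in `strict` mode (default), any term in `fulltext` mode.
Numeric clauses compare standardized molar values only and are
existential over a relation's evidences; strength clauses on "Relation
Strength" test the aggregate, those on "Activity Strength" are
evidence-level. The strength order is no < weak < medium < strong with
`unclassified` excluded from ordered comparisons. Absent values never
match any operator, `!=` included: a clause and its negation together
cover exactly the relations with a defined value for that index. This
three-valued choice keeps evidence-free (inferred) relations from
flooding negation queries.

## Export

TSV exports one row per relation with a configurable column set (default
six: Relation ID, Compound, Gene Symbol, Organism Name, Relation
Strength, Evidences); standardized values print first, originals behind
an `SI:` marker. Inferred relations get a `*` suffix on their id and an
explicit selectable "Homology Inferred" column. XML export emits one
`<relation>` element per evidence in exactly the dialect the ingest
module reads, making export→import lossless for every representable
field. SDF export writes one V2000 record per distinct compound with
relation and evidence data as data fields; structureless compounds get an
empty structure block plus a diagnostic. Gzip compression is available
for all formats. XLS is not offered; TSV covers the tabular use case in
a plain-text format.

## Synthetic fixtures

The generator emits a multi-source corpus with full ground truth. Each
true compound (default 50, drawn from a ~50-molecule library plus a
branched-alcohol homolog family for larger corpora) appears in 1..k of
the sources (default 3, files cycling the SDF/TSV/XML dialects), with
perturbations drawn per record: counterion or water components appended
(p = 0.2 / 0.15), isotope labels and chiral flags set (p = 0.15 each),
whole-molecule duplication (p = 0.1), atom order scrambled always, and
the structure dropped entirely with probability 0.2 — replaced by a
cross-reference to a structured sibling (p = 0.6), an InChIKey, a CAS
number, or names alone. Five percent of targets are traps (pathway or
disease class, pseudogenes, ambiguous or unknown keys). Evidence values
are log-uniform over 10⁻⁹·⁵–10⁻³·⁵ M, printed in a random molar unit
(occasionally mg/mL), with evidence classes mixed 60/20/10/10
measured/predicted/curated/textual. Homology groups (default 6 of size
2–4) carry pairwise identities uniform in 60–99.5%. All perturbations
are reversible by the purge rules, so with `p_structure = 1` the true
partition is exactly recoverable — the recovery tests assert precisely
that, and the expected direct and inferred pair sets are computed
independently inside the generator.

What the fixtures do **not** emulate: name collisions between distinct
compounds, conflicting or wrong cross-references, tautomer or salt-form
ambiguity beyond the purge rules, or realistic chemistry-space sampling.
Passing fixture tests therefore demonstrates correctness of the
mechanics, not robustness to dirty real-world naming.

## Problem sizes and numerics

The default test suite runs corpora of 20–80 true compounds (~60–250
records); the scaled end-to-end check uses ~5,000 records over 3 sources,
500 genes and 50 homology groups, chosen as a size where all invariants
remain exhaustively checkable in seconds. Unit conversion is exact
multiplication (relative error ≤ 1e-12 asserted); no floating-point
comparison tolerances are needed elsewhere because strengths, scores and
partitions are discrete. Determinism throughout comes from sorted
iteration orders, stable hashes for ids, and a single integer seed in the
generator.

## Known limitations

- No stereochemistry-aware registration or tautomer canonicalization:
  stereoisomers unify intentionally.
- Dipolar-bond normalization (nitro/N-oxide drawing variants) is limited
  to what RDKit sanitization already canonicalizes.
- No structure-similarity (Tanimoto) search; the query engine is exact.
- The reliability scale beyond the four configured classes, and strength
  propagation onto inferred relations, are configuration points rather
  than fixed semantics.
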