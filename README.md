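# ctkb — a compound–target relation knowledge base engine

Drug discovery teams routinely need one answer to "which compounds hit
this gene product?" or "what are all known targets of this drug?" — but
the evidence is scattered across many relation databases that describe
the same chemical under different names, ids and structure drawings, and
report bioactivity in incompatible types and units. `ctkb` is a library
and CLI that integrates such heterogeneous compound–target assertion
dumps into a single non-redundant knowledge base with directly comparable
evidence, and a Boolean field-query layer on top.

The core method, stage by stage:

1. **Compound unification.** Structures are purged — free water and small
   counterions removed, repeated units collapsed, isotope labels and
   stereo flags erased — and merged on equal canonical keys (canonical
   SMILES of the purged graph). Structureless entries merge through
   cross-references, then identifiers and names in a strict priority
   order (InChI > InChIKey > CAS > systematic > brand > synonym). A
   lower-tier criterion can never merge two entries whose structures
   conflict, and every merged entry carries a unification confidence:
   *high* for structure/InChI merges, *medium* for cross-references,
   *low* for names — always the weakest link in the entry.
2. **Target mapping.** Each target is traced to a unique gene of a common
   gene index; pathways, diseases, pseudogenes, ambiguous and unknown
   keys are rejected with machine-readable reasons.
3. **Evidence standardization.** Activity types normalize against a
   synonym table ("Inhibitory Concentration" → IC50 when the evidence
   refers to inhibition); molar-prefixed values convert exactly to molar
   (207.2 µM → 2.072·10⁻⁴ M); affinities (IC50/EC50/AC50/K_i/K_d) are
   bucketed into binding strengths — ≤10⁻⁸ M *strong*, (10⁻⁸, 10⁻⁶] M
   *medium*, (10⁻⁶, 10⁻⁵] M *weak*, >10⁻⁵ M *no* — and every evidence
   gets a reliability score by provenance (predicted 4, measured 9,
   curated 10). Originals are preserved verbatim behind the standardized
   values.
4. **Relation building.** Records collapse to unique (compound, gene)
   relations; a relation inherits the strongest strength and the highest
   score among its evidences.
5. **Homology inference.** Genes whose encoded proteins are >80%
   identical (strictly) to a related gene's protein receive flagged,
   evidence-free inferred relations, with the parent relation and the
   identity percentage attached.
6. **Query & export.** A field-query language with AND / OR / AND NOT,
   strict/fulltext text matching and ordered strength comparisons,
   evaluated left-to-right; results export to TSV, a lossless relation
   XML dialect, SDF (one record per distinct compound, data fields
   attached) and per-compound mol files.

A synthetic-fixture module generates multi-source corpora with known
ground truth (true compound partition, expected relations and inferred
pairs), so every stage is testable without any external database.

## Worked example

```bash
$ ctkb fixtures --seed 1 --out demo
emitted 151 records over 3 sources (145 with mappable targets)
true compounds: 50; expected inferred pairs: 111
fixture written to demo

$ ctkb build --sources demo --config demo/build_config.yaml --kb demo/kb
records read:        151
parse diagnostics:   0
compound entries:    51
relations (direct):  143
relations (inferred):111
target rejections:   6
knowledge base saved to demo/kb
```

151 source records over three dumps (an SDF, a TSV and an XML source)
describing 50 true compounds resolve to 51 unified entries — one
structureless record carried neither a cross-reference nor a shared
identifier, so it correctly stays a separate entry rather than being
guessed into a merge. Six records pointed at pathway/pseudogene/ambiguous
targets and were rejected; the remaining 145 evidences collapse to 143
unique compound–gene relations, and homology expansion adds the 111
inferred relations the generator predicted.

```bash
$ ctkb query --kb demo/kb --q '"Relation Strength" = "strong" AND "Organism Name" = "Homo sapiens"'
R3ecffa8a8716
R8d38509a7ba2
Rc9211656ca33
```

Three relations to human targets have at least one evidence at or below
10 nM. Add `--format tsv --out hits.tsv` (or `xml`/`sdf`) to export them;
`ctkb export --kb demo/kb --format sdf --out all.sdf` writes one SDF
record per distinct compound, structures included.

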