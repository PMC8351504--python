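# Methods

## Data model

The toolkit represents glycoconjugate observations with the *referenced
compound* pattern: the identity of a molecule (a protein, a glycan) is kept
separate from each evidence-bearing instance of it. A
`gco:ReferencedGlycoconjugate` node stands for one observation of a
glycoconjugate in one curated source, and carries its protein part,
saccharide parts, biological source, citations and disease associations.
Sites and glycans hang off the conjugate independently: a saccharide part
does not point at a site. This is deliberate — glycoproteomics workflows
often identify glycans without site mapping, and the model must accept
partially missing site information. Consequently a saccharide part with no
associated site is valid, never a validation error.

Each curated source occupies its own named graph; the graph IRI is the unit
of provenance, and all cross-database reconciliation is phrased as
"which graphs bind this value".

### Namespaces

The vocabulary is fixed to the prefix table of the published query
prologues: `gco` (conjugate), `glycan` (GlycoRDF), `faldo`, `sio`,
`dcterms`, `foaf`, `rdfs`, `up`, and `skos`. Two quirks are inherited
knowingly rather than silently corrected:

* `skos` is `http://www.w3.org/2008/05/skos#` (the 2008 draft), not the
  2004 `skos/core` namespace — the queries only match data in the 2008
  namespace, so emitting the 2004 one would make disease notations
  invisible to them.
* `foaf:primaryTopicOf` is not a term of the official FOAF vocabulary
  (which defines `isPrimaryTopicOf`); the schema uses it, so the toolkit
  does too, via an open namespace.

Two predicates the schema names but never prints are placed in a dedicated,
explicitly non-normative extension namespace
`http://glycoinfo.org/glycocoo/extension#`: `gcox:abundance_ratio` (a
`xsd:decimal` in [0, 1] on the saccharide-part node — the ratio of one
glycan within the glycoforms observed) and `gcox:has_lipid_part` (the
structural mirror of `gco:has_protein_part` for glycolipids; no lipid
builders or fixtures are provided beyond validator support).

### Instance IRIs

Instance-IRI conventions are not part of the schema, so the toolkit mints
its own: `{base}/{kind}/{sha256(graph, kind, natural-key)[:16]}` under a
configurable base (default `http://glycoinfo.org/glycocoo/instance/`).
Natural keys are the scientific identifiers (accession, accession+position,
notation, PMID, source content). Minting is therefore deterministic and
graph-local: rebuilding a record is idempotent (RDF set semantics plus
stable IRIs), two runs produce byte-identical files, and the same protein
observed by two databases gets distinct per-graph instance nodes, as
separate evidence should. Blank nodes are never emitted, so documents can
be diffed across serializations. Cross-reference nodes use the public IRI
schemes directly (`purl.uniprot.org/uniprot/`, `rdf.glycoinfo.org/glycan/`,
`rdf.ncbi.nlm.nih.gov/pubmed/`).

Positions are 1-based UniProt residue indices stored as FALDO exact
positions (`xsd:integer`); only single positions are supported, since every
published example is a single residue. Accessions are validated against the
UniProt pattern and the GlyTouCan pattern `G[0-9]{5}[A-Z]{2}` at record
construction, so malformed input fails before any triple is written.

## Serialization

Parsing (Turtle, TriG, N-Quads) is rdflib's. Writing is a canonical
serializer of our own: a fixed sorted prefix block, graphs sorted by name,
one triple per line sorted lexicographically by (subject, predicate,
object), no abbreviation syntax. The price is larger files; the gain is
that equal datasets serialize to identical bytes, fixtures are diffable,
and round-trip identity (`parse ∘ write = id` on triple sets) is testable
mechanically. Turtle, having no graph syntax, is restricted to a single
selected graph.

## Validation

No formal shape definitions accompany the schema, so the validator derives
its rules from what the five queries treat as mandatory: the protein-part
chain (R1), the UniProt cross-reference (R2), the site chain with an
integer position ≥ 1 (R3), the glycan chain with a pattern-valid GlyTouCan
identifier (R4), disease label + notation (R5), citation PMID + PubMed
reference (R6), and at least one protein or lipid part per conjugate (R7).
Patterns the queries wrap in OPTIONAL — tissue, cell line, taxon, organism
name — are exempt: validation guarantees *queryability*, not metadata
completeness. Each rule also checks its chain's reverse direction (no
orphaned regions, saccharide parts, associations or citations), which makes
the validator sensitive to the deletion of any single triple on a mandatory
chain — the property the test suite exercises exhaustively. All findings
are errors; a binary conforms/violates outcome keeps reports and exit codes
unambiguous. Rules are evaluated per graph and reports are fully sorted, so
the outcome is independent of iteration order.

Implementation note: rules are evaluated by direct graph traversal in
rdflib rather than through a SHACL engine — seventeen fixed checks over
small graphs need no constraint language, and the traversal keeps violation
messages specific to each chain.

## Queries and local federation

The five query texts are stored byte-verbatim, including their duplicated
prefix declarations, their use of `rdfs:` without declaring it (supplied at
evaluation time through rdflib's `initNs`), and the sources query's
disconnected GlycoNAVI variables (`?ref_conjugate`/`?ref_protein` never
join the `?glycoconjugate_ref` source pattern, so that branch cross-joins
sources with protein chains). A `corrected=True` variant unifies those
variables; the verbatim form remains the default because fidelity to the
published text matters more than repairing it, and on single-protein graphs
the cross-join is harmless.

`SERVICE` blocks are rewritten offline-first: each block whose endpoint IRI
appears in the endpoint→graph mapping is replaced by its own body (which
carries its `GRAPH` wrapper, preserving named-graph scoping), so the
federated query evaluates entirely against the local dataset. This is
semantics-preserving whenever the local graphs equal the remote content —
the federation-equivalence tests assert exactly that identity. Unmapped
endpoints raise an error naming the IRI; live federation is opt-in
(`allow_remote`).

The typed runners (`run_sites` … `run_sources`) apply the same triple
patterns over *all* named graphs with an injected accession filter,
returning deduplicated dataclass rows with integers where the published
projections apply `str()`. Canonical orderings: sites by (graph, position),
glycans by (graph, accession), publications by (graph, PMID), sources by
(graph, then bound-ness of each optional field).

`overlap` partitions result values by the set of graphs binding them into
common-to-all / shared-by-some / unique-to-one; the partitions are disjoint
and exhaustive by construction, and with a single-graph universe everything
is unique-to-one.

## Fixtures

`fixture_haptoglobin` rebuilds the three-database haptoglobin (P00738)
example from its published cross-database facts: the per-database site
lists (GlyConnect 184/207/211/241, GlycoNAVI 184/207/211, UniCarbKB
184/187/207/211/241); the four GlyTouCan accessions reported by more than
one database (G22140GZ, G36131WL, G42358LZ, G62165AG — distributed so one
occurs in all three graphs and the others in two, plus two clearly
synthetic unshared accessions per graph so the unique-to-one partition is
non-trivial); esophageal cancer shared by GlyConnect + UniCarbKB and
hepatocellular carcinoma by GlycoNAVI + GlyConnect, each of GlyConnect and
GlycoNAVI adding one unshared cancer; *Homo sapiens* in all graphs, a cell
line only in GlycoNAVI, a tissue only in GlyConnect; and PMIDs overlapping
only between UniCarbKB and GlyConnect. Identifiers the example never
states — PMIDs, tissue/cell-line IRIs, the unshared glycan accessions —
are placeholders (e.g. PMIDs in the 9xxxxxxx range) chosen only to
preserve these sharing patterns; the two named cancers carry their real
Disease Ontology codes. `fixture_worked_example` encodes Q9EQH7 with its
asparagine site at residue 146 and one placeholder glycan; its other five
sites are not encoded because the source example details only this one.

## Synthetic generator

`synth(SynthParams)` emits every entity through the model builders and
records ground-truth tables of exactly what it generated — the oracle
against which all five query families are compared. Defaults model a small
multi-database curation scenario: 20 proteins, 1–5 sites per protein, 0–4
glycans per site, the three database graphs, with each protein entering
each graph independently with probability 0.7 (forced into one graph if it
would otherwise vanish) so cross-graph overlap is exercised. Diseases come
from a synthetic pool of eight labelled notations, PMIDs are random 8-digit
integers, sources draw from three mammalian taxa with optional tissue and
cell line; whether a taxon's scientific name is asserted is decided once
per (graph, taxon), since the taxon node is shared within a graph. All
randomness flows from a single seed; equal seeds give byte-identical
serializations.

What the generator does **not** emulate: real glycan structures or
compositions (accessions are random strings of the right shape),
correlated site/glycan biology, curation disagreements between databases
beyond random membership, free-text experimental-method metadata, or the
scale of production triplestores. Passing the oracle tests therefore shows
that building and querying are mutually consistent and lossless — not that
the toolkit's annotations are biologically meaningful.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by choice: the
fixture graphs hold ~170 triples, oracle checks use 8–20 proteins
(~1–2.5 k triples), round-trip properties use 100 two-protein datasets.
Abundance ratios are serialized as `xsd:decimal` with Python's shortest
`float` repr; positions and PMIDs as `xsd:integer`. Validation accepts
integer literals whether or not they carry an explicit datatype, and
rejects non-numeric or sub-1 positions rather than coercing them.

## Known limitations

* Glycolipids have structural support only (`gcox:has_lipid_part` in the
  validator); there are no lipid builders or fixtures.
* No OWL reasoning, and no resolution of cross-references against live
  UniProt/GlyTouCan services.
* The canonical writer covers Turtle/TriG/N-Quads only (no RDF/XML or
  JSON-LD) and is not meant for multi-gigabyte dumps.
* SPARQL support is whatever rdflib evaluates; `SERVICE` rewriting assumes
  brace-balanced query text (string literals containing braces inside a
  SERVICE block would confuse the block scanner).
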