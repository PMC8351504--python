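# glycocoo

A toolkit for the **GlycoConjugate Ontology (GlycoCoO)**: build, validate,
serialize and query standards-conformant RDF descriptions of glycoconjugates
— glycoproteins and glycolipids with their glycosylation sites, attached
glycans, abundance ratios, biological sources, disease associations and
literature citations.

## Why

Glycoproteomics experiments report which glycans occupy which sites of which
proteins, at what abundance, in which tissue and disease context — but very
little of this reaches databases, largely for want of a shared digital
representation. GlycoCoO extends the GlycoRDF *referenced compound* pattern:
a `gco:ReferencedGlycoconjugate` node anchors one evidence-bearing
observation, linking

* a protein part (`gco:has_protein_part` → `gco:has_protein` →
  `rdfs:seeAlso` → UniProt cross-reference with `dcterms:identifier`),
  glycosylated at FALDO regions (`gco:glycosylated_at` → `faldo:location` →
  `faldo:position`, 1-based residue numbers);
* saccharide parts (`gco:has_saccharide_part` → `glycan:has_glycan` →
  `foaf:primaryTopicOf` → GlyTouCan cross-reference), optionally with an
  abundance ratio in [0, 1];
* source (`glycan:is_from_source`: taxon, optional tissue and cell line),
  citations (`glycan:published_in`: PMID + PubMed IRI) and disease
  associations (`glycan:has_association` → `sio:SIO_000628`: label +
  ontology notation).

Because each curated source database publishes its records in its own named
graph, a single SPARQL query — federated across endpoints with `SERVICE`
clauses — can reconcile site lists, glycan accessions and metadata across
databases. This package ships those five canned queries verbatim, rewrites
the `SERVICE` blocks to run against local named graphs (no network), and
summarizes cross-graph overlap.

Audience: glycoinformatics developers and curators who need to emit
conformant GlycoCoO RDF from tabular records, check third-party datasets for
queryability, or reproduce cross-database integration results offline.

## Worked example

The bundled fixture rebuilds the three-database integration example for
human haptoglobin (UniProt **P00738**) as annotated by GlyConnect, UniCarbKB
and GlycoNAVI, one named graph per database:

```sh
$ glycocoo fixture haptoglobin -o hapto.trig
wrote haptoglobin fixture (169 triples) to hapto.trig

$ glycocoo validate hapto.trig
conforms: true (0 violations)

$ glycocoo query sites -d hapto.trig --uniprot P00738
graph	uniprot_id	position
http://glycoinfo.org/glycocoo/glyconavi	P00738	184
http://glycoinfo.org/glycocoo/glyconavi	P00738	207
http://glycoinfo.org/glycocoo/glyconavi	P00738	211
http://glycoinfo.org/glycocoo/glyconnect	P00738	184
http://glycoinfo.org/glycocoo/glyconnect	P00738	207
http://glycoinfo.org/glycocoo/glyconnect	P00738	211
http://glycoinfo.org/glycocoo/glyconnect	P00738	241
http://glycoinfo.org/glycocoo/unicarbkb	P00738	184
http://glycoinfo.org/glycocoo/unicarbkb	P00738	187
http://glycoinfo.org/glycocoo/unicarbkb	P00738	207
http://glycoinfo.org/glycocoo/unicarbkb	P00738	211
http://glycoinfo.org/glycocoo/unicarbkb	P00738	241
```

Twelve rows: GlyConnect annotates sites 184/207/211/241, GlycoNAVI
184/207/211, UniCarbKB 184/187/207/211/241 — so 184/207/211 are common to
all three databases, 187 is unique to UniCarbKB, and 241 is shared by two.
The same comparison in Python:

```python
>>> from glycocoo import fixture_haptoglobin, run_glycans, overlap
>>> ds = fixture_haptoglobin()
>>> ov = overlap(run_glycans(ds, "P00738"), key=lambda r: r.glytoucan_id)
>>> sorted(ov.multi_graph)
['G22140GZ', 'G36131WL', 'G42358LZ', 'G62165AG']
```

Exactly four GlyTouCan accessions are reported by more than one database.

Building your own dataset from a delimited record table:

```sh
$ glycocoo build -i records.csv -g http://example.org/mylab -o out.trig
wrote 16 triples, 1 conjugates to out.trig
```

Other subcommands: `query` also accepts a SPARQL file (its `SERVICE`
clauses are rewritten to local graphs; opt into live federation via a YAML
config with `allow_remote: true`), and `synth` generates seeded random
conformant datasets together with per-query ground-truth TSV tables.

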