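"""GlycoCoO vocabulary: the namespaces and predicate terms used by the toolkit.

The core namespaces are those declared in the prologues of the five published
GlycoCoO integration queries (gco, glycan, faldo, sio, dcterms, foaf, skos,
rdfs, up).  Note that ``skos`` here is the 2008 draft namespace
``http://www.w3.org/2008/05/skos#``, as declared by the query prologues — not
the 2004 ``skos/core`` namespace.

A small, explicitly non-normative extension namespace (``gcox``) carries the
two terms the published schema names but never prints a predicate for:
glycan abundance ratios and lipid parts.
"""

from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import DCTERMS, RDF, RDFS, XSD

# Open namespace: the published schema uses foaf:primaryTopicOf, which the
# closed rdflib FOAF namespace does not define.
FOAF = Namespace("http://xmlns.com/foaf/0.1/")

GCO = Namespace("http://purl.jp/bio/12/glyco/conjugate#")
GLYCAN = Namespace("http://purl.jp/bio/12/glyco/glycan#")
FALDO = Namespace("http://biohackathon.org/resource/faldo#")
SIO = Namespace("http://semanticscience.org/resource/")
SKOS2008 = Namespace("http://www.w3.org/2008/05/skos#")
UP = Namespace("http://purl.uniprot.org/core/")

#: Non-normative extension namespace for terms the schema names but does not
#: print a predicate for (abundance ratios, lipid parts).
GCOX = Namespace("http://glycoinfo.org/glycocoo/extension#")

#: Prefixes exactly as declared in the published query prologues.
PAPER_PREFIXES: dict[str, Namespace] = {
    "gco": GCO,
    "glycan": GLYCAN,
    "faldo": FALDO,
    "sio": SIO,
    "dcterms": DCTERMS,
    "foaf": FOAF,
    "skos": SKOS2008,
    "rdfs": RDFS,
    "up": UP,
}

#: Additional prefixes the toolkit itself needs (typing triples, literal
#: datatypes, the extension terms).
EXTRA_PREFIXES: dict[str, Namespace] = {
    "gcox": GCOX,
    "rdf": RDF,
    "xsd": XSD,
}

#: Full prefix table used for parsing, serialization and query evaluation.
VOCABULARY: dict[str, Namespace] = {**PAPER_PREFIXES, **EXTRA_PREFIXES}

# Classes
REFERENCED_GLYCOCONJUGATE = GCO.ReferencedGlycoconjugate
REFERENCED_PROTEIN = GCO.ReferencedProtein
REFERENCED_LIPID = GCO.ReferencedLipid

# Conjugate / protein predicates (query 1 & 2 patterns)
HAS_PROTEIN_PART = GCO.has_protein_part
HAS_SACCHARIDE_PART = GCO.has_saccharide_part
GLYCOSYLATED_AT = GCO.glycosylated_at
HAS_PROTEIN = GCO.has_protein

# Glycan predicates
HAS_GLYCAN = GLYCAN.has_glycan

# Metadata predicates (queries 3–5)
HAS_ASSOCIATION = GLYCAN.has_association
REFERS_TO_DISEASE = SIO.SIO_000628
PUBLISHED_IN = GLYCAN.published_in
HAS_PMID = GLYCAN.has_pmid
IS_FROM_SOURCE = GLYCAN.is_from_source
HAS_TAXON = GLYCAN.has_taxon
HAS_TISSUE = GLYCAN.has_tissue
HAS_CELL_LINE = GLYCAN.has_cell_line
SCIENTIFIC_NAME = UP.scientificName

# Extension predicates (non-normative; see module docstring)
ABUNDANCE_RATIO = GCOX.abundance_ratio
HAS_LIPID_PART = GCOX.has_lipid_part

#: Every predicate the builders may emit.  Validators and property tests use
#: this to assert that no stray term leaves the toolkit.
EMITTED_PREDICATES = frozenset(
    {
        RDF.type,
        HAS_PROTEIN_PART,
        HAS_SACCHARIDE_PART,
        GLYCOSYLATED_AT,
        HAS_PROTEIN,
        RDFS.seeAlso,
        RDFS.label,
        DCTERMS.identifier,
        DCTERMS.references,
        FALDO.location,
        FALDO.position,
        HAS_GLYCAN,
        FOAF.primaryTopicOf,
        HAS_ASSOCIATION,
        REFERS_TO_DISEASE,
        SKOS2008.notation,
        PUBLISHED_IN,
        HAS_PMID,
        IS_FROM_SOURCE,
        HAS_TAXON,
        HAS_TISSUE,
        HAS_CELL_LINE,
        SCIENTIFIC_NAME,
        ABUNDANCE_RATIO,
        HAS_LIPID_PART,
    }
)


def namespaces_for(term: str) -> Namespace:
    """Return the namespace bound to ``term`` (a prefix), or raise KeyError."""
    return VOCABULARY[term]
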