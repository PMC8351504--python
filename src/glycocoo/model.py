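"""Typed builders for GlycoCoO glycoconjugate graphs.

The central pattern is the *referenced compound*: a glycoconjugate instance
node (``gco:ReferencedGlycoconjugate``) anchors one evidence-bearing
observation of a glycoprotein, linking

* a protein part (``gco:has_protein_part``) whose protein cross-references a
  UniProt accession and carries glycosylation-site regions described with
  FALDO exact positions (1-based residue numbering),
* saccharide parts (``gco:has_saccharide_part``) whose glycans cross-reference
  GlyTouCan accessions, optionally annotated with an abundance ratio,
* a biological source (taxon, optional tissue and cell line),
* literature citations (PubMed), and
* disease associations (label + ontology notation).

Instance IRIs are minted deterministically from a graph-local hash of the
node's type and natural key, so building the same record twice — in the same
session or across runs — yields byte-identical graphs and never duplicates a
triple.  Blank nodes are never used.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, RDF, RDFS, XSD

from . import vocab
from .vocab import FOAF
from .dataset import NamedGraphDataset

#: Default base IRI under which instance nodes are minted.
DEFAULT_BASE_IRI = "http://glycoinfo.org/glycocoo/instance/"

#: UniProt accession pattern (6- or 10-character forms).
UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

#: GlyTouCan accession pattern, e.g. G22140GZ.
GLYTOUCAN_RE = re.compile(r"^G[0-9]{5}[A-Z]{2}$")

UNIPROT_PURL = "http://purl.uniprot.org/uniprot/"
GLYTOUCAN_PURL = "http://rdf.glycoinfo.org/glycan/"
PUBMED_PURL = "http://rdf.ncbi.nlm.nih.gov/pubmed/"


def new_dataset() -> NamedGraphDataset:
    """Create an empty named-graph dataset."""
    return NamedGraphDataset()


def _mint(base: str, graph_name: str, kind: str, *key: object) -> URIRef:
    digest = hashlib.sha256(
        "\x1f".join([str(graph_name), kind, *(str(k) for k in key)]).encode()
    ).hexdigest()[:16]
    return URIRef(f"{base}{kind}/{digest}")


# ---------------------------------------------------------------------------
# Input records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlycanObservation:
    """One observed glycan: a GlyTouCan accession, optionally with an abundance ratio."""

    accession: str
    abundance: Optional[float] = None

    def __post_init__(self) -> None:
        if not GLYTOUCAN_RE.match(self.accession):
            raise ValueError(
                f"glycans: {self.accession!r} is not a GlyTouCan accession "
                "(expected G + 5 digits + 2 uppercase letters, e.g. G22140GZ)"
            )
        if self.abundance is not None and not (0.0 <= self.abundance <= 1.0):
            raise ValueError(
                f"glycans: abundance ratio {self.abundance!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class SourceSpec:
    """Biological source: taxon IRI with optional scientific name, tissue, cell line."""

    taxon_iri: str
    organism: Optional[str] = None
    tissue_iri: Optional[str] = None
    cell_line_iri: Optional[str] = None


@dataclass(frozen=True)
class GlycoconjugateRecord:
    """Flat description of one glycoprotein observation, consumed by builders.

    Site positions are 1-based residue indices in the UniProt sequence.
    Sites and glycans are independent lists: the schema supports partially
    missing site information, so glycans are not bound to specific sites.
    """

    uniprot_id: str
    sites: tuple[int, ...] = ()
    glycans: tuple[GlycanObservation, ...] = ()
    source: Optional[SourceSpec] = None
    diseases: tuple[tuple[str, str], ...] = ()
    pmids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not UNIPROT_RE.match(self.uniprot_id):
            raise ValueError(
                f"uniprot_id: {self.uniprot_id!r} is not a UniProt accession"
            )
        for pos in self.sites:
            if not isinstance(pos, int) or pos < 1:
                raise ValueError(
                    f"sites: position {pos!r} invalid; positions are 1-based "
                    "residue numbers (>= 1)"
                )
        for label, notation in self.diseases:
            if not label or not notation:
                raise ValueError(
                    f"diseases: empty label or notation in ({label!r}, {notation!r})"
                )
        for pmid in self.pmids:
            if not isinstance(pmid, int) or pmid < 1:
                raise ValueError(f"pmids: {pmid!r} is not a positive integer")


# ---------------------------------------------------------------------------
# Graph-anchor node handles
# ---------------------------------------------------------------------------


@dataclass
class RegionNode:
    iri: URIRef
    location_iri: URIRef
    position: int


@dataclass
class ProteinPartNode:
    iri: URIRef
    protein_iri: URIRef
    xref_iri: URIRef
    uniprot_id: str
    regions: list[RegionNode] = field(default_factory=list)
    _graph: Graph = field(default=None, repr=False, compare=False)
    _graph_name: str = field(default="", repr=False, compare=False)
    _base: str = field(default=DEFAULT_BASE_IRI, repr=False, compare=False)


@dataclass
class SaccharidePartNode:
    iri: URIRef
    saccharide_iri: URIRef
    xref_iri: URIRef
    accession: str
    abundance: Optional[float] = None


@dataclass
class SourceNode:
    iri: URIRef
    taxon_iri: URIRef
    tissue_iri: Optional[URIRef] = None
    cell_line_iri: Optional[URIRef] = None
    organism: Optional[str] = None


@dataclass
class CitationNode:
    iri: URIRef
    pmid: int
    pubmed_iri: URIRef


@dataclass
class DiseaseAssociationNode:
    iri: URIRef
    disease_iri: URIRef
    label: str
    notation: str


@dataclass
class ReferencedGlycoconjugateNode:
    """Handle for a built conjugate; sub-builders append to the same graph."""

    iri: URIRef
    protein_part: Optional[ProteinPartNode] = None
    lipid_part: Optional[URIRef] = None
    saccharide_parts: list[SaccharidePartNode] = field(default_factory=list)
    source: Optional[SourceNode] = None
    citations: list[CitationNode] = field(default_factory=list)
    associations: list[DiseaseAssociationNode] = field(default_factory=list)
    _graph: Graph = field(default=None, repr=False, compare=False)
    _graph_name: str = field(default="", repr=False, compare=False)
    _base: str = field(default=DEFAULT_BASE_IRI, repr=False, compare=False)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _protein_part(
    g: Graph, graph_name: str, base: str, conjugate_iri: URIRef, uniprot_id: str
) -> ProteinPartNode:
    part_iri = _mint(base, graph_name, "protein-part", uniprot_id)
    protein_iri = _mint(base, graph_name, "protein", uniprot_id)
    xref_iri = URIRef(UNIPROT_PURL + uniprot_id)
    g.add((conjugate_iri, vocab.HAS_PROTEIN_PART, part_iri))
    g.add((part_iri, RDF.type, vocab.REFERENCED_PROTEIN))
    g.add((part_iri, vocab.HAS_PROTEIN, protein_iri))
    g.add((protein_iri, RDFS.seeAlso, xref_iri))
    g.add((xref_iri, DCTERMS.identifier, Literal(uniprot_id)))
    return ProteinPartNode(
        iri=part_iri,
        protein_iri=protein_iri,
        xref_iri=xref_iri,
        uniprot_id=uniprot_id,
        _graph=g,
        _graph_name=graph_name,
        _base=base,
    )


def add_glycosylation_site(part: ProteinPartNode, position: int) -> RegionNode:
    """Attach a glycosylation site at a 1-based residue ``position``.

    Emits the ``gco:glycosylated_at`` → ``faldo:location`` →
    ``faldo:position`` chain.  Repeated calls with the same position reuse
    the same region node (keyed by protein and position), so the call is
    idempotent.
    """
    if not isinstance(position, int) or position < 1:
        raise ValueError(
            f"position {position!r} invalid: glycosylation sites use 1-based "
            "residue numbering (position >= 1)"
        )
    g, base, gname = part._graph, part._base, part._graph_name
    region_iri = _mint(base, gname, "region", part.uniprot_id, position)
    location_iri = _mint(base, gname, "location", part.uniprot_id, position)
    g.add((part.iri, vocab.GLYCOSYLATED_AT, region_iri))
    g.add((region_iri, vocab.FALDO.location, location_iri))
    g.add((location_iri, vocab.FALDO.position, Literal(position, datatype=XSD.integer)))
    node = RegionNode(iri=region_iri, location_iri=location_iri, position=position)
    if all(r.iri != region_iri for r in part.regions):
        part.regions.append(node)
    return node


def add_saccharide(
    conjugate: ReferencedGlycoconjugateNode,
    glytoucan_id: str,
    abundance: Optional[float] = None,
) -> SaccharidePartNode:
    """Attach a saccharide part referencing a GlyTouCan accession.

    The optional ``abundance`` is the glycan's abundance ratio within the
    observed glycoforms, a fraction in [0, 1], stored via the non-normative
    extension predicate ``gcox:abundance_ratio`` on the saccharide-part node.
    """
    obs = GlycanObservation(glytoucan_id, abundance)  # validates both fields
    g, base, gname = conjugate._graph, conjugate._base, conjugate._graph_name
    part_iri = _mint(base, gname, "saccharide-part", conjugate.iri, obs.accession)
    sacc_iri = _mint(base, gname, "saccharide", obs.accession)
    xref_iri = URIRef(GLYTOUCAN_PURL + obs.accession)
    g.add((conjugate.iri, vocab.HAS_SACCHARIDE_PART, part_iri))
    g.add((part_iri, vocab.HAS_GLYCAN, sacc_iri))
    g.add((sacc_iri, FOAF.primaryTopicOf, xref_iri))
    g.add((xref_iri, DCTERMS.identifier, Literal(obs.accession)))
    if obs.abundance is not None:
        g.add(
            (
                part_iri,
                vocab.ABUNDANCE_RATIO,
                Literal(f"{obs.abundance}", datatype=XSD.decimal),
            )
        )
    node = SaccharidePartNode(
        iri=part_iri,
        saccharide_iri=sacc_iri,
        xref_iri=xref_iri,
        accession=obs.accession,
        abundance=obs.abundance,
    )
    if all(p.iri != part_iri for p in conjugate.saccharide_parts):
        conjugate.saccharide_parts.append(node)
    return node


def add_metadata(
    conjugate: ReferencedGlycoconjugateNode,
    source: Optional[SourceSpec] = None,
    citations: Sequence[int] = (),
    diseases: Sequence[tuple[str, str]] = (),
) -> ReferencedGlycoconjugateNode:
    """Attach source, citation and disease-association metadata.

    Tissue and cell line are independently optional on the source; the taxon
    may carry an ``up:scientificName``.  Citations emit both
    ``glycan:has_pmid`` and ``dcterms:references``.  Disease nodes carry both
    ``rdfs:label`` and ``skos:notation``.
    """
    g, base, gname = conjugate._graph, conjugate._base, conjugate._graph_name

    if source is not None:
        source_iri = _mint(
            base,
            gname,
            "source",
            source.taxon_iri,
            source.tissue_iri,
            source.cell_line_iri,
        )
        taxon_iri = URIRef(source.taxon_iri)
        g.add((conjugate.iri, vocab.IS_FROM_SOURCE, source_iri))
        g.add((source_iri, vocab.HAS_TAXON, taxon_iri))
        if source.organism:
            g.add((taxon_iri, vocab.SCIENTIFIC_NAME, Literal(source.organism)))
        tissue = cell_line = None
        if source.tissue_iri:
            tissue = URIRef(source.tissue_iri)
            g.add((source_iri, vocab.HAS_TISSUE, tissue))
        if source.cell_line_iri:
            cell_line = URIRef(source.cell_line_iri)
            g.add((source_iri, vocab.HAS_CELL_LINE, cell_line))
        conjugate.source = SourceNode(
            iri=source_iri,
            taxon_iri=taxon_iri,
            tissue_iri=tissue,
            cell_line_iri=cell_line,
            organism=source.organism,
        )

    for pmid in citations:
        if not isinstance(pmid, int) or pmid < 1:
            raise ValueError(f"pmids: {pmid!r} is not a positive integer")
        citation_iri = _mint(base, gname, "citation", pmid)
        pubmed_iri = URIRef(f"{PUBMED_PURL}{pmid}")
        g.add((conjugate.iri, vocab.PUBLISHED_IN, citation_iri))
        g.add((citation_iri, vocab.HAS_PMID, Literal(pmid, datatype=XSD.integer)))
        g.add((citation_iri, DCTERMS.references, pubmed_iri))
        node = CitationNode(iri=citation_iri, pmid=pmid, pubmed_iri=pubmed_iri)
        if all(c.iri != citation_iri for c in conjugate.citations):
            conjugate.citations.append(node)

    for label, notation in diseases:
        if not label or not notation:
            raise ValueError(
                f"diseases: empty label or notation in ({label!r}, {notation!r})"
            )
        association_iri = _mint(base, gname, "association", conjugate.iri, notation)
        disease_iri = _mint(base, gname, "disease", notation)
        g.add((conjugate.iri, vocab.HAS_ASSOCIATION, association_iri))
        g.add((association_iri, vocab.REFERS_TO_DISEASE, disease_iri))
        g.add((disease_iri, RDFS.label, Literal(label)))
        g.add((disease_iri, vocab.SKOS2008.notation, Literal(notation)))
        node = DiseaseAssociationNode(
            iri=association_iri, disease_iri=disease_iri, label=label, notation=notation
        )
        if all(a.iri != association_iri for a in conjugate.associations):
            conjugate.associations.append(node)

    return conjugate


def build_conjugate(
    dataset: NamedGraphDataset,
    graph: str | URIRef,
    record: GlycoconjugateRecord,
    base_iri: str = DEFAULT_BASE_IRI,
) -> ReferencedGlycoconjugateNode:
    """Build the full referenced-glycoconjugate graph for ``record``.

    All triples needed to answer the five canned queries (sites, glycans,
    diseases, publications, sources) are inserted into the named ``graph``.
    Building an identical record twice leaves the graph unchanged.
    """
    gname = str(graph)
    g = dataset.graph(gname)
    conjugate_iri = _mint(base_iri, gname, "conjugate", record.uniprot_id)
    g.add((conjugate_iri, RDF.type, vocab.REFERENCED_GLYCOCONJUGATE))
    conjugate = ReferencedGlycoconjugateNode(
        iri=conjugate_iri, _graph=g, _graph_name=gname, _base=base_iri
    )
    conjugate.protein_part = _protein_part(
        g, gname, base_iri, conjugate_iri, record.uniprot_id
    )
    for position in record.sites:
        add_glycosylation_site(conjugate.protein_part, position)
    for obs in record.glycans:
        add_saccharide(conjugate, obs.accession, obs.abundance)
    add_metadata(
        conjugate,
        source=record.source,
        citations=record.pmids,
        diseases=record.diseases,
    )
    return conjugate
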