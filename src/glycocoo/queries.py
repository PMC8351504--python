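"""The five canned GlycoCoO integration queries, SERVICE rewriting, overlap.

Two evaluation surfaces are provided:

* :func:`run_paper_query` evaluates the published query texts verbatim
  (stored in :data:`PAPER_QUERIES`), after locally rewriting their SPARQL 1.1
  ``SERVICE`` clauses so the three-database federation runs against named
  graphs of a local dataset with zero network access.

* The typed runners (:func:`run_sites`, :func:`run_glycans`,
  :func:`run_diseases`, :func:`run_publications`, :func:`run_sources`) apply
  the same graph patterns over *all* named graphs of a dataset, filter by a
  UniProt accession, and return typed, deduplicated, canonically ordered
  rows (positions and PMIDs as integers rather than strings).

:func:`overlap` partitions query-result values by the set of graphs binding
them — the cross-database reconciliation step (which sites/glycans/diseases
are common to all sources, shared by some, or unique to one).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence, TypeVar

from .dataset import NamedGraphDataset
from .model import GLYTOUCAN_RE, UNIPROT_RE

GRAPH_GLYCONNECT = "http://glycoinfo.org/glycocoo/glyconnect"
GRAPH_UNICARBKB = "http://glycoinfo.org/glycocoo/unicarbkb"
GRAPH_GLYCONAVI = "http://glycoinfo.org/glycocoo/glyconavi"

GLYCONAVI_ENDPOINT = "https://sparql.glyconavi.org/sparql"

#: Default endpoint → named-graph mapping for local SERVICE rewriting.
DEFAULT_ENDPOINT_GRAPHS: dict[str, str] = {GLYCONAVI_ENDPOINT: GRAPH_GLYCONAVI}


class ServiceRewriteError(ValueError):
    """A SERVICE endpoint IRI has no local graph mapping in offline mode."""


# ---------------------------------------------------------------------------
# Published query texts (verbatim)
# ---------------------------------------------------------------------------

SITES_QUERY = """\
prefix gco:<http://purl.jp/bio/12/glyco/conjugate#>
prefix dcterms:<http://purl.org/dc/terms/>
prefix faldo:<http://biohackathon.org/resource/faldo#>
prefix dcterms:<http://purl.org/dc/terms/>
select distinct ?g ?uniprot_id (str(?position) AS ?site)
where
{
{
graph ?g {
VALUES ?g { <http://glycoinfo.org/glycocoo/glyconnect> <http://glycoinfo.org/glycocoo/unicarbkb>}
# GlyConnect and UniCarbKB
?ref_conjugate gco:has_protein_part ?ref_protein.
?ref_protein gco:glycosylated_at ?region .
?region faldo:location ?location .
?location faldo:position ?position .
?ref_protein gco:has_protein ?protein .
?protein rdfs:seeAlso ?uniprot .
?uniprot dcterms:identifier ?uniprot_id .
}
}
UNION
{
# GlycoNAVI
SERVICE <https://sparql.glyconavi.org/sparql> {
graph ?g {
VALUES ?g { <http://glycoinfo.org/glycocoo/glyconavi> }
?ref_conjugate gco:has_protein_part ?ref_protein .
?ref_protein gco:glycosylated_at ?region .
?region faldo:location ?location .
?location faldo:position ?position .
?ref_protein gco:has_protein ?protein .
?protein rdfs:seeAlso ?uniprot .
?uniprot dcterms:identifier ?uniprot_id .
}
}
}
}
order by ?g ?position
"""

GLYCANS_QUERY = """\
# Glycan Part
prefix glycan:<http://purl.jp/bio/12/glyco/glycan#>
prefix gco:<http://purl.jp/bio/12/glyco/conjugate#>
prefix dcterms:<http://purl.org/dc/terms/>
prefix faldo:<http://biohackathon.org/resource/faldo#>
prefix sio:<http://semanticscience.org/resource/>
prefix foaf:<http://xmlns.com/foaf/0.1/>
select distinct ?g ?uniprot_id ?glytoucan_id
where
{
{
graph ?g{
VALUES ?g { <http://glycoinfo.org/glycocoo/glyconnect> <http://glycoinfo.org/glycocoo/unicarbkb>}
# GlyConnect & UniCarbKB
?glycoconjugate_ref gco:has_protein_part ?protein_part.
?protein_part gco:has_protein ?protein.
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
?glycoconjugate_ref gco:has_saccharide_part ?ref_sac.
?ref_sac glycan:has_glycan ?saccharide.
?saccharide foaf:primaryTopicOf ?glytoucan.
?glytoucan dcterms:identifier ?glytoucan_id.
}
}
UNION
{
# GlycoNAVI
SERVICE <https://sparql.glyconavi.org/sparql> {
graph ?g {
VALUES ?g{<http://glycoinfo.org/glycocoo/glyconavi>}
?glycoconjugate_ref gco:has_protein_part ?protein_part.
?protein_part gco:has_protein ?protein.
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
?glycoconjugate_ref gco:has_saccharide_part ?ref_sac.
?ref_sac glycan:has_glycan ?saccharide.
?saccharide foaf:primaryTopicOf ?glytoucan.
?glytoucan dcterms:identifier ?glytoucan_id.
}
}
}
}
order by ?g ?uniprot_id ?glytoucan_id
"""

DISEASES_QUERY = """\
# Disease Association part
PREFIX glycan:<http://purl.jp/bio/12/glyco/glycan#>
PREFIX gco:<http://purl.jp/bio/12/glyco/conjugate#>
PREFIX skos:<http://www.w3.org/2008/05/skos#>
PREFIX dcterms:<http://purl.org/dc/terms/>
PREFIX faldo:<http://biohackathon.org/resource/faldo#>
PREFIX sio:<http://semanticscience.org/resource/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT DISTINCT ?g ?disease_label ?notation ?uniprot_id
WHERE
{
{
graph ?g {
VALUES ?g {<http://glycoinfo.org/glycocoo/glyconnect> <http://glycoinfo.org/glycocoo/unicarbkb>}
# GlyConnect & UniCarbKB
?glycoconjugate_ref glycan:has_association ?association;
gco:has_protein_part ?protein_part.
?association sio:SIO_000628 ?disease.
?disease rdfs:label ?disease_label.
?disease skos:notation ?notation.
?protein_part gco:has_protein ?protein .
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
VALUES ?uniprot_id {"P00738"}
}
}
UNION
{
# GlycoNAVI
SERVICE <https://sparql.glyconavi.org/sparql> {
graph ?g {
VALUES ?g {<http://glycoinfo.org/glycocoo/glyconavi>}
?glycoconjugate_ref glycan:has_association ?association;
gco:has_protein_part ?protein_part.
?association sio:SIO_000628 ?disease.
?disease rdfs:label ?disease_label.
?disease skos:notation ?notation.
?protein_part gco:has_protein ?protein.
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
VALUES ?uniprot_id {"P00738"}
}
}
}
}
ORDER BY ?g
"""

PUBLICATIONS_QUERY = """\
prefix glycan:<http://purl.jp/bio/12/glyco/glycan#>
prefix gco:<http://purl.jp/bio/12/glyco/conjugate#>
prefix dcterms:<http://purl.org/dc/terms/>
prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#>
select distinct ?g ?uniprot_id (str (?pmid) AS ?PMID)
where
{
{
graph ?g {
VALUES ?g { <http://glycoinfo.org/glycocoo/glyconnect> <http://glycoinfo.org/glycocoo/unicarbkb>}
?glycoconjugate_ref glycan:published_in ?citation.
?glycoconjugate_ref gco:has_protein_part ?protein_part.
?protein_part gco:has_protein ?protein.
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
VALUES ?uniprot_id {"P00738"}
# glyconnect & unicarbkb
?citation dcterms:references ?pubmed.
?citation glycan:has_pmid ?pmid.
}
}
UNION
{
# GlycoNAVI
SERVICE <https://sparql.glyconavi.org/sparql> {
graph ?g {
VALUES ?g {<http://glycoinfo.org/glycocoo/glyconavi>}
?glycoconjugate_ref glycan:published_in ?citation.
?glycoconjugate_ref gco:has_protein_part ?protein_part.
?protein_part gco:has_protein ?protein.
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
VALUES ?uniprot_id {"P00738"}
?citation dcterms:references ?pubmed.
?citation glycan:has_pmid ?pmid.
}
}
}
}
order by ?g ?pmid
"""

SOURCES_QUERY = """\
prefix glycan:<http://purl.jp/bio/12/glyco/glycan#>
prefix gco:<http://purl.jp/bio/12/glyco/conjugate#>
prefix dcterms:<http://purl.org/dc/terms/>
prefix faldo:<http://biohackathon.org/resource/faldo#>
prefix sio:<http://semanticscience.org/resource/>
prefix dcterms:<http://purl.org/dc/terms/>
prefix up: <http://purl.uniprot.org/core/>
select distinct ?g ?uniprot_id ?tissue ?cell_line ?organism
where
{
{
graph ?g {
VALUES ?g {<http://glycoinfo.org/glycocoo/glyconnect> <http://glycoinfo.org/glycocoo/unicarbkb>}
# glyconnect & unicarbkb
?glycoconjugate_ref glycan:is_from_source ?source; gco:has_protein_part ?protein_part.
optional {?source glycan:has_tissue ?tissue.}
optional {?source glycan:has_cell_line ?cell_line.}
?protein_part gco:has_protein ?protein.
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
VALUES ?uniprot_id {"P00738"}
optional {
?source glycan:has_taxon ?taxon.
OPTIONAL {?taxon up:scientificName ?organism.}
}
}
}
UNION
{
# GlycoNAVI
SERVICE <https://sparql.glyconavi.org/sparql> {
graph ?g {
VALUES ?g {<http://glycoinfo.org/glycocoo/glyconavi>}
?glycoconjugate_ref glycan:is_from_source ?source;
gco:has_protein_part ?protein_part.
optional{?source glycan:has_tissue ?tissue.}
optional{?source glycan:has_cell_line ?cell_line.}
optional{
?source glycan:has_taxon ?taxon.
optional {?taxon up:scientificName ?organism.}
}
?ref_conjugate gco:has_protein_part ?ref_protein.
?ref_protein gco:has_protein ?protein .
?protein rdfs:seeAlso ?uniprot.
?uniprot dcterms:identifier ?uniprot_id.
VALUES ?uniprot_id {"P00738"}
}
}
}
}
order by ?g ?tissue ?cell_line ?taxon
"""

#: Published queries by canned name.
PAPER_QUERIES: dict[str, str] = {
    "sites": SITES_QUERY,
    "glycans": GLYCANS_QUERY,
    "diseases": DISEASES_QUERY,
    "publications": PUBLICATIONS_QUERY,
    "sources": SOURCES_QUERY,
}

# The published sources query binds the protein chain of its GlycoNAVI branch
# through variables (?ref_conjugate/?ref_protein) disjoint from the source
# pattern's ?glycoconjugate_ref, which cross-joins sources with proteins.
# The corrected variant unifies the variables so the branch joins properly.
_SOURCES_CORRECTIONS = (
    ("?ref_conjugate gco:has_protein_part ?ref_protein.",
     "?glycoconjugate_ref gco:has_protein_part ?protein_part."),
    ("?ref_protein gco:has_protein ?protein .",
     "?protein_part gco:has_protein ?protein ."),
)


def paper_query(name: str, corrected: bool = False) -> str:
    """Return a canned query text; ``corrected`` unifies the variables of the
    sources query's GlycoNAVI branch (see module comment)."""
    try:
        text = PAPER_QUERIES[name]
    except KeyError:
        raise KeyError(
            f"unknown query {name!r}; valid names: {sorted(PAPER_QUERIES)}"
        ) from None
    if corrected and name == "sources":
        for old, new in _SOURCES_CORRECTIONS:
            text = text.replace(old, new)
    return text


# ---------------------------------------------------------------------------
# SERVICE rewriting
# ---------------------------------------------------------------------------

_SERVICE_RE = re.compile(r"SERVICE\s*<([^>]*)>\s*\{", re.IGNORECASE)


def rewrite_service(
    query_text: str,
    endpoint_to_graph: Mapping[str, str] = DEFAULT_ENDPOINT_GRAPHS,
    allow_remote: bool = False,
) -> str:
    """Replace each mapped ``SERVICE <endpoint> { body }`` block by ``{ body }``.

    The body keeps its own ``GRAPH`` wrapper, so named-graph scoping is
    preserved and the pattern evaluates against the local dataset.  An
    endpoint absent from ``endpoint_to_graph`` raises
    :class:`ServiceRewriteError` naming the IRI, unless ``allow_remote`` is
    set, in which case the block is passed through untouched for live
    federation.
    """
    out = []
    pos = 0
    while True:
        m = _SERVICE_RE.search(query_text, pos)
        if m is None:
            out.append(query_text[pos:])
            break
        endpoint = m.group(1)
        # find the matching close brace of the block opened at m.end() - 1
        depth = 1
        i = m.end()
        while i < len(query_text) and depth:
            if query_text[i] == "{":
                depth += 1
            elif query_text[i] == "}":
                depth -= 1
            i += 1
        if depth:
            raise ValueError("unbalanced braces in SERVICE block")
        if endpoint in endpoint_to_graph:
            body = query_text[m.end(): i - 1]
            out.append(query_text[pos: m.start()])
            out.append("{" + body + "}")
        elif allow_remote:
            out.append(query_text[pos:i])
        else:
            raise ServiceRewriteError(
                f"no local graph mapped for SERVICE endpoint <{endpoint}> "
                "in offline mode"
            )
        pos = i
    return "".join(out)


def run_paper_query(
    dataset: NamedGraphDataset,
    name_or_text: str,
    endpoint_to_graph: Mapping[str, str] = DEFAULT_ENDPOINT_GRAPHS,
    corrected: bool = False,
    allow_remote: bool = False,
):
    """Evaluate a canned query (by name) or arbitrary SPARQL text locally.

    SERVICE blocks are rewritten per ``endpoint_to_graph`` first; the result
    is an rdflib SELECT result.
    """
    text = (
        paper_query(name_or_text, corrected=corrected)
        if name_or_text in PAPER_QUERIES
        else name_or_text
    )
    text = rewrite_service(text, endpoint_to_graph, allow_remote=allow_remote)
    return dataset.query(text)


# ---------------------------------------------------------------------------
# Typed result rows
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SiteRow:
    graph: str
    uniprot_id: str
    position: int


@dataclass(frozen=True, order=True)
class GlycanRow:
    graph: str
    uniprot_id: str
    glytoucan_id: str


@dataclass(frozen=True, order=True)
class DiseaseRow:
    graph: str
    disease_label: str
    notation: str
    uniprot_id: str


@dataclass(frozen=True, order=True)
class PublicationRow:
    graph: str
    uniprot_id: str
    pmid: int


@dataclass(frozen=True)
class SourceRow:
    graph: str
    uniprot_id: str
    tissue: Optional[str] = None
    cell_line: Optional[str] = None
    organism: Optional[str] = None

    def sort_key(self):
        opt = lambda v: (v is not None, v or "")
        return (self.graph, self.uniprot_id, opt(self.tissue),
                opt(self.cell_line), opt(self.organism))


def _check_accession(uniprot_id: str) -> str:
    if not UNIPROT_RE.match(uniprot_id):
        raise ValueError(f"{uniprot_id!r} is not a UniProt accession")
    return uniprot_id


_SITES_PATTERN = """\
SELECT DISTINCT ?g ?uniprot_id ?position
WHERE {{
  GRAPH ?g {{
    ?ref_conjugate gco:has_protein_part ?ref_protein .
    ?ref_protein gco:glycosylated_at ?region .
    ?region faldo:location ?location .
    ?location faldo:position ?position .
    ?ref_protein gco:has_protein ?protein .
    ?protein rdfs:seeAlso ?uniprot .
    ?uniprot dcterms:identifier ?uniprot_id .
    VALUES ?uniprot_id {{ "{acc}" }}
  }}
}}
"""

_GLYCANS_PATTERN = """\
SELECT DISTINCT ?g ?uniprot_id ?glytoucan_id
WHERE {{
  GRAPH ?g {{
    ?glycoconjugate_ref gco:has_protein_part ?protein_part .
    ?protein_part gco:has_protein ?protein .
    ?protein rdfs:seeAlso ?uniprot .
    ?uniprot dcterms:identifier ?uniprot_id .
    ?glycoconjugate_ref gco:has_saccharide_part ?ref_sac .
    ?ref_sac glycan:has_glycan ?saccharide .
    ?saccharide foaf:primaryTopicOf ?glytoucan .
    ?glytoucan dcterms:identifier ?glytoucan_id .
    VALUES ?uniprot_id {{ "{acc}" }}
  }}
}}
"""

_DISEASES_PATTERN = """\
SELECT DISTINCT ?g ?disease_label ?notation ?uniprot_id
WHERE {{
  GRAPH ?g {{
    ?glycoconjugate_ref glycan:has_association ?association ;
                        gco:has_protein_part ?protein_part .
    ?association sio:SIO_000628 ?disease .
    ?disease rdfs:label ?disease_label .
    ?disease skos:notation ?notation .
    ?protein_part gco:has_protein ?protein .
    ?protein rdfs:seeAlso ?uniprot .
    ?uniprot dcterms:identifier ?uniprot_id .
    VALUES ?uniprot_id {{ "{acc}" }}
  }}
}}
"""

_PUBLICATIONS_PATTERN = """\
SELECT DISTINCT ?g ?uniprot_id ?pmid
WHERE {{
  GRAPH ?g {{
    ?glycoconjugate_ref glycan:published_in ?citation ;
                        gco:has_protein_part ?protein_part .
    ?protein_part gco:has_protein ?protein .
    ?protein rdfs:seeAlso ?uniprot .
    ?uniprot dcterms:identifier ?uniprot_id .
    ?citation dcterms:references ?pubmed .
    ?citation glycan:has_pmid ?pmid .
    VALUES ?uniprot_id {{ "{acc}" }}
  }}
}}
"""

_SOURCES_PATTERN = """\
SELECT DISTINCT ?g ?uniprot_id ?tissue ?cell_line ?organism
WHERE {{
  GRAPH ?g {{
    ?glycoconjugate_ref glycan:is_from_source ?source ;
                        gco:has_protein_part ?protein_part .
    OPTIONAL {{ ?source glycan:has_tissue ?tissue . }}
    OPTIONAL {{ ?source glycan:has_cell_line ?cell_line . }}
    OPTIONAL {{
      ?source glycan:has_taxon ?taxon .
      OPTIONAL {{ ?taxon up:scientificName ?organism . }}
    }}
    ?protein_part gco:has_protein ?protein .
    ?protein rdfs:seeAlso ?uniprot .
    ?uniprot dcterms:identifier ?uniprot_id .
    VALUES ?uniprot_id {{ "{acc}" }}
  }}
}}
"""


def run_sites(dataset: NamedGraphDataset, uniprot_id: str) -> list[SiteRow]:
    """Glycosylation sites of ``uniprot_id``, per graph, ordered by (graph, position)."""
    acc = _check_accession(uniprot_id)
    res = dataset.query(_SITES_PATTERN.format(acc=acc))
    rows = {
        SiteRow(graph=str(r.g), uniprot_id=str(r.uniprot_id), position=int(r.position))
        for r in res
    }
    return sorted(rows)


def run_glycans(dataset: NamedGraphDataset, uniprot_id: str) -> list[GlycanRow]:
    """GlyTouCan accessions attached to ``uniprot_id``, per graph."""
    acc = _check_accession(uniprot_id)
    res = dataset.query(_GLYCANS_PATTERN.format(acc=acc))
    rows = {
        GlycanRow(
            graph=str(r.g),
            uniprot_id=str(r.uniprot_id),
            glytoucan_id=str(r.glytoucan_id),
        )
        for r in res
    }
    return sorted(rows)


def run_diseases(dataset: NamedGraphDataset, uniprot_id: str) -> list[DiseaseRow]:
    """Disease associations (label + notation are both mandatory)."""
    acc = _check_accession(uniprot_id)
    res = dataset.query(_DISEASES_PATTERN.format(acc=acc))
    rows = {
        DiseaseRow(
            graph=str(r.g),
            disease_label=str(r.disease_label),
            notation=str(r.notation),
            uniprot_id=str(r.uniprot_id),
        )
        for r in res
    }
    return sorted(rows)


def run_publications(
    dataset: NamedGraphDataset, uniprot_id: str
) -> list[PublicationRow]:
    """PubMed citations; both has_pmid and dcterms:references are required."""
    acc = _check_accession(uniprot_id)
    res = dataset.query(_PUBLICATIONS_PATTERN.format(acc=acc))
    rows = {
        PublicationRow(graph=str(r.g), uniprot_id=str(r.uniprot_id), pmid=int(r.pmid))
        for r in res
    }
    return sorted(rows)


def run_sources(dataset: NamedGraphDataset, uniprot_id: str) -> list[SourceRow]:
    """Biological sources; tissue, cell line and organism are OPTIONAL (kept unbound)."""
    acc = _check_accession(uniprot_id)
    res = dataset.query(_SOURCES_PATTERN.format(acc=acc))
    rows = {
        SourceRow(
            graph=str(r.g),
            uniprot_id=str(r.uniprot_id),
            tissue=None if r.tissue is None else str(r.tissue),
            cell_line=None if r.cell_line is None else str(r.cell_line),
            organism=None if r.organism is None else str(r.organism),
        )
        for r in res
    }
    return sorted(rows, key=SourceRow.sort_key)


RUNNERS: dict[str, Callable[[NamedGraphDataset, str], list]] = {
    "sites": run_sites,
    "glycans": run_glycans,
    "diseases": run_diseases,
    "publications": run_publications,
    "sources": run_sources,
}


# ---------------------------------------------------------------------------
# Cross-graph overlap
# ---------------------------------------------------------------------------

T = TypeVar("T")
V = TypeVar("V")


@dataclass(frozen=True)
class OverlapSummary:
    """Partition of values by the set of graphs binding them.

    ``common_to_all`` holds values bound in every graph of the universe,
    ``unique_to_one`` values bound in exactly one graph, ``shared_by_some``
    the rest.  The three partitions are disjoint and exhaustive; with a
    single-graph universe every value is unique-to-one.
    """

    graphs_by_value: dict
    universe: frozenset

    @property
    def unique_to_one(self) -> set:
        return {v for v, gs in self.graphs_by_value.items() if len(gs) == 1}

    @property
    def common_to_all(self) -> set:
        return {
            v
            for v, gs in self.graphs_by_value.items()
            if len(gs) > 1 and gs == self.universe
        }

    @property
    def shared_by_some(self) -> set:
        return (
            set(self.graphs_by_value) - self.unique_to_one - self.common_to_all
        )

    @property
    def multi_graph(self) -> set:
        """Values bound in more than one graph."""
        return {v for v, gs in self.graphs_by_value.items() if len(gs) > 1}


def overlap(
    rows: Iterable[T],
    key: Callable[[T], V],
    universe: Optional[Sequence[str]] = None,
) -> OverlapSummary:
    """Group ``key(row)`` values by the set of graphs binding them.

    The universe defaults to the set of graphs observed in ``rows``; pass an
    explicit graph list to treat absent graphs as part of the comparison.
    """
    by_value: dict = {}
    seen_graphs: set[str] = set(str(g) for g in universe) if universe else set()
    for row in rows:
        by_value.setdefault(key(row), set()).add(row.graph)
        seen_graphs.add(row.graph)
    return OverlapSummary(
        graphs_by_value={v: frozenset(gs) for v, gs in by_value.items()},
        universe=frozenset(seen_graphs),
    )
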