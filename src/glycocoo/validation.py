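"""Structural validation of GlycoCoO datasets.

The rules guarantee *queryability*: every chain the five canned queries treat
as mandatory must be complete, while patterns the queries wrap in OPTIONAL
(tissue, cell line, taxon, organism name) are exempt.  Each rule also checks
the reverse direction of its chain (no orphaned region/saccharide/citation/
association nodes), so removing any single triple from a mandatory chain is
detected.

Rules (all errors; there is no warning tier):

R1  every ``gco:has_protein_part`` object has ``gco:has_protein``, and every
    protein-part node is referenced by some conjugate;
R2  every protein has ``rdfs:seeAlso`` to a cross-reference carrying
    ``dcterms:identifier``;
R3  every ``gco:glycosylated_at`` region chains ``faldo:location`` →
    ``faldo:position`` with an integer ≥ 1, and every located region is
    referenced by some protein part;
R4  every ``gco:has_saccharide_part`` object chains ``glycan:has_glycan`` →
    ``foaf:primaryTopicOf`` → ``dcterms:identifier`` matching the GlyTouCan
    pattern, and every glycan-bearing part is referenced by some conjugate;
R5  every disease (object of ``sio:SIO_000628``) carries both ``rdfs:label``
    and ``skos:notation``, and every association is referenced by some
    conjugate;
R6  every citation carries both ``glycan:has_pmid`` and
    ``dcterms:references``, and every PMID-bearing node is referenced by
    some conjugate;
R7  every ``gco:ReferencedGlycoconjugate`` has at least one protein or lipid
    part.

A saccharide part without any site mapping is *not* a violation: the schema
explicitly supports partially missing site information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, RDF, RDFS, XSD

from . import vocab
from .vocab import FOAF
from .dataset import NamedGraphDataset
from .model import GLYTOUCAN_RE


@dataclass(frozen=True, order=True)
class Violation:
    rule_id: str
    graph: str
    focus: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def conforms(self) -> bool:
        return not self.violations

    def by_rule(self, rule_id: str) -> list[Violation]:
        return [v for v in self.violations if v.rule_id == rule_id]

    def as_table(self) -> str:
        """Plain-text report, one row per violation."""
        if self.conforms:
            return "conforms: true (0 violations)\n"
        header = "rule\tgraph\tfocus\tmessage"
        rows = [
            f"{v.rule_id}\t{v.graph}\t{v.focus}\t{v.message}"
            for v in self.violations
        ]
        return "\n".join([f"conforms: false ({len(rows)} violations)", header, *rows]) + "\n"


def _integer_value(lit) -> int | None:
    if not isinstance(lit, Literal):
        return None
    if lit.datatype not in (XSD.integer, XSD.int, XSD.long, None):
        return None
    try:
        return int(lit)
    except (ValueError, TypeError):
        return None


def _check_graph(g: Graph, gname: str, out: list[Violation]) -> None:
    def v(rule: str, focus, message: str) -> None:
        out.append(Violation(rule, gname, str(focus), message))

    # R1: protein-part chain
    for part in set(g.objects(None, vocab.HAS_PROTEIN_PART)):
        if (part, vocab.HAS_PROTEIN, None) not in g:
            v("R1", part, "protein part lacks gco:has_protein")
    for part in set(g.subjects(vocab.HAS_PROTEIN, None)):
        if (None, vocab.HAS_PROTEIN_PART, part) not in g:
            v("R1", part, "protein part not referenced by any gco:has_protein_part")

    # R2: UniProt cross-reference chain
    for protein in set(g.objects(None, vocab.HAS_PROTEIN)):
        xrefs = list(g.objects(protein, RDFS.seeAlso))
        if not xrefs:
            v("R2", protein, "protein lacks rdfs:seeAlso cross-reference")
            continue
        if not any((x, DCTERMS.identifier, None) in g for x in xrefs):
            v("R2", protein, "cross-reference lacks dcterms:identifier")

    # R3: glycosylation-site chain
    for region in set(g.objects(None, vocab.GLYCOSYLATED_AT)):
        locations = list(g.objects(region, vocab.FALDO.location))
        if not locations:
            v("R3", region, "region lacks faldo:location")
            continue
        for loc in locations:
            positions = list(g.objects(loc, vocab.FALDO.position))
            if not positions:
                v("R3", loc, "location lacks faldo:position")
                continue
            for pos in positions:
                value = _integer_value(pos)
                if value is None or value < 1:
                    v(
                        "R3",
                        loc,
                        f"faldo:position {pos!r} is not an integer >= 1 "
                        "(positions are 1-based)",
                    )
    for region in set(g.subjects(vocab.FALDO.location, None)):
        if (None, vocab.GLYCOSYLATED_AT, region) not in g:
            v("R3", region, "region not referenced by any gco:glycosylated_at")

    # R4: saccharide chain
    for part in set(g.objects(None, vocab.HAS_SACCHARIDE_PART)):
        saccharides = list(g.objects(part, vocab.HAS_GLYCAN))
        if not saccharides:
            v("R4", part, "saccharide part lacks glycan:has_glycan")
            continue
        for sacc in saccharides:
            xrefs = list(g.objects(sacc, FOAF.primaryTopicOf))
            if not xrefs:
                v("R4", sacc, "saccharide lacks foaf:primaryTopicOf")
                continue
            idents = [i for x in xrefs for i in g.objects(x, DCTERMS.identifier)]
            if not idents:
                v("R4", sacc, "glycan cross-reference lacks dcterms:identifier")
            elif not any(GLYTOUCAN_RE.match(str(i)) for i in idents):
                v(
                    "R4",
                    sacc,
                    f"identifier(s) {[str(i) for i in idents]} do not match the "
                    "GlyTouCan accession pattern",
                )
    for part in set(g.subjects(vocab.HAS_GLYCAN, None)):
        if (None, vocab.HAS_SACCHARIDE_PART, part) not in g:
            v("R4", part, "saccharide part not referenced by any gco:has_saccharide_part")

    # R5: disease associations
    for assoc in set(g.subjects(vocab.REFERS_TO_DISEASE, None)):
        if (None, vocab.HAS_ASSOCIATION, assoc) not in g:
            v("R5", assoc, "association not referenced by any glycan:has_association")
    for assoc in set(g.objects(None, vocab.HAS_ASSOCIATION)):
        diseases = list(g.objects(assoc, vocab.REFERS_TO_DISEASE))
        if not diseases:
            v("R5", assoc, "association lacks sio:SIO_000628 disease")
            continue
        for disease in diseases:
            if (disease, RDFS.label, None) not in g:
                v("R5", disease, "disease lacks rdfs:label")
            if (disease, vocab.SKOS2008.notation, None) not in g:
                v("R5", disease, "disease lacks skos:notation")

    # R6: citations
    for citation in set(g.objects(None, vocab.PUBLISHED_IN)):
        if (citation, vocab.HAS_PMID, None) not in g:
            v("R6", citation, "citation lacks glycan:has_pmid")
        if (citation, DCTERMS.references, None) not in g:
            v("R6", citation, "citation lacks dcterms:references")
    for citation in set(g.subjects(vocab.HAS_PMID, None)):
        if (None, vocab.PUBLISHED_IN, citation) not in g:
            v("R6", citation, "citation not referenced by any glycan:published_in")

    # R7: conjugates need at least one part
    for conj in set(g.subjects(RDF.type, vocab.REFERENCED_GLYCOCONJUGATE)):
        if (conj, vocab.HAS_PROTEIN_PART, None) not in g and (
            conj,
            vocab.HAS_LIPID_PART,
            None,
        ) not in g:
            v("R7", conj, "conjugate has neither protein part nor lipid part")


def validate(dataset: NamedGraphDataset) -> ValidationReport:
    """Check every graph (named graphs and the default graph) against R1–R7.

    Problems are reported, never raised; the report is independent of graph
    iteration order (violations are fully sorted).
    """
    out: list[Violation] = []
    for name in dataset.graph_names():
        _check_graph(dataset.graph(name), str(name), out)
    if len(dataset.default_graph) > 0:
        _check_graph(dataset.default_graph, "default", out)
    return ValidationReport(violations=sorted(set(out)))
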