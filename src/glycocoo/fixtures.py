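"""Reference and synthetic GlycoCoO datasets.

:func:`fixture_haptoglobin` rebuilds, from its published cross-database
facts, the three-source integration example for human haptoglobin (UniProt
P00738) as annotated by GlyConnect, UniCarbKB and GlycoNAVI: the per-database
glycosylation-site lists, the four GlyTouCan accessions shared between
databases, the disease/citation/source sharing patterns.  Identifiers the
running example never states (disease notations beyond the two named
cancers, PMIDs, tissue and cell-line IRIs, per-database unshared glycan
accessions) are synthetic placeholders chosen only to preserve those sharing
patterns.

:func:`fixture_worked_example` is the single-protein example: UniProt
Q9EQH7 with an N-glycosylation site at residue 146 and one attached glycan.

:func:`synth` generates arbitrary-size conformant datasets through the model
builders together with a :class:`GroundTruth` table of exactly what was
generated — the oracle for query tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .dataset import NamedGraphDataset
from .model import (
    GlycanObservation,
    GlycoconjugateRecord,
    SourceSpec,
    build_conjugate,
    new_dataset,
)
from .queries import (
    GRAPH_GLYCONAVI,
    GRAPH_GLYCONNECT,
    GRAPH_UNICARBKB,
    DiseaseRow,
    GlycanRow,
    PublicationRow,
    SiteRow,
    SourceRow,
)

HAPTOGLOBIN = "P00738"
WORKED_EXAMPLE_PROTEIN = "Q9EQH7"
WORKED_EXAMPLE_GRAPH = "http://glycoinfo.org/glycocoo/worked-example"

#: The four GlyTouCan accessions reported by more than one database.
SHARED_GLYCANS = ("G22140GZ", "G36131WL", "G42358LZ", "G62165AG")

_HOMO_SAPIENS = "http://purl.uniprot.org/taxonomy/9606"
# Placeholder context IRIs (the example names "a tissue" / "a cell line"
# without printing identifiers): liver (Uberon) and a Cellosaurus line.
_TISSUE_PLACEHOLDER = "http://purl.obolibrary.org/obo/UBERON_0002107"
_CELL_LINE_PLACEHOLDER = "https://www.cellosaurus.org/CVCL_0027"

# Placeholder PMIDs preserving the published overlap pattern: citations
# overlap only between UniCarbKB and GlyConnect.
_PMIDS = {
    GRAPH_GLYCONNECT: (90000001, 90000002),
    GRAPH_UNICARBKB: (90000001, 90000003),
    GRAPH_GLYCONAVI: (90000004,),
}


def fixture_haptoglobin() -> NamedGraphDataset:
    """The three-database haptoglobin integration example.

    Encodes, per named graph:

    * sites — GlyConnect 184/207/211/241, GlycoNAVI 184/207/211,
      UniCarbKB 184/187/207/211/241;
    * glycans — the four shared accessions distributed so each occurs in at
      least two graphs (G62165AG in all three), plus two synthetic unshared
      accessions per graph;
    * diseases — esophageal cancer in GlyConnect + UniCarbKB, hepatocellular
      carcinoma in GlycoNAVI + GlyConnect, one extra unshared cancer each
      for GlycoNAVI and GlyConnect;
    * sources — Homo sapiens in all three graphs; a cell line only in
      GlycoNAVI; a tissue only in GlyConnect;
    * citations — PMIDs overlapping only between UniCarbKB and GlyConnect.
    """
    ds = new_dataset()

    glyconnect = GlycoconjugateRecord(
        uniprot_id=HAPTOGLOBIN,
        sites=(184, 207, 211, 241),
        glycans=(
            GlycanObservation("G22140GZ"),
            GlycanObservation("G36131WL"),
            GlycanObservation("G62165AG"),
            # synthetic unshared accessions
            GlycanObservation("G90101AA"),
            GlycanObservation("G90102AA"),
        ),
        source=SourceSpec(
            taxon_iri=_HOMO_SAPIENS,
            organism="Homo sapiens",
            tissue_iri=_TISSUE_PLACEHOLDER,
        ),
        diseases=(
            ("esophageal cancer", "DOID:5041"),
            ("hepatocellular carcinoma", "DOID:684"),
            ("lung cancer", "DOID:1324"),  # unshared extra
        ),
        pmids=_PMIDS[GRAPH_GLYCONNECT],
    )

    unicarbkb = GlycoconjugateRecord(
        uniprot_id=HAPTOGLOBIN,
        sites=(184, 187, 207, 211, 241),
        glycans=(
            GlycanObservation("G22140GZ"),
            GlycanObservation("G42358LZ"),
            GlycanObservation("G62165AG"),
            GlycanObservation("G90201AA"),
            GlycanObservation("G90202AA"),
        ),
        source=SourceSpec(taxon_iri=_HOMO_SAPIENS, organism="Homo sapiens"),
        diseases=(("esophageal cancer", "DOID:5041"),),
        pmids=_PMIDS[GRAPH_UNICARBKB],
    )

    glyconavi = GlycoconjugateRecord(
        uniprot_id=HAPTOGLOBIN,
        sites=(184, 207, 211),
        glycans=(
            # GlycoNAVI curates abundance ratios; placeholder fractions
            GlycanObservation("G36131WL", 0.25),
            GlycanObservation("G42358LZ", 0.15),
            GlycanObservation("G62165AG", 0.40),
            GlycanObservation("G90301AA", 0.10),
            GlycanObservation("G90302AA", 0.10),
        ),
        source=SourceSpec(
            taxon_iri=_HOMO_SAPIENS,
            organism="Homo sapiens",
            cell_line_iri=_CELL_LINE_PLACEHOLDER,
        ),
        diseases=(
            ("hepatocellular carcinoma", "DOID:684"),
            ("pancreatic cancer", "DOID:1793"),  # unshared extra
        ),
        pmids=_PMIDS[GRAPH_GLYCONAVI],
    )

    build_conjugate(ds, GRAPH_GLYCONNECT, glyconnect)
    build_conjugate(ds, GRAPH_UNICARBKB, unicarbkb)
    build_conjugate(ds, GRAPH_GLYCONAVI, glyconavi)
    return ds


def fixture_worked_example() -> NamedGraphDataset:
    """Single-graph dataset: Q9EQH7 with the asparagine site at residue 146.

    The glycan accession is a synthetic placeholder following the schema
    chain (the example's figure does not print one).
    """
    ds = new_dataset()
    record = GlycoconjugateRecord(
        uniprot_id=WORKED_EXAMPLE_PROTEIN,
        sites=(146,),
        glycans=(GlycanObservation("G00000AA"),),
        source=SourceSpec(
            taxon_iri="http://purl.uniprot.org/taxonomy/10090",
            organism="Mus musculus",
        ),
    )
    build_conjugate(ds, WORKED_EXAMPLE_GRAPH, record)
    return ds


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthParams:
    """Shape of a synthetic dataset.

    ``sites_per_protein`` and ``glycans_per_site`` are inclusive integer
    ranges sampled uniformly per protein/site.  Metadata flags switch the
    disease/citation/source/abundance chains on or off wholesale.
    """

    n_proteins: int = 20
    sites_per_protein: tuple[int, int] = (1, 5)
    glycans_per_site: tuple[int, int] = (0, 4)
    graph_names: tuple[str, ...] = (
        GRAPH_GLYCONNECT,
        GRAPH_UNICARBKB,
        GRAPH_GLYCONAVI,
    )
    with_diseases: bool = True
    with_citations: bool = True
    with_sources: bool = True
    with_abundances: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        for name, rng in (
            ("sites_per_protein", self.sites_per_protein),
            ("glycans_per_site", self.glycans_per_site),
        ):
            lo, hi = rng
            if lo < 0 or hi < lo:
                raise ValueError(f"{name}: invalid range {rng!r}")
        if not self.graph_names:
            raise ValueError("graph_names must be non-empty")


@dataclass
class GroundTruth:
    """Exactly the rows the five canned queries must recover."""

    sites: list[SiteRow] = field(default_factory=list)
    glycans: list[GlycanRow] = field(default_factory=list)
    diseases: list[DiseaseRow] = field(default_factory=list)
    publications: list[PublicationRow] = field(default_factory=list)
    sources: list[SourceRow] = field(default_factory=list)

    @property
    def accessions(self) -> list[str]:
        accs = {r.uniprot_id for r in self.sites} | {r.uniprot_id for r in self.sources}
        accs |= {r.uniprot_id for r in self.glycans}
        return sorted(accs)

    def for_accession(self, table: str, uniprot_id: str) -> list:
        rows = [r for r in getattr(self, table) if r.uniprot_id == uniprot_id]
        if table == "sources":
            return sorted(rows, key=SourceRow.sort_key)
        return sorted(rows)

    def sort(self) -> None:
        self.sites.sort()
        self.glycans.sort()
        self.diseases.sort()
        self.publications.sort()
        self.sources.sort(key=SourceRow.sort_key)


_DISEASE_POOL = [(f"synthetic disease {i}", f"SYN:{i:04d}") for i in range(1, 9)]
_TAXA = [
    ("http://purl.uniprot.org/taxonomy/9606", "Homo sapiens"),
    ("http://purl.uniprot.org/taxonomy/10090", "Mus musculus"),
    ("http://purl.uniprot.org/taxonomy/10116", "Rattus norvegicus"),
]


def _random_uniprot(rng: random.Random, taken: set[str]) -> str:
    while True:
        acc = "P" + "".join(rng.choices("0123456789", k=5))
        if acc not in taken:
            taken.add(acc)
            return acc


def _random_glytoucan(rng: random.Random, taken: set[str]) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    while True:
        acc = (
            "G"
            + "".join(rng.choices("0123456789", k=5))
            + "".join(rng.choices(alphabet, k=2))
        )
        if acc not in taken:
            taken.add(acc)
            return acc


def synth(params: SynthParams) -> tuple[NamedGraphDataset, GroundTruth]:
    """Generate a random conformant dataset plus its ground-truth tables.

    Every entity is emitted through the model builders; the same seed always
    yields a byte-identical serialization and identical ground truth.  Each
    protein is assigned to a random non-empty subset of the graphs so that
    cross-graph overlap is non-trivial.
    """
    rng = random.Random(params.seed)
    ds = new_dataset()
    truth = GroundTruth()
    taken_proteins: set[str] = set()
    # Taxon nodes are shared within a graph, so whether a taxon's scientific
    # name is asserted must be decided once per (graph, taxon) — not per
    # record — or one record's assertion would bind another record's
    # organism variable.
    organism_known: dict[tuple[str, str], bool] = {}

    for _ in range(params.n_proteins):
        acc = _random_uniprot(rng, taken_proteins)
        member_graphs = [g for g in params.graph_names if rng.random() < 0.7]
        if not member_graphs:
            member_graphs = [rng.choice(params.graph_names)]
        for gname in member_graphs:
            n_sites = rng.randint(*params.sites_per_protein)
            positions = tuple(sorted(rng.sample(range(1, 500), n_sites)))
            n_glycans = sum(
                rng.randint(*params.glycans_per_site) for _ in range(max(n_sites, 1))
            )
            taken_glycans: set[str] = set()
            glycans = []
            for _ in range(n_glycans):
                gt = _random_glytoucan(rng, taken_glycans)
                abundance = (
                    round(rng.uniform(0.0, 1.0), 3)
                    if params.with_abundances and rng.random() < 0.5
                    else None
                )
                glycans.append(GlycanObservation(gt, abundance))

            diseases: tuple = ()
            if params.with_diseases:
                diseases = tuple(
                    sorted(rng.sample(_DISEASE_POOL, rng.randint(0, 2)))
                )
            pmids: tuple = ()
            if params.with_citations:
                pmids = tuple(
                    sorted(
                        rng.sample(range(10_000_000, 99_999_999), rng.randint(0, 3))
                    )
                )
            source = None
            if params.with_sources:
                taxon_iri, organism = rng.choice(_TAXA)
                known = organism_known.setdefault(
                    (gname, taxon_iri), rng.random() < 0.8
                )
                source = SourceSpec(
                    taxon_iri=taxon_iri,
                    organism=organism if known else None,
                    tissue_iri=(
                        f"http://purl.obolibrary.org/obo/UBERON_{rng.randint(1, 9999):07d}"
                        if rng.random() < 0.5
                        else None
                    ),
                    cell_line_iri=(
                        f"https://www.cellosaurus.org/CVCL_{rng.randint(1, 9999):04d}"
                        if rng.random() < 0.3
                        else None
                    ),
                )

            record = GlycoconjugateRecord(
                uniprot_id=acc,
                sites=positions,
                glycans=tuple(glycans),
                source=source,
                diseases=diseases,
                pmids=pmids,
            )
            build_conjugate(ds, gname, record)

            truth.sites += [SiteRow(gname, acc, p) for p in positions]
            truth.glycans += [GlycanRow(gname, acc, g.accession) for g in glycans]
            truth.diseases += [
                DiseaseRow(gname, label, notation, acc) for label, notation in diseases
            ]
            truth.publications += [PublicationRow(gname, acc, p) for p in pmids]
            if source is not None:
                truth.sources.append(
                    SourceRow(
                        graph=gname,
                        uniprot_id=acc,
                        tissue=source.tissue_iri,
                        cell_line=source.cell_line_iri,
                        organism=source.organism,
                    )
                )

    truth.sort()
    return ds, truth
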