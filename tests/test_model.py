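"""Builder unit tests: record validation, schema emission, idempotence."""

import pytest

from glycocoo import (
    GlycanObservation,
    GlycoconjugateRecord,
    SourceSpec,
    add_glycosylation_site,
    add_saccharide,
    build_conjugate,
    new_dataset,
    run_glycans,
    run_publications,
    run_sites,
    write_dataset,
)
from glycocoo.vocab import ABUNDANCE_RATIO, EMITTED_PREDICATES

G = "http://example.org/test-graph"


def _build(record, ds=None):
    ds = ds or new_dataset()
    node = build_conjugate(ds, G, record)
    return ds, node


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"uniprot_id": "NOTANACC"}, "uniprot_id"),
        ({"uniprot_id": "p00738"}, "uniprot_id"),  # lowercase
        ({"uniprot_id": "P00738", "sites": (0,)}, "site"),
        ({"uniprot_id": "P00738", "sites": (-3,)}, "site"),
        ({"uniprot_id": "P00738", "diseases": (("", "DOID:1"),)}, "disease"),
        ({"uniprot_id": "P00738", "diseases": (("cancer", ""),)}, "disease"),
        ({"uniprot_id": "P00738", "pmids": (0,)}, "pmid"),
    ],
)
def test_record_rejects_invalid_fields(kwargs, field):
    with pytest.raises(ValueError) as exc:
        GlycoconjugateRecord(**kwargs)
    assert field.rstrip("s") in str(exc.value).lower()


@pytest.mark.parametrize("accession", ["BADID", "g22140gz", "G2214GZ", "G22140GZZ"])
def test_glycan_observation_rejects_malformed_accession(accession):
    with pytest.raises(ValueError, match="GlyTouCan"):
        GlycanObservation(accession)


@pytest.mark.parametrize("abundance", [-0.1, 1.5])
def test_glycan_observation_rejects_out_of_range_abundance(abundance):
    with pytest.raises(ValueError, match="abundance"):
        GlycanObservation("G22140GZ", abundance)


def test_empty_dataset_is_isolated():
    ds1 = new_dataset()
    assert ds1.triple_count() == 0 and ds1.graph_names() == []
    _build(GlycoconjugateRecord(uniprot_id="P00738", sites=(1,)), ds1)
    ds2 = new_dataset()
    assert ds2.triple_count() == 0, "datasets must not share state"


def test_minimal_record_has_protein_part_only():
    ds, node = _build(GlycoconjugateRecord(uniprot_id="P00738"))
    assert node.protein_part is not None
    assert run_sites(ds, "P00738") == []
    assert run_glycans(ds, "P00738") == []
    assert run_publications(ds, "P00738") == []


def test_triples_match_hand_expanded_schema_pattern():
    """2 sites + 3 glycans expand to a hand-counted 24 triples.

    Hand expansion of the schema chain: conjugate typing (1) + protein part
    chain has_protein_part/type/has_protein/seeAlso/identifier (5) + three
    triples per site (2 x glycosylated_at/location/position = 6) + four per
    glycan (3 x has_saccharide_part/has_glycan/primaryTopicOf/identifier
    = 12).
    """
    record = GlycoconjugateRecord(
        uniprot_id="P00738",
        sites=(10, 20),
        glycans=tuple(GlycanObservation(a) for a in ("G11111AA", "G22222BB", "G33333CC")),
    )
    ds, _ = _build(record)
    assert ds.triple_count() == 24
    assert len(run_sites(ds, "P00738")) == 2
    assert len(run_glycans(ds, "P00738")) == 3


def test_build_is_idempotent_and_deterministic():
    record = GlycoconjugateRecord(
        uniprot_id="Q9EQH7",
        sites=(146,),
        glycans=(GlycanObservation("G00000AA", 0.5),),
        source=SourceSpec(taxon_iri="http://purl.uniprot.org/taxonomy/9606"),
        diseases=(("x", "SYN:0001"),),
        pmids=(1234,),
    )
    ds, node1 = _build(record)
    n = ds.triple_count()
    node2 = build_conjugate(ds, G, record)
    assert ds.triple_count() == n, "rebuilding an identical record added triples"
    assert node1.iri == node2.iri

    other, _ = _build(record)
    assert write_dataset(ds, "trig") == write_dataset(other, "trig")


def test_site_at_146_retrievable():
    ds, _ = _build(GlycoconjugateRecord(uniprot_id="Q9EQH7", sites=(146,)))
    rows = run_sites(ds, "Q9EQH7")
    assert [r.position for r in rows] == [146]


def test_add_site_rejects_non_positive_position():
    ds, node = _build(GlycoconjugateRecord(uniprot_id="P00738"))
    with pytest.raises(ValueError, match="1-based"):
        add_glycosylation_site(node.protein_part, 0)


def test_repeated_site_reuses_region_node():
    ds, node = _build(GlycoconjugateRecord(uniprot_id="P00738"))
    r1 = add_glycosylation_site(node.protein_part, 184)
    n = ds.triple_count()
    r2 = add_glycosylation_site(node.protein_part, 184)
    assert r1.iri == r2.iri
    assert ds.triple_count() == n
    assert len(node.protein_part.regions) == 1


def test_abundance_ratio_round_trips():
    ds, node = _build(GlycoconjugateRecord(uniprot_id="P00738"))
    part = add_saccharide(node, "G36131WL", 0.25)
    g = ds.graph(G)
    values = list(g.objects(part.iri, ABUNDANCE_RATIO))
    assert len(values) == 1 and float(values[0]) == 0.25


def test_add_saccharide_rejects_bad_input():
    ds, node = _build(GlycoconjugateRecord(uniprot_id="P00738"))
    with pytest.raises(ValueError, match="GlyTouCan"):
        add_saccharide(node, "BADID")
    with pytest.raises(ValueError, match="abundance"):
        add_saccharide(node, "G36131WL", 1.2)


def test_every_emitted_predicate_is_in_vocabulary(hapto, small_synth):
    ds, _ = small_synth
    for dataset in (hapto, ds):
        predicates = {p for _, p, _, _ in dataset.quads()}
        assert predicates <= EMITTED_PREDICATES
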