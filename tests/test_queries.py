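"""Canned queries, SERVICE rewriting, and cross-graph overlap summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from glycocoo import (
    GlycanObservation,
    GlycoconjugateRecord,
    SiteRow,
    ServiceRewriteError,
    build_conjugate,
    new_dataset,
    overlap,
    rewrite_service,
    run_diseases,
    run_glycans,
    run_paper_query,
    run_publications,
    run_sites,
    run_sources,
)
from glycocoo.queries import (
    GRAPH_GLYCONAVI,
    GRAPH_GLYCONNECT,
    GRAPH_UNICARBKB,
    PAPER_QUERIES,
    paper_query,
)
from glycocoo import vocab

THREE_GRAPHS = {GRAPH_GLYCONNECT, GRAPH_UNICARBKB, GRAPH_GLYCONAVI}


# -- canned queries over the haptoglobin fixture ---------------------------


def test_sites_per_graph_match_database_annotations(hapto):
    rows = run_sites(hapto, "P00738")
    by_graph = {}
    for r in rows:
        by_graph.setdefault(r.graph, []).append(r.position)
    assert by_graph[GRAPH_GLYCONNECT] == [184, 207, 211, 241]
    assert by_graph[GRAPH_GLYCONAVI] == [184, 207, 211]
    assert by_graph[GRAPH_UNICARBKB] == [184, 187, 207, 211, 241]
    assert rows == sorted(rows), "rows must be ordered by (graph, position)"


def test_sites_empty_dataset_returns_no_rows():
    assert run_sites(new_dataset(), "P00738") == []


def test_malformed_accession_rejected(hapto):
    with pytest.raises(ValueError, match="UniProt"):
        run_sites(hapto, "not-an-accession")


def test_shared_glycans_bound_in_at_least_two_graphs(hapto):
    rows = run_glycans(hapto, "P00738")
    by_acc = {}
    for r in rows:
        by_acc.setdefault(r.glytoucan_id, set()).add(r.graph)
    for acc in ("G22140GZ", "G36131WL", "G42358LZ", "G62165AG"):
        assert len(by_acc[acc]) >= 2, acc


def test_conjugate_without_saccharide_part_yields_no_glycan_rows():
    ds = new_dataset()
    build_conjugate(ds, GRAPH_GLYCONNECT, GlycoconjugateRecord(uniprot_id="P00738", sites=(1,)))
    assert run_glycans(ds, "P00738") == []


def test_esophageal_cancer_in_glyconnect_and_unicarbkb_only(hapto):
    rows = run_diseases(hapto, "P00738")
    graphs = {r.graph for r in rows if r.disease_label == "esophageal cancer"}
    assert graphs == {GRAPH_GLYCONNECT, GRAPH_UNICARBKB}


def test_disease_without_notation_is_excluded(hapto):
    from glycocoo import fixture_haptoglobin

    ds = fixture_haptoglobin()
    g = ds.graph(GRAPH_UNICARBKB)
    for s, o in list(g.subject_objects(vocab.SKOS2008.notation)):
        g.remove((s, vocab.SKOS2008.notation, o))
    assert [r.graph for r in run_diseases(ds, "P00738") if r.graph == GRAPH_UNICARBKB] == []


def test_publication_overlap_only_between_unicarbkb_and_glyconnect(hapto):
    ov = overlap(run_publications(hapto, "P00738"), key=lambda r: r.pmid)
    for pmid in ov.multi_graph:
        assert ov.graphs_by_value[pmid] == frozenset({GRAPH_UNICARBKB, GRAPH_GLYCONNECT})
    assert ov.multi_graph, "fixture must exhibit the citation overlap"


def test_citation_without_references_is_excluded():
    from glycocoo import fixture_haptoglobin
    from rdflib.namespace import DCTERMS

    ds = fixture_haptoglobin()
    g = ds.graph(GRAPH_GLYCONAVI)
    for s, o in list(g.subject_objects(DCTERMS.references)):
        g.remove((s, DCTERMS.references, o))
    assert all(r.graph != GRAPH_GLYCONAVI for r in run_publications(ds, "P00738"))


def test_sources_optional_bindings_follow_database_pattern(hapto):
    rows = run_sources(hapto, "P00738")
    assert {r.graph for r in rows} == THREE_GRAPHS
    assert all(r.organism == "Homo sapiens" for r in rows)
    assert {r.graph for r in rows if r.cell_line} == {GRAPH_GLYCONAVI}
    assert {r.graph for r in rows if r.tissue} == {GRAPH_GLYCONNECT}


def test_source_with_unnamed_taxon_leaves_organism_unbound():
    from glycocoo import SourceSpec

    ds = new_dataset()
    build_conjugate(
        ds,
        GRAPH_GLYCONNECT,
        GlycoconjugateRecord(
            uniprot_id="P00738",
            sites=(5,),
            source=SourceSpec(taxon_iri="http://purl.uniprot.org/taxonomy/9606"),
        ),
    )
    rows = run_sources(ds, "P00738")
    assert len(rows) == 1 and rows[0].organism is None


# -- verbatim query texts & SERVICE rewriting ------------------------------


@pytest.mark.parametrize("name", sorted(PAPER_QUERIES))
def test_verbatim_query_equals_typed_runner(hapto, name):
    """Verbatim texts (SERVICE-rewritten) and typed operations agree."""
    typed = {
        "sites": {(r.graph, r.uniprot_id, str(r.position)) for r in run_sites(hapto, "P00738")},
        "glycans": {(r.graph, r.uniprot_id, r.glytoucan_id) for r in run_glycans(hapto, "P00738")},
        "diseases": {(r.graph, r.disease_label, r.notation, r.uniprot_id) for r in run_diseases(hapto, "P00738")},
        "publications": {(r.graph, r.uniprot_id, str(r.pmid)) for r in run_publications(hapto, "P00738")},
        "sources": {
            (r.graph, r.uniprot_id, r.tissue, r.cell_line, r.organism)
            for r in run_sources(hapto, "P00738")
        },
    }[name]
    corrected = name == "sources"  # unify the GlycoNAVI branch variables
    verbatim = {
        tuple(None if v is None else str(v) for v in row)
        for row in run_paper_query(hapto, name, corrected=corrected)
    }
    assert verbatim == typed


def test_verbatim_sources_query_is_kept_uncorrected_by_default():
    text = paper_query("sources")
    assert "?ref_conjugate gco:has_protein_part ?ref_protein." in text
    corrected = paper_query("sources", corrected=True)
    assert "?ref_conjugate" not in corrected


def test_rewrite_preserves_query_without_service():
    q = "SELECT ?s WHERE { ?s ?p ?o }"
    assert rewrite_service(q) == q


def test_rewrite_unmapped_service_names_the_endpoint():
    q = "SELECT * WHERE { SERVICE <http://x.example/sparql> { ?s ?p ?o } }"
    with pytest.raises(ServiceRewriteError, match="http://x.example/sparql"):
        rewrite_service(q, {})
    assert "SERVICE" in rewrite_service(q, {}, allow_remote=True)


def test_rewritten_federation_equals_merged_evaluation(hapto):
    """Local SERVICE rewriting equals evaluating one merged dataset.

    The three named graphs are built as separate datasets (as if held by
    three endpoints), merged, and queried; results match the rewritten
    verbatim query over the single fixture dataset.
    """
    merged = new_dataset()
    for name in hapto.graph_names():
        part = new_dataset()
        for s, p, o in hapto.graph(name):
            part.graph(name).add((s, p, o))
        merged.add_quads(part.quads())
    for qname in sorted(PAPER_QUERIES):
        a = {tuple(str(v) for v in row) for row in run_paper_query(hapto, qname)}
        b = {tuple(str(v) for v in row) for row in run_paper_query(merged, qname)}
        assert a == b, qname


# -- overlap partitions ----------------------------------------------------


def test_site_overlap_partitions_match_database_reports(hapto):
    ov = overlap(run_sites(hapto, "P00738"), key=lambda r: r.position)
    assert ov.common_to_all == {184, 207, 211}
    assert ov.unique_to_one == {187}
    assert ov.shared_by_some == {241}


def test_single_graph_rows_are_all_unique_to_one():
    rows = [SiteRow("http://example.org/g", "P00738", p) for p in (1, 2, 3)]
    ov = overlap(rows, key=lambda r: r.position)
    assert ov.unique_to_one == {1, 2, 3}
    assert not ov.common_to_all and not ov.shared_by_some


def test_empty_rows_give_empty_summary():
    ov = overlap([], key=lambda r: r.position)
    assert not ov.graphs_by_value and not ov.universe


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    pairs=st.lists(
        st.tuples(st.integers(0, 10), st.sampled_from(["g1", "g2", "g3", "g4"])),
        max_size=40,
    )
)
def test_overlap_matches_brute_force_regrouping(pairs):
    rows = [SiteRow(graph=g, uniprot_id="P00738", position=v) for v, g in pairs]
    ov = overlap(rows, key=lambda r: r.position)
    # independent brute-force regrouping over all (value, graph) pairs
    universe = {g for _, g in pairs}
    by_value: dict = {}
    for v, g in pairs:
        by_value.setdefault(v, set()).add(g)
    expect_unique = {v for v, gs in by_value.items() if len(gs) == 1}
    expect_common = {v for v, gs in by_value.items() if len(gs) > 1 and gs == universe}
    expect_shared = set(by_value) - expect_unique - expect_common
    assert ov.unique_to_one == expect_unique
    assert ov.common_to_all == expect_common
    assert ov.shared_by_some == expect_shared
    # partitions are disjoint and exhaustive
    assert ov.unique_to_one | ov.common_to_all | ov.shared_by_some == set(by_value)
    assert not (ov.unique_to_one & ov.common_to_all)
    assert not (ov.unique_to_one & ov.shared_by_some)
    assert not (ov.common_to_all & ov.shared_by_some)
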