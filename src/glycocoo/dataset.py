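"""Named-graph dataset container.

A :class:`NamedGraphDataset` is a thin wrapper over :class:`rdflib.Dataset`
exposing the small surface the toolkit needs: one triple set per graph name
plus a default graph, set semantics (no duplicate triples), order-independent
equality, and SPARQL evaluation with the GlycoCoO prefix table pre-bound.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from rdflib import Dataset, Graph, URIRef
from rdflib.namespace import NamespaceManager
from rdflib.query import Result

from .vocab import VOCABULARY

#: rdflib's identifier for the default graph of a Dataset.
_DEFAULT_ID = URIRef("urn:x-rdflib:default")

Triple = tuple


class NamedGraphDataset:
    """A mapping from graph-name IRI to a set of triples, plus a default graph."""

    def __init__(self) -> None:
        # bind_namespaces="none": only the GlycoCoO vocabulary prefixes are
        # bound, so prefixed-name serialization is canonical (e.g. skos is
        # the 2008 draft namespace the published queries declare, not the
        # 2004 one rdflib would pre-bind).
        self._ds = Dataset(default_union=False)
        self._ds.namespace_manager = NamespaceManager(self._ds, bind_namespaces="none")
        for prefix, ns in VOCABULARY.items():
            self._ds.bind(prefix, ns, override=True, replace=True)

    # -- graph access -----------------------------------------------------

    def graph(self, name: str | URIRef) -> Graph:
        """Return (creating if needed) the named graph ``name``."""
        return self._ds.graph(URIRef(str(name)))

    @property
    def default_graph(self) -> Graph:
        return self._ds.default_graph

    def graph_names(self) -> list[URIRef]:
        """Sorted names of all non-empty named graphs."""
        names = [
            g.identifier
            for g in self._ds.graphs()
            if g.identifier != _DEFAULT_ID and len(g) > 0
        ]
        return sorted(names, key=str)

    def graphs(self) -> Iterator[Graph]:
        """Non-empty named graphs, in name order."""
        for name in self.graph_names():
            yield self._ds.graph(name)

    # -- content ----------------------------------------------------------

    def quads(self) -> Iterator[tuple]:
        """All (s, p, o, graph-name) quads; default-graph triples carry None."""
        for s, p, o, ctx in self._ds.quads((None, None, None, None)):
            name = None if ctx == _DEFAULT_ID else ctx
            yield s, p, o, name

    def triple_count(self) -> int:
        return sum(1 for _ in self.quads())

    def as_dict(self) -> dict[URIRef | None, frozenset]:
        """Graph-name → triple set; the default graph is keyed by None."""
        out: dict[URIRef | None, set] = {}
        for s, p, o, name in self.quads():
            out.setdefault(name, set()).add((s, p, o))
        return {k: frozenset(v) for k, v in out.items()}

    def __len__(self) -> int:
        return self.triple_count()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NamedGraphDataset):
            return NotImplemented
        return self.as_dict() == other.as_dict()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<NamedGraphDataset graphs={len(self.graph_names())} "
            f"triples={self.triple_count()}>"
        )

    # -- query ------------------------------------------------------------

    def query(self, query_text: str, init_ns: dict | None = None) -> Result:
        """Evaluate a SPARQL SELECT query with the vocabulary prefixes bound.

        Prefixes supplied via ``init_ns`` (and the built-in vocabulary table)
        only fill in prefixes the query itself does not declare.
        """
        ns = dict(VOCABULARY)
        if init_ns:
            ns.update(init_ns)
        return self._ds.query(query_text, initNs=ns)

    # -- bulk -------------------------------------------------------------

    def add_quads(self, quads: Iterable[tuple]) -> None:
        for s, p, o, name in quads:
            if name is None:
                self.default_graph.add((s, p, o))
            else:
                self.graph(name).add((s, p, o))

    def union_into_default(self) -> "NamedGraphDataset":
        """A new dataset with every named-graph triple merged into the default graph."""
        merged = NamedGraphDataset()
        for s, p, o, _name in self.quads():
            merged.default_graph.add((s, p, o))
        return merged
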