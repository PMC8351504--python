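"""Parsing and canonical serialization of named-graph datasets.

Parsing is delegated to rdflib (Turtle, TriG, N-Quads).  Writing is done by
a canonical serializer of our own: graphs sorted by name, triples sorted
lexicographically by (subject, predicate, object), one triple per line, and a
fixed prefix block drawn from the GlycoCoO vocabulary.  Two writes of equal
datasets are byte-identical, so fixtures diff cleanly across runs and
serialization order can never influence a query result.
"""

from __future__ import annotations

import os
from typing import Optional

from rdflib import Graph, URIRef
from rdflib.namespace import NamespaceManager

from .dataset import NamedGraphDataset
from .vocab import VOCABULARY

FORMATS = ("turtle", "trig", "nquads")

_SUFFIX_TO_FORMAT = {".ttl": "turtle", ".trig": "trig", ".nq": "nquads"}


class FormatError(ValueError):
    """Unknown serialization format or a format/dataset-shape mismatch."""


class ParseError(ValueError):
    """Input document is not syntactically valid in the stated format."""


def guess_format(path: str) -> str:
    """Infer the serialization format from a file suffix (.ttl/.trig/.nq)."""
    suffix = os.path.splitext(str(path))[1].lower()
    try:
        return _SUFFIX_TO_FORMAT[suffix]
    except KeyError:
        raise FormatError(
            f"cannot infer RDF format from {path!r}; expected one of "
            f"{sorted(_SUFFIX_TO_FORMAT)}"
        ) from None


def _check_format(format: str) -> None:
    if format not in FORMATS:
        raise FormatError(f"unknown format {format!r}; expected one of {FORMATS}")


def parse_dataset(
    source: str,
    format: str,
    graph: Optional[str] = None,
) -> NamedGraphDataset:
    """Parse a document (file path or literal text) into a dataset.

    Turtle carries no graph names: its triples land in the named graph
    ``graph`` when given, otherwise in the default graph.  TriG and N-Quads
    populate named graphs as written.
    """
    _check_format(format)
    dataset = NamedGraphDataset()
    is_path = ("\n" not in source) and os.path.exists(source)
    text = open(source, encoding="utf-8").read() if is_path else source
    try:
        if format == "turtle":
            target = dataset.graph(graph) if graph else dataset.default_graph
            target.parse(data=text, format="turtle")
        else:
            dataset._ds.parse(data=text, format=format)
    except Exception as exc:  # rdflib raises format-specific exception types
        raise ParseError(f"invalid {format} document: {exc}") from exc
    return dataset


def _sorted_lines(graph: Graph, nm: NamespaceManager) -> list[str]:
    rows = sorted((s.n3(nm), p.n3(nm), o.n3(nm)) for s, p, o in graph)
    return [f"    {s} {p} {o} ." for s, p, o in rows]


def _prefix_block(keyword: str) -> list[str]:
    if keyword == "@prefix":
        return [f"@prefix {p}: <{ns}> ." for p, ns in sorted(VOCABULARY.items())]
    return [f"PREFIX {p}: <{ns}>" for p, ns in sorted(VOCABULARY.items())]


def write_dataset(
    dataset: NamedGraphDataset,
    format: str,
    destination: Optional[str] = None,
    graph: Optional[str] = None,
) -> str:
    """Serialize ``dataset`` canonically; returns the document text.

    ``graph`` selects a single named graph (required for Turtle when the
    dataset holds more than one graph).  If ``destination`` is given the text
    is also written there.
    """
    _check_format(format)
    nm = dataset._ds.namespace_manager
    lines: list[str] = []

    if format == "nquads":
        quads = sorted(
            (s.n3(), p.n3(), o.n3(), None if name is None else name.n3())
            for s, p, o, name in dataset.quads()
            if graph is None or (name is not None and str(name) == str(graph))
        )
        lines = [
            f"{s} {p} {o} ." if g is None else f"{s} {p} {o} {g} ."
            for s, p, o, g in quads
        ]
    elif format == "trig":
        lines = _prefix_block("@prefix") + [""]
        names = dataset.graph_names()
        if graph is not None:
            names = [n for n in names if str(n) == str(graph)]
        default_lines = [] if graph else _sorted_lines(dataset.default_graph, nm)
        if default_lines:
            lines += ["{"] + default_lines + ["}", ""]
        for name in names:
            lines += [f"<{name}> {{"]
            lines += _sorted_lines(dataset.graph(name), nm)
            lines += ["}", ""]
    else:  # turtle
        names = dataset.graph_names()
        if graph is not None:
            target = dataset.graph(graph)
        elif len(names) == 1 and len(dataset.default_graph) == 0:
            target = dataset.graph(names[0])
        elif not names:
            target = dataset.default_graph
        else:
            raise FormatError(
                "turtle cannot carry a multi-graph dataset; pass graph=<name> "
                "to select one, or serialize as trig/nquads"
            )
        lines = _prefix_block("@prefix") + [""]
        lines += [line.lstrip() for line in _sorted_lines(target, nm)]

    text = "\n".join(lines).rstrip("\n") + "\n"
    if destination is not None:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
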