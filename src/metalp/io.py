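"""Readers and writers: edge lists, GML, Pajek NET, membership tables."""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import IO, Iterable, Union

from .graph import Graph, Partition

__all__ = [
    "GraphParseError",
    "load_graph",
    "write_edgelist",
    "load_partition",
    "write_partition",
    "write_similarity",
]

Source = Union[str, Path, IO]

_FORMATS = ("edgelist", "gml", "pajek")


class GraphParseError(ValueError):
    """Malformed graph input; carries the offending line number when known."""


def _open_text(source: Source, mode: str = "r"):
    """Return (stream, should_close)."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def load_graph(source: Source, format: str = "edgelist", weighted: bool = False) -> Graph:
    """Load an undirected graph from a path or text stream.

    Supported formats: plain edge list (``u v [w]``, whitespace or comma
    separated, ``#`` comments), GML, and Pajek NET. Duplicate rows for the
    same pair are summed into one weight; self-referential rows are
    rejected; isolated nodes declared in GML/Pajek headers are retained.
    When ``weighted`` is false every edge gets weight 1.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "edgelist":
        return _load_edgelist(source, weighted)
    import networkx as nx

    stream, close = _open_text(source)
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    buf = _io.BytesIO(text.encode("utf-8"))
    if format == "gml":
        nxg = nx.read_gml(buf, label="label")
    else:
        nxg = nx.read_pajek(buf)
    nxg = nx.Graph(nxg) if nxg.is_multigraph() or nxg.is_directed() else nxg
    for u, v, data in nxg.edges(data=True):
        if u == v:
            raise GraphParseError(f"self-referential edge at node {u!r}")
        w = data.get("weight", 1.0)
        if weighted and not float(w) > 0:
            raise GraphParseError(f"nonpositive weight {w!r} on edge {u!r}-{v!r}")
    return Graph.from_networkx(nxg, weighted=weighted)


_SPLIT = re.compile(r"[,\s]+")


def _load_edgelist(source: Source, weighted: bool) -> Graph:
    g = Graph()
    stream, close = _open_text(source)
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = _SPLIT.split(line)
            if len(parts) not in (2, 3):
                raise GraphParseError(
                    f"line {lineno}: expected 'u v [w]', got {raw.rstrip()!r}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                raise GraphParseError(f"line {lineno}: self-referential edge {u!r}")
            w = 1.0
            if weighted and len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise GraphParseError(
                        f"line {lineno}: bad weight {parts[2]!r}"
                    ) from None
                if not w > 0:
                    raise GraphParseError(f"line {lineno}: nonpositive weight {w}")
            g.add_edge(u, v, w)
    finally:
        if close:
            stream.close()
    if g.n == 0:
        raise GraphParseError("no edges found in input")
    return g


def write_edgelist(graph: Graph, sink: Source, weighted: bool = True) -> None:
    stream, close = _open_text(sink, "w")
    try:
        for u, v, w in sorted(graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            if weighted:
                stream.write(f"{u}\t{v}\t{w:g}\n")
            else:
                stream.write(f"{u}\t{v}\n")
    finally:
        if close:
            stream.close()


def load_partition(source: Source) -> Partition:
    """Load a two-column node<TAB>label membership table."""
    membership = {}
    stream, close = _open_text(source)
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = _SPLIT.split(line)
            if len(parts) != 2:
                raise GraphParseError(
                    f"line {lineno}: expected 'node<TAB>label', got {raw.rstrip()!r}"
                )
            node, label = parts
            if node in membership:
                raise GraphParseError(f"line {lineno}: duplicate node {node!r}")
            membership[node] = label
    finally:
        if close:
            stream.close()
    if not membership:
        raise GraphParseError("empty membership table")
    return Partition(membership)


def write_partition(partition: Partition, sink: Source) -> None:
    """Write a membership table, one ``node<TAB>label`` row per node,
    in stable (lexicographic) node order."""
    stream, close = _open_text(sink, "w")
    try:
        for u in sorted(partition, key=str):
            stream.write(f"{u}\t{partition[u]}\n")
    finally:
        if close:
            stream.close()


def write_similarity(sims, sink: Source) -> None:
    """Dump per-edge structural similarities as a u, v, s(u,v) TSV."""
    stream, close = _open_text(sink, "w")
    try:
        for (u, v), s in sorted(sims.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            stream.write(f"{u}\t{v}\t{s:.10g}\n")
    finally:
        if close:
            stream.close()
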