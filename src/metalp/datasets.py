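"""Bundled tiny real-network fixtures (Zachary's karate club)."""

from __future__ import annotations

from importlib import resources

from . import io as _io
from .graph import Graph, Partition

__all__ = ["fixture_path", "karate_club", "karate_factions"]


def fixture_path(name: str):
    """Path to a bundled data file (e.g. ``karate.edgelist``)."""
    return resources.files("metalp.data") / name


def karate_club() -> Graph:
    """Zachary's karate club friendship network: 34 members, 78 ties.

    Node ids are the classic 1-based strings; "1" is the instructor
    (Mr. Hi) and "34" the club president (John A.).
    """
    with fixture_path("karate.edgelist").open("r") as fh:
        return _io.load_graph(fh, format="edgelist")


def karate_factions() -> Partition:
    """The historical two-faction split of the club after its dispute."""
    with fixture_path("karate_factions.tsv").open("r") as fh:
        return _io.load_partition(fh)
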