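"""Controlled-vocabulary hierarchies (CL, UBERON, DOID) and term expansion.

Terms form a DAG under ``is_a``; hierarchical cell selection expands a
query term to its reflexive-transitive descendants (e.g. "enterocyte
CL:0000584 and its children") or ancestors.  Parsing goes through
``obonet``; only ``is_a`` edges define the hierarchy by default, with
``part_of`` as an opt-in.  Miniature CL/UBERON/DOID subsets sufficient for
testing are packaged under :mod:`sccommons.data`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import networkx as nx
import obonet

from .core_model import FormatError, NotFoundError

__all__ = ["Ontology", "load_obo", "load_packaged", "descendants", "ancestors"]

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*:\d+$")


@dataclass
class Ontology:
    """A DAG of CURIE-identified terms with ``is_a`` parentage."""
    terms: set = field(default_factory=set)
    names: dict = field(default_factory=dict)          # term -> label
    is_a: dict = field(default_factory=dict)           # term -> set of parents
    _graph: nx.DiGraph = field(default=None, repr=False, compare=False)

    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph (cached)."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.terms)
            for child, parents in self.is_a.items():
                for p in parents:
                    g.add_edge(child, p)
            self._graph = g
        return self._graph

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def load_obo(path: Union[str, Path], include_part_of: bool = False) -> Ontology:
    """Load an OBO 1.2-style file.

    One term per ``[Term]`` stanza; obsolete terms are excluded; only
    ``is_a`` relations are kept unless ``include_part_of`` is set.  Term ids
    that are not ``PREFIX:digits`` CURIEs (header artefacts, typedefs) are
    dropped.  A cyclic ``is_a`` graph is a format error naming one cycle.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as e:  # obonet raises ValueError on malformed stanzas
        raise FormatError(f"cannot parse OBO file {path}: {e}") from e

    terms = {t for t in graph.nodes if _CURIE_RE.match(str(t))}
    names = {t: graph.nodes[t].get("name", "") for t in terms}
    is_a: dict[str, set] = {t: set() for t in terms}
    for child, parent, rel in graph.edges(keys=True):
        if rel != "is_a" and not (include_part_of and rel == "part_of"):
            continue
        if child in terms and parent in terms:
            is_a[child].add(parent)

    onto = Ontology(terms=terms, names=names, is_a=is_a)
    g = onto.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise FormatError(f"is_a cycle detected: {pretty}")
    return onto


def load_packaged(name: str, include_part_of: bool = False) -> Ontology:
    """Load one of the packaged miniature vocabularies: ``cl``, ``uberon``
    or ``doid``."""
    ref = resources.files("sccommons.data") / f"{name}_mini.obo"
    with resources.as_file(ref) as p:
        return load_obo(p, include_part_of=include_part_of)


def _require(onto: Ontology, term: str) -> None:
    if term not in onto.terms:
        raise NotFoundError(f"term {term!r} not in ontology")


def descendants(onto: Ontology, term: str) -> set:
    """Reflexive-transitive closure of the inverse ``is_a`` relation:
    the term and everything below it."""
    _require(onto, term)
    return nx.ancestors(onto.graph(), term) | {term}


def ancestors(onto: Ontology, term: str) -> set:
    """Reflexive-transitive closure of ``is_a``: the term and everything
    above it."""
    _require(onto, term)
    return nx.descendants(onto.graph(), term) | {term}
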