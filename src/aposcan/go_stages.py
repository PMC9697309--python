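"""GO ancestor propagation, reproduction subset, reproductive-stage counts.

Transcriptome annotation tables carry only low-level GO terms; to ask
whether a locus is linked to reproduction at all, each term is propagated
upwards through the ontology (``is_a`` edges only) and intersected with a
fixed set of reproduction-linked subtrees rooted at:

* GO:0048229 gametophyte development
* GO:0000003 reproduction
* GO:0022414 reproductive process
* GO:1903046 meiotic cell cycle process
* GO:0048236 plant-type sporogenesis
* GO:0000741 karyogamy

Matched terms are then sorted into five reproductive-stage categories
(flower/ovule formation, meiosis, embryo sac development and
gametogenesis, embryo and seed formation, and male functions pooled over
stages).  The term-to-stage assignment is data, not code: a packaged TSV
(``data/stage_map.tsv``) that users can replace.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

REPRODUCTION_ROOTS = frozenset(
    {
        "GO:0048229",
        "GO:0000003",
        "GO:0022414",
        "GO:1903046",
        "GO:0048236",
        "GO:0000741",
    }
)

STAGES = (
    "flower_ovule_formation",
    "meiosis",
    "embryo_sac_gametogenesis",
    "embryo_seed_formation",
    "male_functions",
)
UNASSIGNED = "unassigned"


class GoDag:
    """is_a view of a Gene Ontology graph loaded from an OBO file.

    Obsolete terms are excluded (with a warning when referenced); ``alt_id``
    aliases resolve to their primary term.
    """

    def __init__(self, graph: nx.MultiDiGraph):
        self._graph = graph
        self._alt: dict[str, str] = {}
        for term, data in graph.nodes(data=True):
            for alt in data.get("alt_id", []):
                self._alt[alt] = term
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")

    @classmethod
    def read_obo(cls, path: str | Path) -> "GoDag":
        graph = obonet.read_obo(str(path))  # drops obsolete terms
        return cls(graph)

    def __contains__(self, term: str) -> bool:
        return term in self._graph or term in self._alt

    def resolve(self, term: str) -> str:
        if term in self._graph:
            return term
        if term in self._alt:
            return self._alt[term]
        raise KeyError(f"unknown GO id {term!r} (possibly obsolete)")

    def name(self, term: str) -> str:
        return self._graph.nodes[self.resolve(term)].get("name", "")

    def namespace(self, term: str) -> str:
        return self._graph.nodes[self.resolve(term)].get("namespace", "")

    def parents(self, term: str) -> set[str]:
        """Direct is_a parents."""
        term = self.resolve(term)
        return {
            parent
            for _, parent, key in self._graph.out_edges(term, keys=True)
            if key == "is_a"
        }

    def ancestors(self, term: str) -> set[str]:
        """Transitive is_a closure, including the term itself."""
        term = self.resolve(term)
        closure = {term}
        frontier = [term]
        while frontier:
            current = frontier.pop()
            for parent in self.parents(current):
                if parent not in closure:
                    closure.add(parent)
                    frontier.append(parent)
        return closure

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)


def reproduction_members(dag: GoDag, roots: frozenset[str] = REPRODUCTION_ROOTS) -> set[str]:
    """Roots plus all their is_a descendants present in the DAG."""
    present = {r for r in roots if r in dag}
    missing = roots - present
    if missing:
        logger.warning("reproduction roots absent from ontology: %s", sorted(missing))
    return {
        term for term in dag.terms if dag.ancestors(term) & present
    }


def reproduction_subset(
    locus_terms: Iterable[str],
    dag: GoDag,
    members: set[str] | None = None,
) -> tuple[bool, set[str]]:
    """Flag a locus as reproduction-linked and return its matched terms.

    A term matches when it, or any of its is_a ancestors, is one of the
    reproduction roots -- i.e. when it lies in a reproduction subtree.
    Unknown/obsolete ids are skipped with a warning.
    """
    if members is None:
        members = reproduction_members(dag)
    matched: set[str] = set()
    for term in locus_terms:
        try:
            resolved = dag.resolve(term)
        except KeyError:
            logger.warning("skipping unknown or obsolete GO id %s", term)
            continue
        if resolved in members:
            matched.add(resolved)
    return bool(matched), matched


def load_stage_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the GO-term -> reproductive-stage table (packaged default)."""
    if path is None:
        source = resources.files("aposcan").joinpath("data/stage_map.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        stage = row["stage"]
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r} for term {row['go_id']}")
        mapping[row["go_id"]] = stage
    return mapping


def stage_classify(
    matched_terms: Iterable[str],
    stage_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, int], list[str]]:
    """Count matched terms per reproductive stage.

    Each term counts once under its assigned stage; terms without a stage
    assignment are returned separately (and tallied under ``unassigned``).
    """
    if stage_map is None:
        stage_map = load_stage_map()
    counts = {stage: 0 for stage in STAGES}
    counts[UNASSIGNED] = 0
    unassigned: list[str] = []
    for term in sorted(set(matched_terms)):
        stage = stage_map.get(term)
        if stage is None:
            logger.warning("GO id %s has no stage assignment", term)
            unassigned.append(term)
            counts[UNASSIGNED] += 1
        else:
            counts[stage] += 1
    return counts, unassigned
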