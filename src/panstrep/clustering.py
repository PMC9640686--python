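"""Orthologous-group construction from qualifying similarity hits.

Orthologous groups are the connected components of an undirected graph
whose nodes are all proteins in the analysis and whose edges join
protein pairs for which at least one direction's hit passes the
orthologue criteria.  This is single-linkage clustering: one
qualifying pair suffices to merge two groups, and long chains can in
principle connect proteins with no direct similarity.  No community
detection is applied on top, by design.

Conservation labels follow the prevalence of a group across genomes:
``strict_core`` (all genomes), ``core`` (>= 95% of genomes), ``rare``
(< 5%), ``strain_specific`` (exactly one genome), ``singleton`` (a
single protein with no orthologues) and ``intermediate`` otherwise.
The core/rare fractions are applied to the real-valued prevalence
fraction with no rounding, so at 205 genomes "rare" means 10 genomes
or fewer and "core" means 195 or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .similarity import OrthologueCriteria, SimilarityHit, hit_passes

#: Conservation labels; a group may carry several (e.g. a singleton in a
#: 205-genome pangenome is also rare and strain-specific).
STRICT_CORE = "strict_core"
CORE = "core"
RARE = "rare"
STRAIN_SPECIFIC = "strain_specific"
SINGLETON = "singleton"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class OrthologousGroup:
    """A connected component of the qualifying-hit graph."""

    group_id: str
    members: frozenset[str]
    genomes: frozenset[str]
    copy_number: Mapping[str, int]

    @property
    def prevalence(self) -> int:
        """Number of distinct genomes holding at least one member."""
        return len(self.genomes)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Pangenome:
    """The full partition of a protein universe into orthologous groups."""

    groups: list[OrthologousGroup]
    n_genomes: int
    genome_ids: tuple[str, ...]
    protein_to_group: dict[str, str] = field(repr=False)
    protein_to_genome: dict[str, str] = field(repr=False)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_to_group)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group(self, group_id: str) -> OrthologousGroup:
        return self._by_id[group_id]

    def __post_init__(self) -> None:
        self._by_id = {g.group_id: g for g in self.groups}

    def prevalence_fraction(self, group_id: str) -> float:
        return self._by_id[group_id].prevalence / self.n_genomes


def build_graph(
    hits: Iterable[SimilarityHit],
    universe: Iterable[str],
    criteria: OrthologueCriteria = OrthologueCriteria(),
) -> nx.Graph:
    """Build the undirected orthologue-evidence graph.

    Nodes are the whole protein universe (proteins with no qualifying
    hit become isolated nodes).  An edge is added when *either*
    direction of a pair passes the criteria; reciprocity is not
    required.  Self-loops are never added.
    """
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for hit in hits:
        if hit.query_id not in graph or hit.subject_id not in graph:
            unknown = hit.query_id if hit.query_id not in graph else hit.subject_id
            raise ValueError(f"hit references protein {unknown!r} not in universe")
        if hit.query_id == hit.subject_id:
            continue
        if hit_passes(hit, criteria):
            graph.add_edge(hit.query_id, hit.subject_id)
    return graph


def extract_groups(graph: nx.Graph, genome_map: Mapping[str, str]) -> Pangenome:
    """Extract orthologous groups as connected components.

    Group ids are assigned deterministically: components are sorted by
    their lexicographically smallest member and numbered ``OG000001``
    onwards.  Every node must have a genome assignment.
    """
    for node in graph.nodes:
        if node not in genome_map:
            raise ValueError(f"protein {node!r} has no genome assignment")
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    groups: list[OrthologousGroup] = []
    protein_to_group: dict[str, str] = {}
    for i, members in enumerate(components, start=1):
        gid = f"OG{i:06d}"
        copy_number: dict[str, int] = {}
        for pid in members:
            copy_number[genome_map[pid]] = copy_number.get(genome_map[pid], 0) + 1
            protein_to_group[pid] = gid
        groups.append(
            OrthologousGroup(
                group_id=gid,
                members=frozenset(members),
                genomes=frozenset(copy_number),
                copy_number=copy_number,
            )
        )
    genome_ids = tuple(sorted(set(genome_map[p] for p in graph.nodes)))
    return Pangenome(
        groups=groups,
        n_genomes=len(genome_ids),
        genome_ids=genome_ids,
        protein_to_group=protein_to_group,
        protein_to_genome={p: genome_map[p] for p in graph.nodes},
    )


def cluster_proteins(
    hits: Iterable[SimilarityHit],
    proteins: Mapping[str, str],
    criteria: OrthologueCriteria = OrthologueCriteria(),
) -> Pangenome:
    """Convenience wrapper: graph construction plus group extraction.

    ``proteins`` maps protein id -> genome id for the whole universe.
    """
    graph = build_graph(hits, proteins.keys(), criteria)
    return extract_groups(graph, proteins)


def classify_conservation(
    pangenome: Pangenome,
    core_fraction: float = 0.95,
    rare_fraction: float = 0.05,
) -> dict[str, frozenset[str]]:
    """Label every group by its conservation across genomes.

    Returns group_id -> set of labels.  Labels are not mutually
    exclusive: strict-core groups are also core; strain-specific and
    singleton groups are usually also rare.
    """
    if pangenome.n_genomes < 2:
        raise ValueError("conservation classification requires >= 2 genomes")
    labels: dict[str, frozenset[str]] = {}
    n = pangenome.n_genomes
    for group in pangenome.groups:
        frac = group.prevalence / n
        tags: set[str] = set()
        if group.prevalence == n:
            tags.add(STRICT_CORE)
        if frac >= core_fraction:
            tags.add(CORE)
        if frac < rare_fraction:
            tags.add(RARE)
        if group.prevalence == 1:
            tags.add(STRAIN_SPECIFIC)
        if group.size == 1:
            tags.add(SINGLETON)
        if not tags & {CORE, RARE}:
            tags.add(INTERMEDIATE)
        labels[group.group_id] = frozenset(tags)
    return labels


def single_copy_strict_core(pangenome: Pangenome) -> list[str]:
    """Groups present in every genome with exactly one copy per genome."""
    out = []
    for group in pangenome.groups:
        if group.prevalence == pangenome.n_genomes and all(
            c == 1 for c in group.copy_number.values()
        ):
            out.append(group.group_id)
    return out
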