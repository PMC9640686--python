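"""Shared helper for the example scripts."""

import networkx as nx

from panstrep.clustering import Pangenome, extract_groups
from panstrep.synthetic import PlantedTruth


def pangenome_from_truth(truth: PlantedTruth) -> Pangenome:
    """Build a Pangenome from planted group membership without alignment."""
    graph = nx.Graph()
    graph.add_nodes_from(truth.protein_to_group)
    members: dict[str, list[str]] = {}
    for pid, gid in truth.protein_to_group.items():
        members.setdefault(gid, []).append(pid)
    for group in members.values():
        group.sort()
        graph.add_edges_from(zip(group, group[1:]))
    return extract_groups(graph, truth.protein_to_genome)
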