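from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from panstrep import (
    OrthologousGroup,
    Pangenome,
    SyntheticPangenomeSpec,
    all_vs_all,
    cluster_proteins,
    generate_pangenome,
)
from panstrep.clustering import extract_groups
from panstrep.synthetic import PlantedTruth


def make_pangenome(
    membership: dict[str, list[tuple[str, str]]],
    n_genomes: int | None = None,
    genome_ids: tuple[str, ...] | None = None,
) -> Pangenome:
    """Build a Pangenome directly from group -> [(protein, genome)] lists.

    Lets tests fabricate pangenomes of arbitrary prevalence structure
    (including a 205-genome one) without running any alignment.
    """
    groups = []
    protein_to_group: dict[str, str] = {}
    protein_to_genome: dict[str, str] = {}
    seen_genomes: set[str] = set()
    for gid in sorted(membership):
        members = membership[gid]
        copy_number: dict[str, int] = {}
        for pid, genome in members:
            copy_number[genome] = copy_number.get(genome, 0) + 1
            protein_to_group[pid] = gid
            protein_to_genome[pid] = genome
            seen_genomes.add(genome)
        groups.append(
            OrthologousGroup(
                group_id=gid,
                members=frozenset(p for p, _ in members),
                genomes=frozenset(copy_number),
                copy_number=copy_number,
            )
        )
    if genome_ids is None:
        genome_ids = tuple(sorted(seen_genomes))
    if n_genomes is None:
        n_genomes = len(genome_ids)
    return Pangenome(
        groups=groups,
        n_genomes=n_genomes,
        genome_ids=genome_ids,
        protein_to_group=protein_to_group,
        protein_to_genome=protein_to_genome,
    )


def pangenome_from_truth(truth: PlantedTruth) -> Pangenome:
    """Turn planted truth into a Pangenome by chaining true group members."""
    graph = nx.Graph()
    graph.add_nodes_from(truth.protein_to_group)
    by_group: dict[str, list[str]] = {}
    for pid, gid in truth.protein_to_group.items():
        by_group.setdefault(gid, []).append(pid)
    for members in by_group.values():
        members.sort()
        for a, b in zip(members, members[1:]):
            graph.add_edge(a, b)
    return extract_groups(graph, truth.protein_to_genome)


@pytest.fixture(scope="session")
def planted_run():
    """Full planted-recovery run at study-condition defaults.

    20 genomes x ~200 proteins, within-group identity 0.9, unrelated
    strain-specific fillers; clustered at the default orthologue
    thresholds.  Shared session-wide because the all-vs-all alignment
    dominates suite runtime.
    """
    spec = SyntheticPangenomeSpec()
    proteomes, truth = generate_pangenome(spec)
    proteins = {r.protein_id: r.sequence for g in proteomes for r in proteomes[g]}
    genome_map = {r.protein_id: r.genome_id for g in proteomes for r in proteomes[g]}
    hits = all_vs_all(proteins)
    pangenome = cluster_proteins(hits, genome_map)
    return spec, proteomes, truth, hits, pangenome


@pytest.fixture(scope="session")
def medium_truth_pangenome():
    """A 12-genome pangenome built directly from planted truth (no alignment)."""
    spec = SyntheticPangenomeSpec(
        n_genomes=12,
        n_core_groups=30,
        accessory_prevalence_weights={(0.05, 0.5): 10, (0.5, 0.95): 10},
        n_unique_per_genome=5,
        within_group_identity=0.95,
        seed=11,
    )
    _, truth = generate_pangenome(spec)
    return truth, pangenome_from_truth(truth)
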