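"""Synthetic pangenome generator with planted ground truth.

Emulates the input of a multi-genome bacterial pangenome study: a set
of proteomes sharing orthologous groups at controlled prevalence
(core / accessory / strain-specific), with controlled within-group
sequence identity, within-genome paralogs, and matching functional
annotation tables.  Every protein's true group membership is recorded,
so downstream clustering, statistics and classifiers can be scored
against planted truth.

The model is deliberately simple: each planted group has one ancestor
sequence drawn i.i.d. uniform over the 20 standard residues; each
member genome receives a mutated copy.  Mutation is substitution-only
by default, so the identity of each copy to its ancestor is exact by
construction, which makes the identity-threshold boundary testable
deterministically.  Unrelated proteins are drawn independently; at
length >= 100 the chance that two unrelated uniform sequences reach
80% identity over 70% coverage is negligible, so planted groups are
cleanly separable.  There is no phylogeny-aware gain/loss process and
no indel/domain-shuffling structure: real proteomes are harder than
this generator in those respects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    BGC_COLUMNS,
    CAZY_COLUMNS,
    COG_COLUMNS,
    DOMAIN_COLUMNS,
    KO_COLUMNS,
    ProteinRecord,
    write_annotation_tsv,
    write_fasta,
    write_json,
    write_truth_tsv,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticPangenomeSpec:
    """Parameters of a synthetic pangenome.

    ``accessory_prevalence_weights`` maps prevalence-fraction bands
    (low, high) to the number of accessory groups whose prevalence is
    drawn uniformly within the band.  ``within_group_identity`` is the
    target mean *pairwise* identity between members of one group.
    """

    n_genomes: int = 20
    n_core_groups: int = 150
    accessory_prevalence_weights: Mapping[tuple[float, float], int] = field(
        default_factory=lambda: {(0.05, 0.50): 15, (0.50, 0.95): 15}
    )
    n_unique_per_genome: int = 10
    within_group_identity: float = 0.9
    paralog_rate: float = 0.02
    protein_length_range: tuple[int, int] = (100, 300)
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ConfigurationError("n_genomes must be >= 2")
        if self.n_core_groups < 0:
            raise ConfigurationError("n_core_groups must be >= 0")
        if not 0 < self.within_group_identity <= 1:
            raise ConfigurationError("within_group_identity must be in (0, 1]")
        if not 0 <= self.paralog_rate <= 1:
            raise ConfigurationError("paralog_rate must be in [0, 1]")
        if self.n_unique_per_genome < 0:
            raise ConfigurationError("n_unique_per_genome must be >= 0")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("protein_length_range must satisfy 1 <= min <= max")
        for band, count in self.accessory_prevalence_weights.items():
            blo, bhi = band
            if not 0 < blo <= bhi <= 1:
                raise ConfigurationError(
                    f"accessory_prevalence_weights band {band} must satisfy 0 < low <= high <= 1"
                )
            if count < 0:
                raise ConfigurationError(
                    f"accessory_prevalence_weights count for band {band} must be >= 0"
                )
        if len(set(self.alphabet)) < 2:
            raise ConfigurationError("alphabet must contain at least 2 residues")


@dataclass
class PlantedTruth:
    """Ground-truth bookkeeping for a generated pangenome."""

    protein_to_group: dict[str, str]
    protein_to_genome: dict[str, str]
    group_genomes: dict[str, frozenset[str]]

    def prevalence(self, group_id: str) -> int:
        return len(self.group_genomes[group_id])

    def partition_labels(self, protein_ids: Sequence[str]) -> list[str]:
        """Planted group labels in a given protein order (for ARI scoring)."""
        return [self.protein_to_group[p] for p in protein_ids]

    def rows(self) -> list[tuple[str, str, str]]:
        return [
            (p, self.protein_to_genome[p], g)
            for p, g in sorted(self.protein_to_group.items())
        ]


def mutate_sequence(
    parent: str, target_identity: float, rng: np.random.Generator
) -> str:
    """Substitute exactly round((1 - identity) * length) positions.

    Substitution-only, length-preserving; each substituted position
    receives a residue different from the original, so the global
    ungapped identity to the parent equals the target exactly (up to
    the rounding of the substitution count).
    """
    if not parent:
        raise ValueError("cannot mutate an empty sequence")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    n_sub = round((1 - target_identity) * len(parent))
    if n_sub == 0:
        return parent
    positions = rng.choice(len(parent), size=n_sub, replace=False)
    residues = list(parent)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != residues[pos]]
        residues[pos] = choices[rng.integers(len(choices))]
    return "".join(residues)


def _random_sequence(length: int, alphabet: str, rng: np.random.Generator) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def generate_pangenome(
    spec: SyntheticPangenomeSpec,
) -> tuple[dict[str, list[ProteinRecord]], PlantedTruth]:
    """Generate proteomes and planted truth from a spec.

    Each planted group is one ancestor sequence plus one mutated copy
    per member genome; copies are mutated at identity
    ``1 - (1 - within_group_identity) / 2`` to the ancestor, so two
    members, having accumulated (mostly disjoint) substitutions
    independently, sit at approximately the target pairwise identity.
    Paralogs are extra within-genome copies added at ``paralog_rate``
    per group member.  Identical seeds yield identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome_ids = [f"G{i + 1:03d}" for i in range(spec.n_genomes)]
    proteomes: dict[str, list[ProteinRecord]] = {g: [] for g in genome_ids}
    counters = {g: 0 for g in genome_ids}
    protein_to_group: dict[str, str] = {}
    protein_to_genome: dict[str, str] = {}
    group_genomes: dict[str, frozenset[str]] = {}
    copy_identity = 1 - (1 - spec.within_group_identity) / 2

    def add_protein(genome: str, group: str, sequence: str) -> None:
        counters[genome] += 1
        pid = f"{genome}_P{counters[genome]:05d}"
        proteomes[genome].append(
            ProteinRecord(protein_id=pid, genome_id=genome, sequence=sequence)
        )
        protein_to_group[pid] = group
        protein_to_genome[pid] = genome

    # Shared (core + accessory) groups.
    shared: list[tuple[str, list[str]]] = []
    gnum = 0
    for _ in range(spec.n_core_groups):
        gnum += 1
        shared.append((f"T{gnum:05d}", list(genome_ids)))
    for band in sorted(spec.accessory_prevalence_weights):
        lo, hi = band
        count = spec.accessory_prevalence_weights[band]
        lo_n = max(1, int(np.ceil(lo * spec.n_genomes)))
        hi_n = max(lo_n, int(np.floor(hi * spec.n_genomes)))
        for _ in range(count):
            gnum += 1
            prevalence = int(rng.integers(lo_n, hi_n + 1))
            holders = sorted(
                rng.choice(spec.n_genomes, size=prevalence, replace=False)
            )
            shared.append((f"T{gnum:05d}", [genome_ids[i] for i in holders]))

    lo_len, hi_len = spec.protein_length_range
    for group_id, holders in shared:
        length = int(rng.integers(lo_len, hi_len + 1))
        ancestor = _random_sequence(length, spec.alphabet, rng)
        for genome in holders:
            add_protein(genome, group_id, mutate_sequence(ancestor, copy_identity, rng))
            if rng.random() < spec.paralog_rate:
                add_protein(
                    genome, group_id, mutate_sequence(ancestor, copy_identity, rng)
                )
        group_genomes[group_id] = frozenset(holders)

    # Strain-specific singletons, drawn independently of every group.
    for genome in genome_ids:
        for i in range(spec.n_unique_per_genome):
            gnum += 1
            group_id = f"T{gnum:05d}"
            length = int(rng.integers(lo_len, hi_len + 1))
            add_protein(genome, group_id, _random_sequence(length, spec.alphabet, rng))
            group_genomes[group_id] = frozenset([genome])

    truth = PlantedTruth(
        protein_to_group=protein_to_group,
        protein_to_genome=protein_to_genome,
        group_genomes=group_genomes,
    )
    return proteomes, truth


def write_pangenome(
    proteomes: Mapping[str, list[ProteinRecord]],
    truth: PlantedTruth,
    spec: SyntheticPangenomeSpec,
    out_dir: str | Path,
) -> None:
    """Write one FASTA per genome, the truth TSV, and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for genome in sorted(proteomes):
        write_fasta(proteomes[genome], out / f"{genome}.fasta")
    write_truth_tsv(truth.rows(), out / "truth.tsv")
    manifest = {
        "spec": {
            "n_genomes": spec.n_genomes,
            "n_core_groups": spec.n_core_groups,
            "accessory_prevalence_weights": {
                f"{lo}-{hi}": c
                for (lo, hi), c in spec.accessory_prevalence_weights.items()
            },
            "n_unique_per_genome": spec.n_unique_per_genome,
            "within_group_identity": spec.within_group_identity,
            "paralog_rate": spec.paralog_rate,
            "protein_length_range": list(spec.protein_length_range),
            "seed": spec.seed,
        },
        "n_proteins": sum(len(v) for v in proteomes.values()),
        "n_groups": len(truth.group_genomes),
    }
    write_json(manifest, out / "manifest.json")


# --------------------------------------------------------------------------
# Synthetic annotation tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationLabel:
    """One planted label applied to every member of a group.

    ``kind`` selects the output table: ``domains``, ``cog``, ``ko``,
    ``cazy`` or ``bgc``.  E-values and scores default to comfortably
    passing values; set them explicitly to exercise filter boundaries.
    """

    kind: str
    label: str
    evalue: float = 1e-20
    score: float | None = None
    threshold: float | None = None
    name: str | None = None
    start: int = 1
    end: int = 50
    bgc_id: str | None = None
    core_enzyme: bool = False


def generate_annotations(
    truth: PlantedTruth,
    profile: Mapping[str, Sequence[AnnotationLabel]],
) -> dict[str, pd.DataFrame]:
    """Materialise per-protein annotation tables from a group -> label map.

    Every member protein of a labelled group receives one row per
    label.  Unknown group ids are an error.  An empty profile yields
    header-only tables.
    """
    for group_id in profile:
        if group_id not in truth.group_genomes:
            raise ConfigurationError(f"profile references unknown group {group_id!r}")
    members: dict[str, list[str]] = {}
    for pid, gid in truth.protein_to_group.items():
        members.setdefault(gid, []).append(pid)
    rows: dict[str, list[dict]] = {k: [] for k in ("domains", "cog", "ko", "cazy", "bgc")}
    for group_id in sorted(profile):
        for label in profile[group_id]:
            if label.kind not in rows:
                raise ConfigurationError(f"unknown annotation kind {label.kind!r}")
            for pid in sorted(members.get(group_id, [])):
                if label.kind == "domains":
                    rows["domains"].append(
                        {
                            "protein_id": pid,
                            "accession": label.label,
                            "name": label.name or label.label,
                            "ievalue": label.evalue,
                            "start": label.start,
                            "end": label.end,
                        }
                    )
                elif label.kind == "cog":
                    rows["cog"].append(
                        {"protein_id": pid, "cog_category": label.label, "evalue": label.evalue}
                    )
                elif label.kind == "ko":
                    rows["ko"].append(
                        {
                            "protein_id": pid,
                            "ko": label.label,
                            "score": label.score if label.score is not None else 100.0,
                            "threshold": label.threshold if label.threshold is not None else 50.0,
                            "ievalue": label.evalue,
                        }
                    )
                elif label.kind == "cazy":
                    rows["cazy"].append({"protein_id": pid, "family": label.label})
                else:  # bgc
                    rows["bgc"].append(
                        {
                            "protein_id": pid,
                            "bgc_id": label.bgc_id or f"{pid}_bgc",
                            "bgc_type": label.label,
                            "core_enzyme": label.core_enzyme,
                        }
                    )
    columns = {
        "domains": DOMAIN_COLUMNS,
        "cog": COG_COLUMNS,
        "ko": KO_COLUMNS,
        "cazy": CAZY_COLUMNS,
        "bgc": BGC_COLUMNS,
    }
    return {
        kind: pd.DataFrame(rows[kind], columns=columns[kind]) for kind in rows
    }


def write_annotations(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in sorted(tables):
        path = out / f"{kind}.tsv"
        write_annotation_tsv(tables[kind], path, kind)
        paths[kind] = path
    return paths


def planted_block_matrix(
    n_blocks: int = 2,
    strains_per_block: int = 20,
    cols_per_block: int = 30,
    within_block_flip: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[int]]:
    """Binary presence-absence matrix with well-separated strain blocks.

    Each block of strains carries its own disjoint set of columns;
    ``within_block_flip`` randomly flips that fraction of entries so
    rows within a block are similar but not identical.  Returns the
    matrix and the planted block label per strain (row order).
    """
    rng = np.random.default_rng(seed)
    n_rows = n_blocks * strains_per_block
    n_cols = n_blocks * cols_per_block
    mat = np.zeros((n_rows, n_cols), dtype=np.int8)
    labels = []
    for b in range(n_blocks):
        rows = slice(b * strains_per_block, (b + 1) * strains_per_block)
        cols = slice(b * cols_per_block, (b + 1) * cols_per_block)
        mat[rows, cols] = 1
        labels += [b] * strains_per_block
    flips = rng.random(mat.shape) < within_block_flip
    mat = np.where(flips, 1 - mat, mat).astype(np.int8)
    index = [f"S{i + 1:03d}" for i in range(n_rows)]
    columns = [f"OG{j + 1:05d}" for j in range(n_cols)]
    return pd.DataFrame(mat, index=index, columns=columns), labels
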