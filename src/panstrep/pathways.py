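"""KO assignment and pathway-completeness scoring.

KO (KEGG Orthology) assignment follows the KofamKOALA convention: a
hit is accepted when its independent E-value is below 1e-10 *and* its
bit score reaches the KO-specific adaptive threshold.  A relaxed mode
additionally rescues proteins left unassigned by the standard rule:
they receive their highest-score KO whenever that hit's independent
E-value is below 1e-80 (strict), capturing strong homologues whose
scores narrowly miss the adaptive threshold.

Pathway completeness is genome-level presence: a pathway of k ordered
steps, each satisfiable by any KO from its acceptable set (OR
semantics, isoenzymes being the rationale), is complete iff every step
has at least one KO encoded in the genome.  The canonical case is the
beta-ketoadipate pathway: the protocatechuate and catechol branches
each comprise six reactions of which the last three are shared, so the
shared-step flags of the two branches always agree for a genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError

KO_EVALUE_THRESHOLD = 1e-10
RELAXED_EVALUE_THRESHOLD = 1e-80


@dataclass(frozen=True)
class KOAssignment:
    protein_id: str
    ko: str
    score: float
    evalue: float
    adaptive_threshold_passed: bool


def assign_ko(
    rows: pd.DataFrame | Iterable[tuple[str, str, float, float, float]],
    relaxed: bool = False,
    evalue_threshold: float = KO_EVALUE_THRESHOLD,
    relaxed_evalue_threshold: float = RELAXED_EVALUE_THRESHOLD,
) -> list[KOAssignment]:
    """Assign at most one KO term per protein.

    ``rows`` carries candidate hits (protein_id, ko, score,
    KO-specific threshold, independent E-value), either as a DataFrame
    with those columns or as tuples.  Standard rule: E < 1e-10 and
    score >= threshold.  Relaxed rule (``relaxed=True``): proteins
    with no standard assignment still receive their highest-score KO
    when its E-value is < 1e-80 (strict).  The best hit per protein is
    chosen by score, ties broken by smaller E-value then lexicographic
    KO id.  Output is sorted by protein id.
    """
    if isinstance(rows, pd.DataFrame):
        records = list(
            rows[["protein_id", "ko", "score", "threshold", "ievalue"]].itertuples(
                index=False, name=None
            )
        )
    else:
        records = list(rows)
    by_protein: dict[str, list[tuple[str, float, float, float]]] = {}
    for protein_id, ko, score, threshold, evalue in records:
        score, threshold, evalue = float(score), float(threshold), float(evalue)
        if score < 0 or evalue < 0:
            raise ValueError(
                f"negative score or E-value for protein {protein_id!r}"
            )
        by_protein.setdefault(protein_id, []).append((ko, score, threshold, evalue))

    def best(hits: list[tuple[str, float, float, float]]):
        # highest score, then smaller E-value, then lexicographic KO id
        return min(hits, key=lambda h: (-h[1], h[3], h[0]))

    assignments: list[KOAssignment] = []
    for protein_id in sorted(by_protein):
        hits = by_protein[protein_id]
        standard = [
            h for h in hits if h[3] < evalue_threshold and h[1] >= h[2]
        ]
        if standard:
            ko, score, _, evalue = best(standard)
            assignments.append(
                KOAssignment(protein_id, ko, score, evalue, adaptive_threshold_passed=True)
            )
        elif relaxed:
            ko, score, _, evalue = best(hits)
            if evalue < relaxed_evalue_threshold:
                assignments.append(
                    KOAssignment(
                        protein_id, ko, score, evalue, adaptive_threshold_passed=False
                    )
                )
    return assignments


@dataclass(frozen=True)
class PathwayStep:
    name: str
    kos: frozenset[str]


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered reaction steps, each satisfiable by any KO in its set."""

    pathway_id: str
    steps: tuple[PathwayStep, ...]
    shared_with: str | None = None
    shared_steps: tuple[int, ...] = ()  # 0-based indices into ``steps``

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigurationError(f"pathway {self.pathway_id!r} has no steps")
        for step in self.steps:
            if not step.kos:
                raise ConfigurationError(
                    f"step {step.name!r} of pathway {self.pathway_id!r} has an empty KO set"
                )
        for idx in self.shared_steps:
            if not 0 <= idx < len(self.steps):
                raise ConfigurationError(
                    f"shared step index {idx} out of range for {self.pathway_id!r}"
                )


@dataclass(frozen=True)
class PathwayCall:
    pathway_id: str
    complete: bool
    step_present: tuple[bool, ...]
    missing_steps: tuple[str, ...]


def pathway_complete(genome_kos: Iterable[str], definition: PathwayDefinition) -> PathwayCall:
    """Score one genome against one pathway definition.

    Complete iff every step has at least one of its acceptable KOs in
    the genome's KO set.  Adding KOs can never flip complete to
    incomplete.
    """
    kos = set(genome_kos)
    present = tuple(bool(step.kos & kos) for step in definition.steps)
    missing = tuple(
        step.name for step, ok in zip(definition.steps, present) if not ok
    )
    return PathwayCall(
        pathway_id=definition.pathway_id,
        complete=all(present),
        step_present=present,
        missing_steps=missing,
    )


def branch_summary(
    genome_kos: Mapping[str, Iterable[str]],
    branch_a: PathwayDefinition,
    branch_b: PathwayDefinition,
) -> pd.DataFrame:
    """Joint completeness labels for two branch pathways.

    Returns one row per genome with per-branch completeness and a
    joint label in {both, <branch_a>, <branch_b>, neither}.
    """
    rows = []
    for genome in sorted(genome_kos):
        a = pathway_complete(genome_kos[genome], branch_a)
        b = pathway_complete(genome_kos[genome], branch_b)
        if a.complete and b.complete:
            label = "both"
        elif a.complete:
            label = branch_a.pathway_id
        elif b.complete:
            label = branch_b.pathway_id
        else:
            label = "neither"
        rows.append(
            {
                "genome_id": genome,
                branch_a.pathway_id: a.complete,
                branch_b.pathway_id: b.complete,
                "label": label,
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")


def load_pathway_definitions(path: str | Path) -> dict[str, PathwayDefinition]:
    """Load pathway definitions from a YAML file.

    Schema::

        pathways:
          - pathway_id: protocatechuate
            shared_with: catechol
            shared_steps: [4, 5, 6]     # 1-based step numbers
            steps:
              - name: protocatechuate_34_dioxygenase
                kos: [K00448, K00449]
              ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise ConfigurationError(f"{path}: expected a top-level 'pathways' list")
    out: dict[str, PathwayDefinition] = {}
    for entry in doc["pathways"]:
        steps = tuple(
            PathwayStep(name=s["name"], kos=frozenset(s["kos"])) for s in entry["steps"]
        )
        definition = PathwayDefinition(
            pathway_id=entry["pathway_id"],
            steps=steps,
            shared_with=entry.get("shared_with"),
            shared_steps=tuple(i - 1 for i in entry.get("shared_steps", [])),
        )
        out[definition.pathway_id] = definition
    for definition in out.values():
        if definition.shared_with and definition.shared_with not in out:
            raise ConfigurationError(
                f"pathway {definition.pathway_id!r} shares steps with unknown "
                f"pathway {definition.shared_with!r}"
            )
    return out


def default_beta_ketoadipate_path() -> Path:
    """Path of the shipped beta-ketoadipate definition file."""
    return Path(__file__).parent / "data" / "beta_ketoadipate.yaml"


def load_beta_ketoadipate() -> dict[str, PathwayDefinition]:
    """The shipped six-step protocatechuate and catechol branch definitions."""
    return load_pathway_definitions(default_beta_ketoadipate_path())
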