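"""End-to-end pipeline: proteomes -> hits -> groups -> statistics ->
profiles -> classifiers -> pathways -> CAZyme landscape -> report.

Every stage writes a TSV artefact into the output directory and
records its row counts; stages whose inputs are absent are skipped
with a notice.  A frozen copy of the resolved configuration is written
alongside the outputs, and reruns with the same configuration and seed
produce byte-identical artefacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import classifiers as clf
from . import profiles as prof
from .cazyme import cazyme_landscape
from .clustering import classify_conservation, cluster_proteins, single_copy_strict_core
from .errors import ConfigurationError, PanstrepError
from .io import read_annotation_tsv, read_proteome_dir, write_json
from .pathways import assign_ko, branch_summary, load_beta_ketoadipate, load_pathway_definitions
from .similarity import BLAST14, OrthologueCriteria, all_vs_all, read_blast_tab
from .stats import (
    accumulation_curves,
    conservation_histogram,
    fraction_report,
    per_genome_profile,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    fasta_dir: str
    out_dir: str
    hits: str = "compute"  # "compute" or a BLAST tabular path
    annotations: dict[str, str] = field(default_factory=dict)
    tf_rules: str | None = None
    pathway_definitions: str | None = None
    kegg_mapping: str | None = None
    kegg_exclusions: list[str] = field(default_factory=list)
    min_identity: float = 80.0
    min_coverage_both: float = 0.70
    max_evalue: float = 1e-5
    n_permutations: int = 100
    seed: int = 0
    cazyme_member_fraction: float = 0.70
    cazyme_band: tuple[float, float] = (0.05, 0.55)
    cazyme_min_prevalence: float = 0.05
    embedding_method: str = "umap"
    min_cluster_size: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "cazyme_band" in doc:
            doc["cazyme_band"] = tuple(doc["cazyme_band"])
        return cls(**doc)

    def validate(self) -> None:
        if not Path(self.fasta_dir).is_dir():
            raise ConfigurationError(f"fasta_dir does not exist: {self.fasta_dir}")
        if self.hits != "compute" and not Path(self.hits).is_file():
            raise ConfigurationError(f"hit table does not exist: {self.hits}")
        for kind, path in self.annotations.items():
            if not Path(path).is_file():
                raise ConfigurationError(f"annotation table missing: {kind}={path}")
        if not 0 <= self.min_identity <= 100:
            raise ConfigurationError("min_identity must be in [0, 100]")
        if not 0 < self.min_coverage_both <= 1:
            raise ConfigurationError("min_coverage_both must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ConfigurationError("max_evalue must be positive")

    def criteria(self) -> OrthologueCriteria:
        return OrthologueCriteria(
            min_identity=self.min_identity,
            min_coverage_both=self.min_coverage_both,
            max_evalue=self.max_evalue,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cazyme_band"] = list(d["cazyme_band"])
        return d


def _hits_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "percent_identity": h.percent_identity,
                "alignment_length": h.alignment_length,
                "query_coverage": h.query_coverage,
                "subject_coverage": h.subject_coverage,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
            }
            for h in hits
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage whose inputs are present; return the report dict.

    Any stage failure aborts with the stage name attached to the error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    report: dict[str, Any] = {}
    stage_log: list[dict[str, Any]] = []
    stage = "load_proteomes"
    try:
        records = read_proteome_dir(config.fasta_dir)
        if not records:
            raise PanstrepError(f"no FASTA files found in {config.fasta_dir}")
        genome_map = {r.protein_id: r.genome_id for r in records}
        stage_log.append({"stage": stage, "rows": len(records)})

        stage = "similarity"
        if config.hits == "compute":
            hits = all_vs_all({r.protein_id: r.sequence for r in records})
        else:
            hits = read_blast_tab(config.hits, BLAST14).hits
        _hits_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
        stage_log.append({"stage": stage, "rows": len(hits)})

        stage = "ortholog_clustering"
        pangenome = cluster_proteins(hits, genome_map, config.criteria())
        labels = classify_conservation(pangenome)
        groups_df = pd.DataFrame(
            [
                {
                    "group_id": g.group_id,
                    "size": g.size,
                    "prevalence": g.prevalence,
                    "labels": ",".join(sorted(labels[g.group_id])),
                    "members": ",".join(sorted(g.members)),
                }
                for g in pangenome.groups
            ]
        )
        groups_df.to_csv(out / "groups.tsv", sep="\t", index=False)
        stage_log.append({"stage": stage, "rows": pangenome.n_groups})

        stage = "pangenome_stats"
        curve = accumulation_curves(
            pangenome, n_permutations=config.n_permutations, seed=config.seed
        )
        curve.mean().to_csv(out / "accumulation_curve.tsv", sep="\t", index=False)
        hist = conservation_histogram(pangenome)
        hist.to_frame().to_csv(out / "conservation_histogram.tsv", sep="\t", index=False)
        profile = per_genome_profile(pangenome)
        profile.to_csv(out / "per_genome_profile.tsv", sep="\t")
        n_strict = sum("strict_core" in labels[g.group_id] for g in pangenome.groups)
        n_core = sum("core" in labels[g.group_id] for g in pangenome.groups)
        strict_proteins = sum(
            g.size for g in pangenome.groups if "strict_core" in labels[g.group_id]
        )
        core_proteins = sum(
            g.size for g in pangenome.groups if "core" in labels[g.group_id]
        )
        rare_proteins = sum(
            g.size for g in pangenome.groups if "rare" in labels[g.group_id]
        )
        report["pangenome"] = {
            "n_genomes": pangenome.n_genomes,
            "n_proteins": pangenome.n_proteins,
            "n_groups": pangenome.n_groups,
            "n_strict_core_groups": n_strict,
            "n_core_groups": n_core,
            "n_single_copy_strict_core": len(single_copy_strict_core(pangenome)),
            "counts": {
                "strict_core_proteins": strict_proteins,
                "core_proteins": core_proteins,
                "rare_proteins": rare_proteins,
            },
            "fractions_pct": fraction_report(
                {
                    "strict_core_proteins": (strict_proteins, pangenome.n_proteins),
                    "core_proteins": (core_proteins, pangenome.n_proteins),
                    "rare_proteins": (rare_proteins, pangenome.n_proteins),
                }
            ),
        }
        stage_log.append({"stage": stage, "rows": pangenome.n_genomes})

        annotations = None
        if config.annotations:
            stage = "annotation_profiles"
            annotations = prof.load_annotations(
                {k: Path(v) for k, v in config.annotations.items()},
                kegg_mapping=config.kegg_mapping,
                kegg_exclusions=config.kegg_exclusions,
            )
            report["profiles"] = {}
            for label_type in sorted(set(annotations.df["label_type"])):
                cp = prof.category_profile(pangenome, annotations, label_type)
                cp.counts.to_csv(out / f"profile_{label_type}.tsv", sep="\t")
                report["profiles"][label_type] = {
                    "n_labels": int(len(cp.counts)),
                    "n_proteins": int(cp.totals.sum()),
                }
            stage_log.append({"stage": stage, "rows": len(annotations.df)})
        else:
            stage_log.append({"stage": "annotation_profiles", "skipped": True})

        if annotations is not None and "domains" in config.annotations:
            stage = "feature_classifiers"
            dom_raw = read_annotation_tsv(config.annotations["domains"], "domains")
            raw_hits = [
                clf.DomainHit(
                    protein_id=r.protein_id,
                    accession=r.accession,
                    name=r.name,
                    ievalue=float(r.ievalue),
                    start=int(r.start),
                    end=int(r.end),
                )
                for r in dom_raw.itertuples(index=False)
            ]
            filtered = clf.group_hits_by_protein(
                h for h in raw_hits if h.ievalue < prof.DEFAULT_THRESHOLDS["domains"]
            )
            sigma = clf.classify_sigma(filtered)
            tf = clf.classify_tf(filtered, clf.load_tf_rules(config.tf_rules), sigma)
            chaplins = clf.identify_chaplins(filtered)
            pptases = clf.identify_pptases(clf.group_hits_by_protein(raw_hits))
            call_rows = (
                [
                    {"protein_id": p, "call": f"sigma:{c.family}:{c.group or '-'}"}
                    for p, c in sigma.items()
                ]
                + [{"protein_id": p, "call": f"tf:{fam}"} for p, fam in tf.items()]
                + [{"protein_id": p, "call": "chaplin"} for p in sorted(chaplins)]
                + [
                    {"protein_id": p, "call": f"pptase:{c.pptase_type}"}
                    for p, c in pptases.items()
                ]
            )
            calls = pd.DataFrame(
                call_rows, columns=["protein_id", "call"]
            ).sort_values(["protein_id", "call"])
            calls.to_csv(out / "classifier_calls.tsv", sep="\t", index=False)
            report["classifiers"] = {
                "n_sigma_factors": len(sigma),
                "n_transcription_factors": len(tf),
                "n_chaplins": len(chaplins),
                "n_pptases": len(pptases),
                "n_sfp_type": sum(c.pptase_type == "Sfp" for c in pptases.values()),
            }
            stage_log.append({"stage": stage, "rows": len(calls)})
        else:
            stage_log.append({"stage": "feature_classifiers", "skipped": True})

        if annotations is not None and "ko" in config.annotations:
            stage = "pathway_completeness"
            ko_raw = read_annotation_tsv(config.annotations["ko"], "ko")
            assignments = assign_ko(ko_raw, relaxed=True)
            genome_kos: dict[str, set[str]] = {g: set() for g in pangenome.genome_ids}
            for a in assignments:
                genome = pangenome.protein_to_genome.get(a.protein_id)
                if genome is not None:
                    genome_kos[genome].add(a.ko)
            if config.pathway_definitions:
                definitions = load_pathway_definitions(config.pathway_definitions)
            else:
                definitions = load_beta_ketoadipate()
            ids = sorted(definitions)
            if len(ids) >= 2:
                summary = branch_summary(
                    genome_kos, definitions[ids[0]], definitions[ids[1]]
                )
                summary.to_csv(out / "pathway_completeness.tsv", sep="\t")
                report["pathways"] = summary["label"].value_counts().to_dict()
            stage_log.append({"stage": stage, "rows": len(genome_kos)})
        else:
            stage_log.append({"stage": "pathway_completeness", "skipped": True})

        if annotations is not None and "cazy" in config.annotations:
            stage = "cazyme_landscape"
            families, pa, embedding = cazyme_landscape(
                annotations,
                pangenome,
                member_fraction=config.cazyme_member_fraction,
                band=config.cazyme_band,
                min_prevalence=config.cazyme_min_prevalence,
                method=config.embedding_method,
                min_cluster_size=config.min_cluster_size,
                seed=config.seed,
            )
            landscape = embedding.coordinates.copy()
            landscape["cluster"] = embedding.labels
            landscape.to_csv(out / "cazyme_landscape.tsv", sep="\t")
            report["cazyme"] = {
                "n_selected_families": len(families),
                "n_matrix_columns": pa.matrix.shape[1],
                "cluster_sizes": {
                    str(k): int(v) for k, v in embedding.cluster_sizes().items()
                },
                "n_noise": int((embedding.labels == -1).sum()),
            }
            stage_log.append({"stage": stage, "rows": len(landscape)})
        else:
            stage_log.append({"stage": "cazyme_landscape", "skipped": True})
    except PanstrepError:
        raise
    except Exception as exc:
        raise PanstrepError(f"stage {stage!r} failed: {exc}") from exc

    report["stages"] = stage_log
    write_json(report, out / "report.json")
    return report
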