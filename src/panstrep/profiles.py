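"""Conservation-binned functional profiles.

Joins protein-level functional labels (COG category, KO term / KEGG
category, CAZy family and class, BGC type) with the orthologous-group
prevalence of each protein, and tabulates, for every label, how its
proteins distribute over the twenty 5%-wide conservation bins.  The
bin of a protein is a pure function of its group's prevalence
fraction, identical across all label types.

Label-type-specific E-value thresholds are applied at load time:
domain hits (Pfam/SMART-style) at independent E < 1e-1, COG
assignments (EggNOG-style) at E < 1e-10, and KO assignments via the
adaptive-threshold rule of :mod:`panstrep.pathways`.  Dropped rows are
counted so kept + dropped always equals the input row count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clustering import Pangenome
from .errors import ConfigurationError
from .io import read_annotation_tsv
from .pathways import assign_ko
from .stats import N_BINS, bin_edges, percent, prevalence_bin

logger = logging.getLogger(__name__)

LABEL_TYPES = (
    "COG_category",
    "KO_term",
    "KEGG_category",
    "CAZy_family",
    "CAZy_class",
    "BGC_type",
    "domain_accession",
)

DEFAULT_THRESHOLDS = {
    "domains": 1e-1,  # Pfam/SMART independent E-value
    "cog": 1e-10,  # EggNOG independent E-value
    "ko_evalue": 1e-10,  # KofamKOALA independent E-value (plus adaptive score)
}

_ANNOTATION_COLUMNS = [
    "protein_id", "label_type", "label", "evalue", "score", "core_enzyme", "provenance",
]


@dataclass
class AnnotationTable:
    """Long-format protein -> label rows with drop accounting."""

    df: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)
    n_duplicates: int = 0

    def of_type(self, label_type: str) -> pd.DataFrame:
        if label_type not in LABEL_TYPES:
            raise ValueError(f"unknown label_type {label_type!r}")
        return self.df[self.df["label_type"] == label_type]


def cazy_class_of(family: str) -> str:
    """CAZy class prefix of a family name, e.g. GH13 -> GH, CBM2 -> CBM."""
    m = re.match(r"[A-Za-z]+", family)
    if not m:
        raise ValueError(f"cannot derive CAZy class from family {family!r}")
    return m.group(0)


def load_annotations(
    tables: Mapping[str, pd.DataFrame | str | Path],
    thresholds: Mapping[str, float] | None = None,
    kegg_mapping: pd.DataFrame | str | Path | None = None,
    kegg_exclusions: Iterable[str] = (),
    cog_split: bool = True,
    ko_relaxed: bool = False,
) -> AnnotationTable:
    """Load, threshold and normalise annotation tables.

    ``tables`` maps table kind (``domains``, ``cog``, ``ko``, ``cazy``,
    ``bgc``) to a DataFrame or TSV path in that kind's dialect.
    Multi-letter COG assignments are split into one contribution per
    letter by default (``cog_split=False`` keeps the first letter
    only).  ``kegg_mapping`` (columns: ko, pathway, category) rolls KO
    terms up to KEGG categories; pathways named in ``kegg_exclusions``
    (e.g. eukaryote-only pathways and the secondary-metabolite
    biosynthesis category) are excluded.  Duplicate identical rows are
    deduplicated and counted.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    frames: list[pd.DataFrame] = []
    dropped: dict[str, int] = {}

    def resolve(kind: str) -> pd.DataFrame | None:
        src = tables.get(kind)
        if src is None:
            return None
        if isinstance(src, pd.DataFrame):
            return src
        return read_annotation_tsv(src, kind)

    dom = resolve("domains")
    if dom is not None:
        keep = dom["ievalue"] < th["domains"]
        dropped["domains"] = int((~keep).sum())
        kept = dom[keep]
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": kept["protein_id"],
                    "label_type": "domain_accession",
                    "label": kept["accession"],
                    "evalue": kept["ievalue"],
                    "score": np.nan,
                    "core_enzyme": pd.NA,
                    "provenance": "domains",
                }
            )
        )

    cog = resolve("cog")
    if cog is not None:
        keep = cog["evalue"] < th["cog"]
        dropped["cog"] = int((~keep).sum())
        kept = cog[keep]
        records = []
        for _, row in kept.iterrows():
            letters = list(row["cog_category"]) if cog_split else [row["cog_category"][0]]
            for letter in letters:
                records.append((row["protein_id"], letter, row["evalue"]))
        rec = pd.DataFrame(records, columns=["protein_id", "label", "evalue"])
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": rec["protein_id"],
                    "label_type": "COG_category",
                    "label": rec["label"],
                    "evalue": rec["evalue"],
                    "score": np.nan,
                    "core_enzyme": pd.NA,
                    "provenance": "cog",
                }
            )
        )

    ko = resolve("ko")
    if ko is not None:
        assignments = assign_ko(ko, relaxed=ko_relaxed, evalue_threshold=th["ko_evalue"])
        dropped["ko"] = len(ko) - len(assignments)
        ko_df = pd.DataFrame(
            {
                "protein_id": [a.protein_id for a in assignments],
                "label_type": "KO_term",
                "label": [a.ko for a in assignments],
                "evalue": [a.evalue for a in assignments],
                "score": [a.score for a in assignments],
                "core_enzyme": pd.NA,
                "provenance": "ko",
            }
        )
        frames.append(ko_df)
        if kegg_mapping is not None:
            if not isinstance(kegg_mapping, pd.DataFrame):
                kegg_mapping = pd.read_csv(kegg_mapping, sep="\t", dtype=str)
            required = {"ko", "pathway", "category"}
            if not required <= set(kegg_mapping.columns):
                raise ConfigurationError(
                    f"kegg_mapping needs columns {sorted(required)}"
                )
            excl = set(kegg_exclusions)
            mapping = kegg_mapping[~kegg_mapping["pathway"].isin(excl)]
            merged = ko_df.merge(mapping, left_on="label", right_on="ko", how="inner")
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": merged["protein_id"],
                        "label_type": "KEGG_category",
                        "label": merged["category"],
                        "evalue": merged["evalue"],
                        "score": merged["score"],
                        "core_enzyme": pd.NA,
                        "provenance": "kegg",
                    }
                )
            )

    cazy = resolve("cazy")
    if cazy is not None:
        dropped["cazy"] = 0
        for label_type, labels in (
            ("CAZy_family", cazy["family"]),
            ("CAZy_class", cazy["family"].map(cazy_class_of)),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": cazy["protein_id"],
                        "label_type": label_type,
                        "label": labels,
                        "evalue": np.nan,
                        "score": np.nan,
                        "core_enzyme": pd.NA,
                        "provenance": "cazy",
                    }
                )
            )

    bgc = resolve("bgc")
    if bgc is not None:
        dropped["bgc"] = 0
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": bgc["protein_id"],
                    "label_type": "BGC_type",
                    "label": bgc["bgc_type"],
                    "evalue": np.nan,
                    "score": np.nan,
                    "core_enzyme": bgc["core_enzyme"].astype("boolean"),
                    "provenance": "bgc",
                }
            )
        )

    frames = [f for f in frames if not f.empty]
    if frames:
        df = pd.concat(frames, ignore_index=True)[_ANNOTATION_COLUMNS]
    else:
        df = pd.DataFrame(columns=_ANNOTATION_COLUMNS)
    before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    n_dup = before - len(df)
    if n_dup:
        logger.info("load_annotations: removed %d duplicate rows", n_dup)
    return AnnotationTable(df=df, dropped=dropped, n_duplicates=n_dup)


@dataclass
class CategoryConservationProfile:
    """Per-label conservation-bin distribution.

    ``counts`` is labels x 20 bins (protein counts); percentages are
    row-normalised; ``core_fraction`` is the fraction of each label's
    proteins in groups at prevalence >= 95%.
    """

    counts: pd.DataFrame
    label_type: str
    n_genomes: int

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def percentages(self, decimals: int = 1) -> pd.DataFrame:
        totals = self.totals
        out = self.counts.copy().astype(float)
        for label in out.index:
            total = int(totals[label])
            out.loc[label] = [
                percent(int(c), total, decimals) if total else 0.0
                for c in self.counts.loc[label]
            ]
        return out

    def core_fraction(self, core_fraction: float = 0.95) -> pd.Series:
        first_core_bin = prevalence_bin(core_fraction)
        core = self.counts.iloc[:, first_core_bin:].sum(axis=1)
        return core / self.totals


def category_profile(
    pangenome: Pangenome,
    annotations: AnnotationTable,
    label_type: str,
) -> CategoryConservationProfile:
    """Distribute each label's annotated proteins over conservation bins.

    A protein contributes once per distinct label of the requested
    type; unannotated proteins are excluded.  Annotations referencing
    proteins outside the pangenome universe are an error.
    """
    rows = annotations.of_type(label_type)[["protein_id", "label"]].drop_duplicates()
    unknown = set(rows["protein_id"]) - set(pangenome.protein_to_group)
    if unknown:
        raise ValueError(
            f"annotations reference proteins outside the pangenome: {sorted(unknown)[:5]}"
        )
    labels = sorted(rows["label"].unique())
    counts = pd.DataFrame(
        0, index=labels, columns=[f"bin_{i + 1:02d}" for i in range(N_BINS)], dtype=np.int64
    )
    for protein_id, label in rows.itertuples(index=False):
        gid = pangenome.protein_to_group[protein_id]
        b = prevalence_bin(pangenome.prevalence_fraction(gid))
        counts.loc[label, f"bin_{b + 1:02d}"] += 1
    counts.attrs["bin_edges"] = bin_edges()
    return CategoryConservationProfile(
        counts=counts, label_type=label_type, n_genomes=pangenome.n_genomes
    )


@dataclass
class ClassCountStats:
    """Per-genome annotation counts per class, with dispersion summaries."""

    per_genome: pd.DataFrame  # genomes x classes
    summary: pd.DataFrame  # classes x (mean, sd, cv)
    totals: pd.Series  # per-genome totals over all classes


def class_count_stats(
    annotations: AnnotationTable,
    pangenome: Pangenome,
    label_type: str = "CAZy_class",
) -> ClassCountStats:
    """Count annotated proteins per genome and class; report CV = SD/mean.

    SD uses the population convention (ddof=0).  A class absent from
    every genome has mean 0 and its CV is reported as missing (NaN).
    """
    rows = annotations.of_type(label_type)[["protein_id", "label"]].drop_duplicates()
    genomes = list(pangenome.genome_ids)
    classes = sorted(rows["label"].unique())
    per_genome = pd.DataFrame(0, index=genomes, columns=classes, dtype=np.int64)
    for protein_id, label in rows.itertuples(index=False):
        genome = pangenome.protein_to_genome.get(protein_id)
        if genome is None:
            raise ValueError(f"protein {protein_id!r} not in the pangenome universe")
        per_genome.loc[genome, label] += 1
    mean = per_genome.mean(axis=0)
    sd = per_genome.std(axis=0, ddof=0)
    cv = sd / mean.replace(0, np.nan)
    summary = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    return ClassCountStats(
        per_genome=per_genome, summary=summary, totals=per_genome.sum(axis=1)
    )


def bgc_core_enzyme_profile(
    pangenome: Pangenome, annotations: AnnotationTable
) -> CategoryConservationProfile:
    """Conservation profile of BGC core enzymes, keyed by BGC type.

    Same computation as :func:`category_profile`, restricted to
    proteins flagged as core biosynthetic enzymes in the BGC table.
    """
    bgc = annotations.of_type("BGC_type")
    core_rows = bgc[bgc["core_enzyme"].fillna(False).astype(bool)]
    restricted = AnnotationTable(df=core_rows)
    return category_profile(pangenome, restricted, "BGC_type")
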