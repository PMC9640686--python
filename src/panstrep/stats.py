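"""Pangenome summary statistics: accumulation curves, conservation
histograms, per-genome profiles, and printed-percentage reporting.

The accumulation curve samples random genome orderings and tracks, as
genomes are added one by one, the pangenome size (number of groups seen
so far), the strict core (groups present in all genomes so far) and the
soft core (groups present in >= 95% of genomes so far).  An open
pangenome keeps growing with every added genome; the strict core
shrinks monotonically along any single ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import Pangenome

N_BINS = 20  # 5%-wide prevalence bins: (0, 0.05], (0.05, 0.10], ..., (0.95, 1.0]


def prevalence_bin(fraction: float, n_bins: int = N_BINS) -> int:
    """Index of the half-open bin ((i)/n, (i+1)/n] containing ``fraction``.

    Fractions are in (0, 1]; bin edges are open on the left and closed
    on the right, so prevalence 10/205 (~4.88%) falls in the lowest bin
    and exactly 5% falls in the first, not the second.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"prevalence fraction must be in (0, 1], got {fraction}")
    return min(math.ceil(fraction * n_bins) - 1, n_bins - 1)


def bin_edges(n_bins: int = N_BINS) -> list[tuple[float, float]]:
    return [(i / n_bins, (i + 1) / n_bins) for i in range(n_bins)]


@dataclass
class AccumulationCurve:
    """Per-permutation pangenome / core trajectories.

    Arrays are shaped (n_permutations, n_genomes); column k-1 holds the
    statistic after the first k genomes of each sampled ordering.
    """

    pangenome_size: np.ndarray
    strict_core_size: np.ndarray
    soft_core_size: np.ndarray
    n_permutations: int
    seed: int
    soft_core_fraction: float = 0.95

    def mean(self) -> pd.DataFrame:
        k = np.arange(1, self.pangenome_size.shape[1] + 1)
        return pd.DataFrame(
            {
                "k": k,
                "pangenome": self.pangenome_size.mean(axis=0),
                "strict_core": self.strict_core_size.mean(axis=0),
                "soft_core": self.soft_core_size.mean(axis=0),
            }
        )


def _incidence_matrix(pangenome: Pangenome) -> np.ndarray:
    """Genome x group boolean presence matrix in genome_ids order."""
    gidx = {g: i for i, g in enumerate(pangenome.genome_ids)}
    mat = np.zeros((pangenome.n_genomes, pangenome.n_groups), dtype=bool)
    for j, group in enumerate(pangenome.groups):
        for genome in group.genomes:
            mat[gidx[genome], j] = True
    return mat


def accumulation_curves(
    pangenome: Pangenome,
    n_permutations: int = 100,
    seed: int = 0,
    soft_core_fraction: float = 0.95,
) -> AccumulationCurve:
    """Sample genome orderings and accumulate pangenome/core sizes.

    The number of orderings is a free parameter (default 100, fixed
    seed); at k genomes the soft core counts groups present in at least
    ``soft_core_fraction`` of those k.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    incidence = _incidence_matrix(pangenome)
    n = pangenome.n_genomes
    pan = np.zeros((n_permutations, n), dtype=np.int64)
    strict = np.zeros_like(pan)
    soft = np.zeros_like(pan)
    ks = np.arange(1, n + 1)[:, None]
    for p in range(n_permutations):
        order = rng.permutation(n)
        counts = np.cumsum(incidence[order], axis=0)  # (k, groups)
        pan[p] = (counts >= 1).sum(axis=1)
        strict[p] = (counts == ks).sum(axis=1)
        soft[p] = (counts >= soft_core_fraction * ks).sum(axis=1)
    return AccumulationCurve(
        pangenome_size=pan,
        strict_core_size=strict,
        soft_core_size=soft,
        n_permutations=n_permutations,
        seed=seed,
        soft_core_fraction=soft_core_fraction,
    )


@dataclass
class ConservationHistogram:
    """Protein and group counts per 5%-wide prevalence bin."""

    group_counts: np.ndarray
    protein_counts: np.ndarray
    edges: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": [lo for lo, _ in self.edges],
                "bin_high": [hi for _, hi in self.edges],
                "groups": self.group_counts,
                "proteins": self.protein_counts,
            }
        )


def conservation_histogram(pangenome: Pangenome, n_bins: int = N_BINS) -> ConservationHistogram:
    """Bin every group by its prevalence fraction; proteins weight by group size."""
    group_counts = np.zeros(n_bins, dtype=np.int64)
    protein_counts = np.zeros(n_bins, dtype=np.int64)
    for group in pangenome.groups:
        b = prevalence_bin(group.prevalence / pangenome.n_genomes, n_bins)
        group_counts[b] += 1
        protein_counts[b] += group.size
    return ConservationHistogram(
        group_counts=group_counts,
        protein_counts=protein_counts,
        edges=bin_edges(n_bins),
    )


def per_genome_profile(
    pangenome: Pangenome,
    core_fraction: float = 0.95,
    rare_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-genome protein tallies by the conservation of their groups.

    Columns: total, core (group prevalence >= 95%), rare (< 5%),
    strain_specific (group confined to this genome) and singletons
    (proteins with no orthologues at all).
    """
    rows = {
        g: {"total": 0, "core": 0, "rare": 0, "strain_specific": 0, "singletons": 0}
        for g in pangenome.genome_ids
    }
    n = pangenome.n_genomes
    for group in pangenome.groups:
        frac = group.prevalence / n
        for genome, copies in group.copy_number.items():
            row = rows[genome]
            row["total"] += copies
            if frac >= core_fraction:
                row["core"] += copies
            if frac < rare_fraction:
                row["rare"] += copies
            if group.prevalence == 1:
                row["strain_specific"] += copies
            if group.size == 1:
                row["singletons"] += copies
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("genome_id")


def unique_vs_size_correlation(
    profile: pd.DataFrame,
    rare_column: str = "rare",
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation between per-genome rare-protein count and proteome size.

    Spearman rank correlation by default (Pearson switchable); requires
    at least 3 genomes and non-constant columns.
    """
    if len(profile) < 3:
        raise ValueError("correlation requires at least 3 genomes")
    x = profile[rare_column].to_numpy(dtype=float)
    y = profile["total"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant column")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator with half-up rounding.

    Half-up (not banker's) rounding matches the convention of printed
    percentages such as 4.3% and 16.0%.
    """
    if denominator == 0:
        raise ValueError("zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def fraction_report(
    counts: Mapping[str, tuple[int, int]], decimals: int = 1
) -> dict[str, float]:
    """Named (numerator, denominator) pairs -> rounded percentages."""
    return {name: percent(num, den, decimals) for name, (num, den) in counts.items()}


def heaps_exponent(curve: AccumulationCurve) -> float:
    """Least-squares exponent gamma of a Heaps-law fit P(k) ~ kappa * k^gamma.

    Convenience openness diagnostic on the mean accumulation curve:
    gamma < 1 with gamma > 0 indicates an open pangenome; a closed
    pangenome plateaus (gamma near 0 at large k).
    """
    mean = curve.pangenome_size.mean(axis=0)
    k = np.arange(1, len(mean) + 1)
    slope, _ = np.polyfit(np.log(k), np.log(mean), 1)
    return float(slope)
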