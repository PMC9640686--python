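"""CAZyme-based strain clustering.

Selects CAZyme families whose members are predominantly mid-prevalence
-- at least 70% of a family's proteins in orthologous groups conserved
in 5-55% of strains (both bounds inclusive) -- builds the binary
strain x orthologous-group presence-absence matrix over those
families' groups (restricted to groups at >= 5% prevalence), embeds
strains in 2D and clusters them by density.

The default embedding is UMAP with a fixed seed; a deterministic
classical-MDS fallback on the same Jaccard distances is provided so
cluster recovery can be verified independently of the stochastic
embedder.  Clusters are found with HDBSCAN on the 2D coordinates;
noise points are labelled -1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import HDBSCAN

from .clustering import Pangenome
from .errors import PanstrepError
from .profiles import AnnotationTable

logger = logging.getLogger(__name__)


def select_families(
    annotations: AnnotationTable,
    pangenome: Pangenome,
    member_fraction: float = 0.70,
    band: tuple[float, float] = (0.05, 0.55),
) -> list[str]:
    """CAZyme families with >= 70% of members in the mid-prevalence band.

    A family qualifies iff at least ``member_fraction`` of its
    annotated proteins belong to orthologous groups whose prevalence
    fraction lies in ``band`` (inclusive on both ends).  Families with
    zero members are skipped with a log entry.
    """
    lo, hi = band
    rows = annotations.of_type("CAZy_family")[["protein_id", "label"]].drop_duplicates()
    selected = []
    for family, fam_rows in rows.groupby("label"):
        n = len(fam_rows)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            logger.info("select_families: skipping empty family %s", family)
            continue
        in_band = 0
        for protein_id in fam_rows["protein_id"]:
            gid = pangenome.protein_to_group.get(protein_id)
            if gid is None:
                raise ValueError(f"protein {protein_id!r} not in the pangenome")
            frac = pangenome.prevalence_fraction(gid)
            if lo <= frac <= hi:
                in_band += 1
        if in_band / n >= member_fraction:
            selected.append(family)
    return sorted(selected)


@dataclass
class PresenceAbsenceMatrix:
    """Binary strain x orthologous-group matrix with column metadata."""

    matrix: pd.DataFrame  # rows strains, columns group ids, int8 entries
    column_meta: pd.DataFrame  # group -> families, prevalence fraction

    @property
    def strains(self) -> list[str]:
        return list(self.matrix.index)


def build_pa_matrix(
    selected_families: list[str],
    annotations: AnnotationTable,
    pangenome: Pangenome,
    min_prevalence: float = 0.05,
) -> PresenceAbsenceMatrix:
    """Presence-absence matrix over the selected families' groups.

    Columns are the orthologous groups containing at least one protein
    of a selected family, restricted to prevalence fraction >=
    ``min_prevalence``; rows are all strains; an entry is 1 iff the
    strain holds at least one member of the group.
    """
    rows = annotations.of_type("CAZy_family")[["protein_id", "label"]].drop_duplicates()
    rows = rows[rows["label"].isin(selected_families)]
    group_families: dict[str, set[str]] = {}
    for protein_id, family in rows.itertuples(index=False):
        gid = pangenome.protein_to_group[protein_id]
        group_families.setdefault(gid, set()).add(family)
    kept = sorted(
        gid
        for gid in group_families
        if pangenome.prevalence_fraction(gid) >= min_prevalence
    )
    if not kept:
        raise PanstrepError(
            "empty presence-absence matrix; relax the family-selection band "
            "or the minimum group prevalence"
        )
    strains = list(pangenome.genome_ids)
    mat = pd.DataFrame(0, index=strains, columns=kept, dtype=np.int8)
    for gid in kept:
        for genome in pangenome.group(gid).genomes:
            mat.loc[genome, gid] = 1
    meta = pd.DataFrame(
        {
            "families": [",".join(sorted(group_families[g])) for g in kept],
            "prevalence_fraction": [pangenome.prevalence_fraction(g) for g in kept],
        },
        index=kept,
    )
    return PresenceAbsenceMatrix(matrix=mat, column_meta=meta)


@dataclass
class StrainEmbedding:
    """2D strain coordinates plus density-cluster labels (-1 = noise)."""

    coordinates: pd.DataFrame  # strains x (x, y)
    labels: pd.Series  # strain -> cluster label
    params: dict = field(default_factory=dict)
    seed: int = 0

    def cluster_sizes(self) -> pd.Series:
        return self.labels[self.labels >= 0].value_counts().sort_index()


def _classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Deterministic classical (Torgerson) MDS of a distance matrix."""
    n = distances.shape[0]
    d2 = distances**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_components]
    vals = np.clip(eigval[order], 0, None)
    coords = eigvec[:, order] * np.sqrt(vals)
    # fix the sign convention so the embedding is reproducible
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords


def embed_and_cluster(
    pa: PresenceAbsenceMatrix | pd.DataFrame,
    method: str = "umap",
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "jaccard",
    min_cluster_size: int = 5,
    seed: int = 0,
) -> StrainEmbedding:
    """Embed strains in 2D and cluster by density.

    ``method`` is ``"umap"`` (stochastic, seeded) or ``"mds"``
    (deterministic classical MDS on the pairwise Jaccard distances).
    Clustering uses HDBSCAN on the 2D coordinates.  Requires at least
    5 strains.  With a fixed seed the output is reproducible.
    """
    matrix = pa.matrix if isinstance(pa, PresenceAbsenceMatrix) else pa
    if len(matrix) < 5:
        raise PanstrepError("embedding requires at least 5 strains")
    data = matrix.to_numpy(dtype=bool)
    if method == "umap":
        import umap  # deferred: heavy import

        n_neighbors = min(n_neighbors, len(matrix) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                min_dist=min_dist,
                metric=metric,
                random_state=seed,
            )
            coords = np.asarray(reducer.fit_transform(data), dtype=np.float64)
    elif method == "mds":
        if metric != "jaccard":  # pragma: no cover - configuration guard
            raise PanstrepError("the MDS fallback supports the jaccard metric only")
        distances = squareform(pdist(data, metric="jaccard"))
        coords = _classical_mds(distances)
    else:
        raise PanstrepError(f"unknown embedding method {method!r}")
    if np.allclose(coords, coords[0]):
        # fully degenerate input (all strains identical): one cluster,
        # which density clustering cannot represent on zero spread
        labels = np.zeros(len(coords), dtype=int)
    else:
        clusterer = HDBSCAN(min_cluster_size=min_cluster_size, copy=True)
        labels = clusterer.fit_predict(coords)
    return StrainEmbedding(
        coordinates=pd.DataFrame(coords, index=matrix.index, columns=["x", "y"]),
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        params={
            "method": method,
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "metric": metric,
            "min_cluster_size": min_cluster_size,
        },
        seed=seed,
    )


def cazyme_landscape(
    annotations: AnnotationTable,
    pangenome: Pangenome,
    member_fraction: float = 0.70,
    band: tuple[float, float] = (0.05, 0.55),
    min_prevalence: float = 0.05,
    method: str = "umap",
    min_cluster_size: int = 5,
    seed: int = 0,
) -> tuple[list[str], PresenceAbsenceMatrix, StrainEmbedding]:
    """Full chain: family selection -> matrix -> embedding + clusters."""
    families = select_families(annotations, pangenome, member_fraction, band)
    pa = build_pa_matrix(families, annotations, pangenome, min_prevalence)
    embedding = embed_and_cluster(
        pa, method=method, min_cluster_size=min_cluster_size, seed=seed
    )
    return families, pa, embedding
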