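"""Strain clustering from a CAZyme presence-absence matrix.

Two planted strain blocks carry disjoint sets of orthologous groups
(with 5% random flips).  The strains are embedded in 2D and clustered
by density; with well-separated blocks both the seeded UMAP embedding
and the deterministic classical-MDS fallback recover the blocks
exactly (cluster label -1 would mean noise).
"""

from sklearn.metrics import adjusted_rand_score

from panstrep import embed_and_cluster, planted_block_matrix

matrix, truth = planted_block_matrix(
    n_blocks=2, strains_per_block=20, cols_per_block=30, seed=7
)
print(f"matrix: {matrix.shape[0]} strains x {matrix.shape[1]} groups")

for method in ("mds", "umap"):
    embedding = embed_and_cluster(matrix, method=method, min_cluster_size=10, seed=4)
    sizes = embedding.cluster_sizes().to_dict()
    ari = adjusted_rand_score(truth, embedding.labels.to_numpy())
    print(f"{method}: cluster sizes {sizes}, "
          f"noise {(embedding.labels == -1).sum()}, ARI vs planted blocks {ari}")
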