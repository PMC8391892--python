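"""Ward/Euclidean clustering and PCA of all simulated samples.

Applies the classification pipeline (second derivative + vector
normalization over the 3541-3153 and 1771-663 cm^-1 windows) to the full
56-sample design, builds the Ward dendrogram, and cuts it into two
clusters: the phenylethyl-alcohol arm separates from every terpene-oil
sample, mirroring how an aromatic adulterant stands apart from
chemically related essential oils.
"""

from rosecal import RunConfig, cut_dendrogram, run_clustering

config = RunConfig(seed=1, noise_sd=0.003)
dendrogram, pca = run_clustering(config)

print(f"dendrogram: {len(dendrogram.merges)} merges over "
      f"{len(dendrogram.leaf_ids)} samples")
print("top three merge heights:",
      [f"{m[2]:.3f}" for m in dendrogram.merges[-3:]])
print("PCA explained variance ratios (3 components):",
      [f"{r:.3f}" for r in pca.explained_variance_ratio])

labels = cut_dendrogram(dendrogram, 2)
clusters: dict[int, list[str]] = {}
for sample_id, label in labels.items():
    clusters.setdefault(label, []).append(sample_id)
minority = min(clusters.values(), key=len)
print(f"\n2-cluster cut -> sizes {sorted(len(c) for c in clusters.values())}")
print("minority cluster:", sorted(minority))
print(
    "\nThe minority cluster holds the phenylethyl-alcohol series at 16% "
    "v/v and above\n(including the pure adulterant): its sharp aromatic "
    "bands dominate the\nsecond-derivative spectrum once the volume "
    "fraction is appreciable, while\nlow-level PEOH samples and all "
    "terpene-oil blends stay on the other arm."
)
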