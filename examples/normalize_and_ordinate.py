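"""TIC normalization + Bray-Curtis PCoA on a synthetic study.

Shows the standard exploratory path: normalize each sample by its total
ion current, compute Bray-Curtis dissimilarities, embed with classical
PCoA, and report how much variation the leading axes capture.
"""

from metord import (
    FixtureSpec, generate, normalize_tic, pairwise_distances, pcoa,
)

table, metadata, _ = generate(FixtureSpec(seed=1))
dm = pairwise_distances(normalize_tic(table), "braycurtis")
result = pcoa(dm, num_axes=3)

print(f"distance matrix: {dm.n} x {dm.n} ({dm.metric_name})")
for a, prop in enumerate(result.proportion_explained):
    print(f"PCo{a + 1}: {100 * prop:.1f}% of variation")
print(f"negative eigenvalue mass: {result.negative_eigenvalue_mass:.3g}")

# Each axis's percentage is its eigenvalue over the sum of positive
# eigenvalues; the negative mass (non-zero for non-Euclidean metrics like
# Bray-Curtis) measures how much of the dissimilarity structure cannot be
# embedded in Euclidean space.
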