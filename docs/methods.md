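# Methods

## Scope and data model

The package operates on post-quantification LC-MS/MS feature tables: a
dense non-negative matrix of peak areas with samples as rows and features
(m/z × retention-time peaks) as columns. Missing cells are stored as
zeros, which is the natural reading of sparse quantification exports where
a feature simply was not detected in a sample. Raw spectral data (mzML)
and network retrieval of processing results are out of scope; users export
a quantification table first.

Two input dialects are read: the GNPS/mzMine quantification CSV (one
feature per row, `row ID` / `row m/z` / `row retention time` headers,
one `<sample>.mzML Peak area` column per sample) and a plain table with a
single id column in either orientation. GNPS sample columns are
canonicalized by stripping one trailing ` Peak area` token and one
`.mzML`/`.mzXML` extension (case-insensitive), which makes table ids match
the ids used in metadata files. Delimiters follow the file extension
(`.csv` comma, `.tsv`/`.txt` tab) and can be overridden.

All numeric output is written with 17 significant digits (`%.17g`), the
shortest representation that round-trips IEEE doubles exactly. A
12-digit format was considered but cannot guarantee the 1e-12 relative
round-trip accuracy the writers promise, so exact round-trip won.

## Blank filtering

For feature f let m_f be its mean intensity over blank samples. f is
retained iff

  |{ non-blank s : x_{s,f} > k · m_f }| / n_nonblank ≥ p

with fold threshold k > 0 and minimum non-blank fraction p ∈ (0, 1].
Two deliberate conventions:

* the intensity comparison is **strict** (`>`), so with an all-zero blank
  mean any positive intensity qualifies — the zero-background edge case is
  well defined and permissive;
* the fraction comparison is `≥` with no rounding of the qualifying count.

Filtering never drops samples; blanks stay in the table so their
separation remains visible in the ordination. A `drop_blanks` switch on
the pipeline removes them just before distance computation when a
blanks-free view is wanted. An empty result (every feature removed) is
returned as such, with the report showing 100% removal — the caller
decides whether that is an error.

## Normalization

* **TIC**: each row divided by its own sum; output rows sum to 1. A
  sample with zero total intensity is an error naming the sample.
* **PQN**: TIC is applied first; the reference spectrum is the
  per-feature **median across all samples** of the TIC-normalized table;
  each sample's dilution factor is the median of quotients x_j / r_j over
  features positive in both the sample and the reference; the TIC row is
  divided by that factor. This is the canonical probabilistic-quotient
  recipe; using all samples for the reference (rather than a designated
  control group) is the standard choice when no QC set is declared.
  Because TIC runs first, PQN is exactly invariant to per-sample dilution.
* **none**: identity, for tables already normalized elsewhere (e.g. by
  internal standards).

## Scaling

Auto-scaling: (x − mean)/sd per feature; Pareto: (x − mean)/√sd. The
standard deviation uses denominator n − 1 everywhere in the package — one
convention, declared once. Constant features cannot be scaled; they become
all-zero columns with a logged warning rather than an error, because
constant features are common in filtered sparse tables and aborting would
block real runs. Stage order is fixed: filter → normalize → scale.

## Dissimilarities

Twenty metrics are registered, delegating to `scipy.spatial.distance`:
braycurtis, euclidean, sqeuclidean, cityblock, chebyshev, canberra,
cosine, correlation, minkowski (p = 3), seuclidean, jensenshannon,
mahalanobis, hamming, jaccard, dice, russellrao, rogerstanimoto,
sokalsneath, yule, matching. Choices within that registry:

* binary metrics (jaccard, dice, russellrao, rogerstanimoto, sokalsneath,
  yule, matching, hamming) operate on presence/absence obtained by
  thresholding at strictly > 0 — presence semantics for intensity tables;
  `matching` is the simple matching distance, i.e. hamming on the
  presence patterns;
* mahalanobis uses the Moore–Penrose pseudo-inverse of the sample
  covariance, since metabolomics tables routinely have p ≫ n and the
  covariance is singular;
* metrics defined for non-negative abundances (braycurtis, jaccard, dice,
  jensenshannon, canberra) emit a warning — not an error — when the table
  contains negative values, which happens after scaling;
* an undefined pair (e.g. Bray-Curtis between two all-zero samples) is an
  error naming the pair.

Every metric is verified in the test suite against an independent
double-loop evaluation of its published formula.

## PCoA and PCA

PCoA: A = −½ D∘D, B = JAJ (J = I − 11ᵀ/n), symmetric eigendecomposition
of B, eigenvalues sorted descending. Coordinates exist only for positive
eigenvalues (threshold 1e-12 relative to the spectral radius);
`proportion_explained` is λ_a / Σλ⁺. Negative eigenvalues from
non-Euclidean metrics are neither embedded nor corrected (no
Lingoes/Cailliez); their absolute sum is reported as
`negative_eigenvalue_mass`, the simplest behavior consistent with
mainstream ordination tools. Eigenvector signs are fixed by making each
vector's largest-magnitude entry positive, so repeated runs are
bit-identical. With tied eigenvalues the axes within the tied block are
rotation-arbitrary; equivalence tests therefore use random
(non-degenerate) tables.

PCA: column-center, thin SVD; scores are U·S, eigenvalues the squared
singular values, proportions relative to total variance. With these
conventions PCoA on Euclidean distances and PCA agree axis-by-axis
(including sign, given the sign rule) to ~1e-10 — the classical
equivalence, checked on 50 random 12×8 tables. The embedding is computed
in closed form by eigendecomposition; no iterative stress minimization is
performed and no stress statistic is reported.

The ordination file uses the block text layout (Eigvals, Proportion
explained, Site, plus empty Species/Biplot/Site-constraints blocks for
interoperability); the written blocks cover the retained axes, while the
in-memory result keeps the full eigenvalue spectrum for diagnostics.

## Synthetic studies

The generator draws log-normal peak areas — the standard model for LC-MS
intensities: skewed, positive, multiplicative noise. Default design: 4
blank runs, 3 groups × 8 samples, 80 contaminant features, 240 biological
features, sparsity 0.3, effect size 4, noise sigma 0.6. Contaminants are
log-normal in blanks and 10× attenuated in biological samples; biological
features are log-normal in samples, 1000× attenuated in blanks (trace
carryover rather than exact zero, so blanks keep a defined TIC after
filtering, as real blanks do), and each biological feature is a marker
for one group (round-robin assignment), where its intensity is multiplied
by the effect size. Sparsity zeroes cells of the biological block
uniformly at random. One `numpy` Generator seeded from the spec governs
every draw, so a spec is a complete recipe for its dataset.

What the generator does **not** emulate: retention-time drift, adducts
and isotopes, correlated features, batch effects, heteroscedastic noise,
or instrument saturation. Passing recovery tests therefore demonstrate
that the pipeline recovers planted blank/group structure under idealized
noise, not performance on any particular real study.

Problem sizes throughout the tests and the acceptance script (28-sample
studies, 20 seeds, 50 equivalence trials, oracle tables up to 50×200)
are chosen as the smallest designs in which the planted structure is
unambiguous while the whole suite stays interactive to run.

## Pipeline and exports

The orchestrated run is deterministic given its config: read → align
(intersection of sample ids, dropped ids reported) → filter → normalize →
scale → distances → PCoA → export. Config precedence is CLI flags over
YAML file over defaults, validated before any I/O. The 3-D scatter export
is a single self-contained HTML file (inline JSON + a small canvas
renderer with drag rotation and per-group show/hide); axis labels carry
the percent of variation explained. The embedded JSON block is the
machine-readable record of exactly what was plotted.

## Known limitations

* No Lingoes/Cailliez correction for negative eigenvalues (diagnostic
  only).
* No internal-standard or batch-effect normalization beyond PQN; bring a
  pre-normalized table and select `none` instead.
* The plain-table dialect is this package's own convention (id column
  named `sample_id`, samples in rows by default); other tools' layouts
  may need the orientation flag.
* Binary metrics on scaled (signed) data binarize at > 0, which is rarely
  meaningful — hence the warning.
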