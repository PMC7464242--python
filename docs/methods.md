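# Methods

This note records the models, conventions and design choices behind
`germdiv`, in the spirit of the methods documentation of statsmodels or
scanpy: what is computed, under which assumptions, and what the
synthetic-data tests do and do not demonstrate.

## Dominant-marker informativeness

Dominant fingerprints score band presence (1) / absence (0) per
accession; heterozygotes are invisible, so all statistics are functions
of band frequencies p = (accessions carrying the band)/(accessions) and
of whole banding patterns, never of allele frequencies.

- **Ib and Rp.** Band informativeness Ib = 1 − 2|0.5 − p| is maximal
  for bands present in half the accessions and zero for fixed or absent
  bands; resolving power Rp sums Ib over a primer's bands.
- **%P, EMR, MI.** Percent polymorphism is 100·PA/TNA; the effective
  multiplex ratio EMR = PA·(PA/TNA) is the number of polymorphic bands
  discounted by the polymorphic fraction; the marker index is PIC·EMR.
- **PIC for dominant assays** has no universally fixed formula. The
  default here is banding-pattern diversity, PIC = 1 − Σ f_i² over the
  distinct multiband patterns a primer produces across accessions
  (f_i = pattern frequencies), computed over all of the primer's bands.
  This is the only common convention compatible with published
  primer-level PIC values near 0.9, which exceed the 0.5 ceiling of the
  per-band heterozygosity 2p(1−p); the per-band mean-heterozygosity
  variant is provided as an option. Whether pattern diversity should be
  computed over all bands or polymorphic bands only is not decidable
  from published tables; all bands is the default because monomorphic
  bands never change the pattern partition.
- **Rounding.** Raw values are retained everywhere; report rendering
  rounds half-up (via `Decimal`): per-primer %P to integer, PIC/RP/
  EMR/MI and column means to two decimals, pooled %P to one decimal.
  The column mean of %P averages the rounded per-primer integers,
  matching how such tables are conventionally printed. The mean number
  of polymorphic bands per primer is quoted at one decimal (85/11 →
  7.7); at two decimals half-up rounding gives 7.73.
- **Empty bands.** Bands absent from every accession are retained and
  counted monomorphic (p = 0): the scoring definition admits them and
  they carry no information either way.

## Similarity, clustering, ordination

- **Coefficients.** Dice 2a/(2a+b+c), Jaccard a/(a+b+c), simple
  matching (a+d)/n. Two all-zero fingerprints have undefined
  Dice/Jaccard support; they are assigned similarity 1 (identical
  absence profiles) and the pair is logged as a warning.
- **Distance transforms.** d = 1 − s by default; d = √(1 − s) is
  offered because it makes Dice dissimilarities Euclidean-embeddable,
  which removes negative eigenvalues in principal coordinates.
- **UPGMA** is implemented directly (O(n³) agglomeration) so that the
  tie rule is pinned: every cluster is keyed by its smallest member
  label in sorted-label order, and among equally close pairs the
  lexicographically smallest key pair merges first; children are
  likewise ordered by key. This makes trees bit-reproducible across
  platforms and input orderings. Node height is half the merge
  distance, so cophenetic distance is twice the height of the lowest
  common ancestor and Newick branch lengths (parent height − child
  height) sum to the cophenetic radius along every root path. The test
  suite checks the implementation against an independent from-scratch
  agglomeration oracle and against scipy's average linkage.
- **Ordination.** "PCA based on a similarity matrix", as popularised by
  the PAST package, is implemented as principal coordinates (Gower
  double-centering of −½D², eigendecomposition, eigenvectors scaled by
  √λ). Negative eigenvalues are reported but their axes dropped, with
  variance proportions over the positive spectrum; scikit-bio's PCoA
  serves as the test oracle. Plain PCA on the raw binary matrix
  (column-centred covariance eigendecomposition, scores + loadings for
  a biplot) is provided as well, since both routes are common and the
  trait biplot requires loadings. All axes are exposed; the choice of
  which pair to plot is the caller's.
- **Heatmap ordering** returns the row and column leaf orders of UPGMA
  dendrograms (Euclidean by default, Dice optional), i.e. the
  permutation a clustered heatmap would display; no rendering is done.

## Barcode alignment statistics and distances

- **Determined vs undetermined.** A cell is determined iff it is
  A/C/G/T; gaps, `N`, `?` and all partial IUPAC ambiguity codes count
  as undetermined. The missing-data percentage is undetermined cells
  over L·N (alignment length × sequences). Site classes use determined
  residues only: constant (≤1 state), parsimony-informative (≥2 states
  each in ≥2 sequences), otherwise variable-uninformative; a column
  with no determined residue is undetermined-only. Base composition
  (AT/GC) pools determined cells of all sequences and is reported as
  proportions to two decimals; site proportions to three, missing
  percent to two.
- **Distances.** p-distance is the mismatch fraction over comparable
  sites; pairwise deletion masks per pair, complete deletion keeps only
  columns determined in every sequence. The Jukes–Cantor correction
  d = −¾ ln(1 − 4p̂/3) assumes equal base frequencies and exchange
  rates and is undefined at p̂ ≥ ¾ (saturation), which raises an error
  listing the offending pairs. Alignments are consumed pre-aligned; no
  block filtering is applied beyond the complete-deletion option.
- **Bootstrap.** Columns are resampled with replacement (same L), the
  distance matrix and UPGMA tree recomputed, and each internal clade of
  the reference tree scored by the percentage of replicates containing
  the same leaf set — support on rooted clades, matching UPGMA's rooted
  output, rather than unrooted bipartitions. Replicates with a
  saturated pair are skipped and the denominator adjusted, with the
  skip count reported. Default 500 replicates; a single seeded numpy
  generator drives the whole run. Majority-rule consensus counts rooted
  clades, keeps those above the threshold (exactly-unanimous at
  threshold 1.0) and adds them greedily in frequency order subject to
  compatibility; the consensus is a topology — its node heights are
  nesting depths, not distances.

## Traits

Two-state morpho-agronomic characters are encoded 0/1 against a
codebook (first-listed state → 0; results are orientation-invariant
because Euclidean distance on binary vectors is √(number of
disagreements)). The bundled eight-cultivar alfalfa table carries 15
two-state traits; its published source titles it with 16 traits but
lists 15, and prints "≥4" for the terminal-leaflet length of three
cultivars although that trait's states are <20/≥20 mm — the codebook
records "≥4" as an alias of the high state and flags it as a
transcription anomaly, so decoding canonicalises those three cells.
The pipeline is Euclidean → UPGMA plus PCA (default, because the
biplot needs loadings) and PCoA of the same distances.

On this bundled table the closest cultivar pair is EGY2–USA7 (3
disagreements), not the two Egyptian cultivars (7); the published
dendrogram showing the Egyptian pair as sisters is therefore not
reproducible from the published 15-trait table itself, and the
acceptance test asserting that sister grouping fails by design rather
than being weakened.

## Synthetic data

- **Band matrices.** Presence is Bernoulli(p) independently per
  accession; defaults emulate the study design the package targets
  (12 accessions, 11 primers, 97 bands of which 12 monomorphic, with
  monomorphic bands fixed at p = 1 and polymorphic frequencies drawn
  uniformly from [0.15, 0.85] — mid-range frequencies typical of
  informative fingerprints). Real fingerprints have correlated bands
  (shared insertion history) and scoring noise; the generator has
  neither, so passing tests demonstrate correctness of the statistics,
  not robustness to scoring error.
- **Alignments.** A uniform-random root sequence evolves down an
  ultrametric tree; each branch of length t substitutes each site with
  probability ¾(1 − e^(−4t/3)) to a uniformly chosen different base —
  exactly the JC69 model the distance estimator assumes, with no rate
  heterogeneity or indels. Optional uniform masking to `N` emulates
  missing data. The default genealogy has 8 leaves and root height
  0.02 substitutions/site with 700 bp, matching the shallow divergence
  and amplicon size of plastid barcodes in a single crop species.
  Parameter-recovery tests (L = 5000, 20 seeds, bias < 3 SE) validate
  estimator consistency under the model, not model adequacy for real
  barcodes.
- **Traits.** Group prototypes differing on a set fraction of traits
  (default 0.5 of 15), cultivars flip each prototype state with
  probability 0.1 — separated enough that UPGMA recovers groups, noisy
  enough to be non-trivial.

Every generator is a pure function of its config including the seed
(numpy `default_rng`); the pipeline writes no wall-clock values into
its output files, so identical config + seed reproduces outputs
byte-for-byte.

## Problem sizes and numerical conventions

Property tests run UPGMA oracle comparisons on ≤5-taxon matrices
(200 random cases), ultrametricity to 1e−9, JC69 recovery at
L ∈ {500, 5000}, and bootstrap checks at 10–120 replicates; these
sizes make the full suite run in seconds while keeping binomial
standard errors small enough for 3·SE assertions. Reported tables
round half-up through `Decimal` to avoid platform-dependent float
formatting of exact ties.

## Known limitations

- Primer-level PIC and Rp printed in published tables cannot be
  verified without the underlying band matrix; only count-derived
  columns (%P, EMR, and MI where PIC×EMR is exact) are reproduced.
- The JC69 model ignores transition/transversion bias, unequal base
  frequencies and rate heterogeneity; for the shallow divergences
  targeted here the correction is nearly linear and model choice is
  largely immaterial.
- Consensus and support are defined for rooted trees only, as produced
  by UPGMA; unrooted bipartition support is out of scope.
- The pipeline emits coordinates, orderings and Newick text; it does
  not render dendrograms, heatmaps or biplots.
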