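# Methods

## Scope and data model

`retinadev` analyses a staged bulk RNA-seq series: a genes × samples
matrix of read counts, per-sample developmental stage in
post-conception weeks (PCW, adult samples last), and a table of splice
junction read counts split into canonical junctions and backsplice
junctions (the diagnostic signature of circular RNAs). All genomic
coordinates are 0-based half-open `[donor, acceptor)`; a backsplice
record has donor < acceptor and its genomic span (acceptor − donor)
proxies circle size.

## Normalisation

Three layers are derived from counts:

* **log₂ CPM** — `log2((c + p) / (L + 2p) × 1e6)` with pseudocount
  p = 1.0 (configurable) and library size L. Used for kurtosis, marker
  panels and rank DE.
* **Quantile-normalised log CPM** — each column's sorted values are
  replaced by the cross-column means of the order statistics; tied
  values within a column receive the mean of the rank-means their run
  spans. Used for sample clustering, where between-sample distribution
  shape differences (which the kurtosis analysis *studies*) must not
  drive the distances.
* **Median-of-ratios size factors** — factor_j = median over
  all-nonzero genes of count_gj / geometric mean_g. Provided for
  count-level normalisation; returned as computed, without rescaling.

Which layer feeds the kurtosis trajectory is configurable
(`layer=`, default `log_cpm`): heterogeneity is a property of the raw
relative-abundance distribution, which quantile normalisation would
erase by construction.

## Expression heterogeneity (kurtosis trajectory)

Per-sample Pearson (non-excess) kurtosis m₄/m₂² with population
moments (denominator n): 3 for a Gaussian, ≥ 1 for any non-degenerate
sample, invariant to affine transforms — so library-size shifts of the
log layer do not affect it. The trajectory statistic is the Pearson
correlation of log₂(kurtosis) against the stage axis with a
t-distribution p-value; a Spearman option makes the result invariant
to monotone relabelling of stages. Adult samples have no PCW; they are
placed at max(PCW) + 20 weeks, far enough above the fetal range to sit
last without dominating leverage. Degenerate (zero-variance) samples
are excluded with a warning.

## Staging: tree, Moran eigenvectors, windows

1. **Distances**: Euclidean, between samples, on the
   quantile-normalised log layer.
2. **Median linkage**: nearest active pair merges; distances to the
   new cluster follow the Lance–Williams update
   ½d(k,i) + ½d(k,j) − ¼d(i,j) applied to the distances *as given* —
   the dialect of the common statistical software implementation. The
   textbook WPGMC variant (update on squared Euclidean distances) is
   available via `squared=True`. Ties break deterministically on the
   smallest representative-leaf pair. Median linkage permits
   inversions (a later merge below an earlier one); nothing downstream
   assumes monotone heights.
3. **Tree cutting** (`cut_tree`): heights are first monotonised by a
   running maximum over children, then the k−1 largest merges are
   undone. The monotonisation makes the undone set an upward-closed
   crown, which is what makes cutting well-defined despite inversions.
4. **Proximity**: patristic distance between leaves is 2 × the merge
   height of their most recent common ancestor; proximity is its
   reciprocal with zero diagonal. Row normalisation is off by default
   (optional flag); duplicate samples (zero patristic distance) are an
   error and must be jittered or merged upstream.
5. **Moran eigenvectors**: the proximity matrix A is double-centred,
   C = (I − 11ᵀ/n) A (I − 11ᵀ/n), and eigen-decomposed. Components
   with |eigenvalue| above 1e−9 × max|eigenvalue| are kept (the
   centring always annihilates the constant vector, so k ≤ n − 1),
   ordered by eigenvalue descending, and each score column is rescaled
   to mean 0 and variance 1 with denominator n (an n−1 option exists).
   Orthogonality of eigenvectors plus centring gives zero pairwise
   correlation by construction. Reproducibility details: each
   eigenvector's sign is fixed so its first nonzero loading is
   positive, and within numerically degenerate eigenvalue blocks
   columns are ordered by the first leaf's loading. `top_k` truncates
   to the leading components when a fixed-size basis is wanted.
6. **Windows**: ordered sign rules — conjunctions of
   (component, low/high), "low" meaning score < 0 — evaluated with
   precedence; the first matching rule labels the sample and an empty
   conjunction acts as catch-all. `derive_window_rules` automates what
   is otherwise read off an ME score plot: cut the tree into k
   clusters, then greedily pick for each cluster the sign conjunction
   (up to 3 conditions over the first 8 MEs) with the best Jaccard
   match among still-unlabelled samples.

## Marker onset and peak detection

Panel expression is the mean of the log layer over the panel's genes
(genes absent from the matrix are dropped with a warning). For each
candidate stage s, a one-sided Wilcoxon rank-sum compares pooled
values at stages < s against stages ≥ s (a candidate-stage-only mode
exists). The rank-sum test uses exact enumeration when the pooled size
is ≤ 12 and no value is shared *between* the samples (within-sample
ties never enter a cross-pair comparison), otherwise the normal
approximation with tie correction.

The onset is the earliest s with p < α (default 0.05) whose increase
is *sustained*: the median of every stage ≥ s exceeds the pre-onset
pooled median by at least `min_increase` log₂ units (default 1, i.e.
2-fold). The margin is the load-bearing design choice here: with the
pure ordering rule (`min_increase=0`) any chance arrangement in which
a run of noise-level stage medians sits above the pooled median of the
stages before them registers as an onset — a ~50% event for the stage
just before a true onset and ~25% two stages before — giving the rule
a systematic early bias. Requiring a 2-fold sustained margin removes
these noise-level onsets while leaving any biologically meaningful
marker induction (typically ≥ 4-fold) untouched. Onset detection is
invariant to adding a constant to all values, and weakly monotone in α.

Peak detection reports the window with maximal median panel
expression (ties go to the earliest window, flagged), with a one-sided
rank-sum against each other window; windows with fewer than two
samples are skipped with a warning.

`rank_de` is deliberately plain two-group DE plumbing: per-gene
two-sided rank-sum on log₂ CPM, log₂ fold change of means,
Benjamini–Hochberg across genes; significant iff q < α and
|log2FC| ≥ `lfc_min`. At group sizes ≤ 8 the exact rank-sum null is
used — with six samples per group the asymptotic p floor (~0.005)
would sit above the BH threshold, making small-n discoveries
structurally impossible.

## circRNA statistics

* **circ:canonical ratio**: total backsplice reads / total canonical
  reads per sample; scale-invariant, so library size cancels.
* **Jonckheere–Terpstra**: J = Σ over ordered group pairs of
  Mann–Whitney counts (ties ½); null mean (N² − Σnᵢ²)/4 and tie-free
  variance [N²(2N+3) − Σnᵢ²(2nᵢ+3)]/72; one-sided p from the normal
  approximation (empirically calibrated at α = 0.05 in the acceptance
  suite), with an optional label-permutation p that also absorbs ties.
* **Trend tests**: the ratio trend runs JT on per-sample ratios
  grouped by window order; the span trend on per-window span lists
  where each circRNA detected in a window (≥ 1 read) contributes its
  span once (presence weighting, so highly expressed circles do not
  dominate; a read-weighted mode exists).
* **circRNA DE** (dual-controlled): adjusted abundance =
  (backsplice/L) ÷ (sample circRNA factor) ÷ (locus expression/L),
  compared between adjacent windows with a two-sided rank-sum and BH.
  The two denominators make the measure invariant to per-sample
  library scaling and to global circRNA-rate shifts — the two stated
  controls. The sample-level factor defaults to the *median* over
  circles detected in both windows of the per-locus
  backsplice:canonical fraction; the plain total-read ratio
  (`ratio_estimator='total'`) coincides with it in genome-scale
  junction sets but is visibly contaminated when a synthetic universe
  of ~150 circles contains tens of regulated ones, which would drag
  every null circle toward significance.
* **circ–linear correlation**: per DE gene, log₂ change of mean gene
  CPM vs log₂ change of mean backsplice CPM between two windows
  (pseudocount 0.5 before log₂); genes under `min_cpm` (default 1
  backsplice read per million) in every sample of both windows are
  excluded and reported.
* **Locus circular fraction**: reads on junctions lying wholly inside
  the circle's `[donor, acceptor)` (backsplice included) over all
  junction reads of the gene; the circle defaults to the gene's most
  abundant backsplice.
* **Conservation**: records are precise when (chrom, donor, acceptor,
  strand) match exactly, overlapping when same-chrom same-strand
  intervals intersect without precise match; each record counts once,
  precise first.

## The synthetic generator

The generator emulates a 4-window series — 4.6–7.2, 7.7–10 and
12–18 PCW plus adult — with three fetal stages per window, one adult
stage, and two replicates per stage (20 samples). Counts are negative
binomial via a gamma–Poisson mixture with shared dispersion 0.1 and
log-normal gene means (median 150, σ_ln = 0.8); library sizes vary
log-normally with CV 0.2 so normalisation is genuinely exercised.
Planted structure, each on its own disjoint gene set:

* **Window signatures**: 300 genes per window at 4-fold in that
  window's samples. Windows in real series differ in a large number of
  moderately changed transcripts; this density is what lets median
  linkage, whose updated heights shrink toward centroid distances,
  separate windows reliably above the replicate noise floor.
* **Marker panels**: seven panels (RGC, horizontal, cone, amacrine,
  rod, bipolar, Müller), five genes each, 8-fold sustained jump at
  staggered onset stages. Transient `peak_panels` (elevated in a
  single window) are available for peak-detection tests.
* **Heterogeneity spikes**: a pool of 2% of genes at 64-fold whose
  per-stage fraction decays linearly to zero, nested (later stages
  spike a subset of earlier stages' pool) — a progenitor programme
  being shut down. The spiked genes carry ~a quarter of the earliest
  libraries, like the top dominant transcripts of a real bulk library,
  and sit several SDs into the log-CPM tail, which is what makes them
  kurtosis rather than variance. Two rejected alternatives are worth
  recording: moderate folds merely inflate variance (kurtosis stays
  flat), and very large folds (~500×) make the spikes eat ~95% of
  early libraries, a compositional artefact that depresses every other
  gene's early log-CPM and corrupts onset detection.
* **circRNAs**: 150 loci with host genes drawn hot (20× the base
  mean — detected circRNA universes are conditioned on junction
  coverage); canonical junction output is 30% of the host's reads
  split over three junctions (two inside the circle, one outside, so
  the locus circular fraction is non-trivial); backsplice counts are
  Poisson with rate = canonical output × per-window global rate
  (0.005 → 0.04, doubling per window) × a log-normal locus multiplier.
  Each circle has a home window — spans drawn log-normal with median
  500 → 1400 by home window — and is silent before it, planting the
  size increase as "new, larger circles arise as development
  proceeds". `SimConfig.null()` switches every planted effect off
  (flat rates, no spikes, no signatures, unit folds, all homes in
  window 1) for calibration runs.

Determinism: all randomness flows through two child generators of the
seed (`[seed, 0]` for the time course, `[seed, 1]` for junctions), so
regenerating junctions does not perturb the count matrix, and repeated
runs are byte-identical on disk.

What the generator does **not** emulate: gene–gene correlation
structure, smooth developmental gradients within windows (windows are
blocky by construction), isoform/GC/length biases, batch effects,
discreteness artefacts of very shallow libraries, and real splice
graph geometry (every locus has at most one circle, coordinates live
on a fictional chromosome `chrS`). Passing recovery tests therefore
demonstrate that the estimators see the structure they were built for
at realistic noise levels — not that they are robust to every failure
mode of real library preparation.

## Numerical and edge-case conventions

* Eigen tolerance 1e−9 (relative) for component retention; basis
  contract checked to 1e−8.
* Exact vs asymptotic rank-sum switch at pooled n ≤ 12 (single tests)
  and group size ≤ 8 (vectorised DE).
* JT ties contribute ½ to J; the analytic variance is the tie-free
  form, permutation mode covers heavy ties.
* BH q-values via the standard step-up; q is monotone in p.
* Proportions must sum to 1 within 1e−12; negative counts, duplicate
  ids, non-symmetric matrices, zero libraries and empty groups raise
  typed errors (`ValidationError` → CLI exit 2, `PreconditionError` →
  exit 3).
* Window order is defined by mean stage index of member samples.

## Known limitations

* Median linkage heights are not monotone and are a poor "scale" for
  the tree; windows should be read from the ME sign structure (as the
  pipeline does), not from merge heights.
* The automatic rule derivation assumes the windows are tree clades;
  heavily interleaved designs would need hand-written rules.
* The circRNA DE test is rank-based on a per-circle adjusted
  abundance; it does not model count overdispersion explicitly and
  has no power below ~10 backsplice reads per sample at these group
  sizes.
* With two samples per stage, onset resolution is inherently ±1 stage
  around weak inductions; the acceptance suite quantifies this on the
  generator's conditions only.
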