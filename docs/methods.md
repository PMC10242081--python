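# Methods

## Dosage-aware allele-specific expression

Endosperm arises from a fertilised triploid central cell (2m:1p), so the
null for an unbiased gene is a maternal read fraction f₀ = 2/3 rather
than 1/2.  For each gene the maternal (m) and paternal (p)
allele-assigned reads are pooled over the nuclei of interest and tested
with an **exact two-sided binomial test** at success probability f₀.  The
two-sided p-value is the minimum-likelihood definition — the sum of
probabilities of all outcomes no more likely than the observed one — with
tail-doubling available by flag.  This makes the test exact at any read
depth and exactly symmetric under allele swap (swapping m↔p and
f₀↔1−f₀ leaves every p-value unchanged).  p-values are BH-adjusted across
assessed genes; calls are MEG (maternal fraction above f₀) or PEG (below)
at q ≤ α = 0.05.

Because m | (m+p) is exactly binomial conditional on the informative-read
total — overdispersion of expression does not propagate into the allelic
fraction when reads are assigned independently — the pooled binomial test
is exactly calibrated under the simulator's model.  Real data can carry
extra between-nucleus allelic heterogeneity; the pooled test is the
simplest defensible default, and interpretation should note that very
deep genes can reach significance at biologically small deviations.  A
beta-binomial variant (``overdispersion`` > 0 sets the intra-class
correlation of the beta mixing distribution) is available for such data
and widens p-values relative to the binomial.

**Assessability.** Genes with fewer than `min_reads = 20` pooled
informative reads or fewer than `min_nuclei = 5` contributing nuclei are
`not_assessed` and carry no p/q.  These thresholds are free parameters,
not derived quantities; at the simulator's default depth (~10⁴ reads per
nucleus, 10⁴ genes, 20% of reads allele-assignable) roughly 70% of genes
are assessable, while shallower real libraries assess far fewer.
Strength bins for calls are fraction-based: MEG strong ≥ 0.95,
intermediate [0.85, 0.95), weak below; PEGs mirrored at ≤ 0.05 / ≤ 0.15.
The three-bin scheme is standard; the cut points are package defaults
exposed in the API.

**Discreteness.** The exact test is conservative: at 60 reads and
f₀ = 2/3 the oracle rejection probability at p < 0.05 is 0.0389, not
0.05.  The calibration test asserts the empirical rate against this exact
oracle, not against the nominal level.

## Five-pattern and heterosis-mode classification

Let LP ≤ HP be the order statistics of the two parents' mean expression
and k > 1 the fold factor (default 3).  The five classes partition
f1 ∈ (0, ∞) totally and disjointly:

| class | region |
|---|---|
| BLP | f1 < LP/k |
| BMP | LP/k ≤ f1 < LP |
| MPV | LP ≤ f1 ≤ HP |
| OMP | HP < f1 < k·HP |
| OHP | f1 ≥ k·HP |

This is the unique ordering-consistent partition for LP ≤ HP; boundary
assignment follows the half-open conventions above.  Classification uses
point estimates (mean CPM) and is applied to genes already significant in
a pairwise comparison; it is scale-invariant and invariant to which named
parent is the higher one.

**Composition normalisation.**  CPM is compositional: a handful of
strongly induced genes inflate a sample's total counts and deflate every
other gene's CPM, biasing all between-sample ratios.  Before fold
changes, pattern assembly and mode tests, samples are put on a common
scale with **median-of-ratios factors** (geometric-mean reference over
genes expressed in all samples; per-sample factor = median reference/
sample ratio) — the same normalisation idea used by standard count-based
DE tools.  Identical samples get factor 1, so the correction is inert
when unnecessary.

**Modes.**  With per-nucleus scaled CPM for F1, P1 and P2:
F1-vs-P1, F1-vs-P2 and P1-vs-P2 use two-sided Wilcoxon rank-sum tests;
F1-vs-midparent uses a Welch-type z statistic on means,
z = (mean(F1) − MP) / √(SE_F1² + (SE_P1² + SE_P2²)/4), with
MP = (mean(P1)+mean(P2))/2.  A rank test against parent values pooled
after rescaling was considered and rejected: rescaled parent
distributions differ from F1 in shape even when the means agree, so a
rank test rejects true additivity on shape alone; additivity is a
statement about means, and the z test is calibrated for it.  Decision
rules: *overdominant* — F1 differs from both parents and its mean lies
outside the parental range (transgression below the low parent is
included); *additive* — parents differ, F1 differs from both, lies
between them and does not differ from MP; *dominant* — parents differ
and F1 matches exactly one of them; otherwise *unclassified*.

**DEGs.**  Pairwise differential expression uses fold change of
(mean scaled CPM + 1) with threshold 1.5 and a two-sided Wilcoxon
rank-sum test (normal approximation with tie correction — the convention
of the single-cell tool family) with BH FDR per group; per-cluster
comparisons with fewer than 3 nuclei on either side are skipped with a
warning, and a pooled `all` group is always evaluated.

## QC, normalisation, clustering, markers

* Cell filter first (keep nuclei detecting ≥ 3,000 genes — "fewer than"
  is strict), then gene filter on the survivors (keep genes detected in
  ≥ 5 remaining nuclei).  The sequential order matters and is tested.
* Normalisation: CPM per nucleus, stored as log10(CPM+1).
* HVG: "vst"-flavour ranking on **raw counts** — a quadratic fit of
  log₁₀ variance on log₁₀ mean supplies the expected SD at each gene's
  mean; counts are standardised, clipped at |z| = 10, and genes ranked by
  the variance of the clipped z-scores (deterministic index tie-break).
  Ranking on the log-normalised layer was markedly worse at recovering
  planted cluster programs and is not used.
* PCA: per-gene z-scored (clipped at 10) HVG expression, exact SVD, sign
  fixed so each component's largest-magnitude loading is positive.
* Clustering: k = 20 nearest neighbours (self included), SNN edge weights
  by Jaccard overlap of neighbour sets, pruning below 1/15, Leiden
  maximisation of resolution-scaled modularity (resolution 0.4, fixed
  seed), labels relabelled by decreasing size.  In the vanishing-
  resolution limit a connected graph collapses to one community;
  disconnected components never merge (they share no edges), which is the
  expected behaviour of graph-based modularity clustering.
* Markers: cluster-vs-rest Wilcoxon on the normalised layer for genes
  detected in ≥ 10% of either group with |log2FC| ≥ 0.58 (log2FC from
  mean back-transformed CPM with pseudo-count 1); BH within cluster;
  `specific` flags log2FC > 0.25 with out-of-cluster detection < 10%.

Without cross-sample integration (deliberately out of scope), joint
clustering of the trio can split clusters by sample when between-sample
divergence rivals between-cluster divergence; the pipeline's heterosis
stage then falls back to the pooled `all` comparison, mirroring how
undersized groups are skipped.

## Enrichment

Exact hypergeometric upper tail P(X ≥ m) for universe N, term size M,
query size n, overlap m, evaluated via log-gamma binomial coefficients
(stable at genome scale); m = 0 returns 1.  BH step-up FDR with
monotonicity enforcement.  Thresholding BH q-values at α is equivalent to
the classical step-up rule, so a second adjustment is never needed —
note that literally re-running the adjustment on its own output is *not*
a no-op (q-values are not p-values), which is why the equivalence is
stated this way.  The universe defaults to all annotated genes and can be
overridden (e.g. to the expressed set); the background choice materially
changes results.

## The simulator

`simulate_trio` draws, per nucleus, a library size
L ~ LogNormal(9.2, 0.35) (median ≈ 10⁴ counts) and per gene a count
NB(mean = L·π, dispersion φ = 0.3; variance μ + φμ²) with π a normalised
expression program.  Components:

* **Baseline abundances** ~ Gamma(shape 0.45), chosen so the median
  nucleus detects ≈ 3,600 of 10,000 genes and ~90% of nuclei survive the
  3,000-gene filter — the retention regime of a typical snRNA-seq study.
  Real libraries' depth/dispersion are not published at this granularity;
  these are order-of-magnitude realism choices, fixed once.
* **Clusters**: 5 equiprobable clusters shared by all samples; 10% of
  genes form cluster programs (×2² in the home cluster), drawn from genes
  above the 30th abundance percentile because real marker programs are
  expressed genes.
* **Allelic structure** (hybrid only): allele-informative reads
  s ~ Binom(count, ρ = 0.2) — binomial thinning for "only SNP-overlapping
  reads are assignable" — then maternal ~ Binom(s, f_g) with f_g = 2/3
  baseline, 0.95 for 200 planted MEGs, 0.20 for 200 planted PEGs.
  Conservation maternal + paternal ≤ count holds cell-wise by
  construction.
* **Pattern/mode genes**: parents at 1× and 4× (which parent is high is
  randomised per gene), hybrid at class targets placed at the geometric
  midpoint of each five-pattern region (BLP LP/6, BMP ≈ 0.58 LP, MPV
  2 LP, OMP ≈ 6.9 LP, OHP 24 LP) and, for modes, at the arithmetic
  mid-parent (additive), the higher parent (dominant) and 6×HP
  (overdominant); 100 genes per class.  Planted genes come from the
  50th–90th abundance percentile band and carry a per-class abundance
  rescale so no class dominates library composition (patterns are
  scale-invariant, so this is inert for classification).  A construction
  invariant asserts that the noiseless means classify to their intended
  regions before any sampling.
* **Determinism**: one `numpy` Generator seeded from the config; the same
  seed gives bit-identical matrices and ground truth.

**What the simulator does not emulate** — ambient RNA, doublets,
maternal-tissue contamination, batch/chemistry effects, UMI saturation,
cis-regulatory divergence between subspecies alleles, or reciprocal-cross
designs.  Passing recovery tests therefore demonstrates correctness of
the algorithms under the stated generative model, not performance on any
real library.

## Pipeline

`endoase run` executes simulate → qc → cluster → markers → ase →
heterosis → enrich, one subdirectory of TSVs per stage plus a JSON
manifest (config + hash, seed, stage wall times, input hashes in real
mode, package version).  Stages reload their inputs from disk, so subsets
can be re-run (`--stages ase,heterosis`).  Everything is single-process
and deterministic: reruns at a fixed seed are byte-identical, which the
test suite asserts at full scale (3 × 1,000 nuclei × 10,000 genes).

## Numerical and design notes

* Matrix Market indices are 1-based on disk, 0-based in memory; the
  on-disk genes × barcodes orientation is transposed on read; duplicate
  coordinate entries are summed; gzipped inputs and 10x-style feature
  files (extra tab-separated columns) are accepted.
* The QC test fixture is a hand-built 12-nucleus × 3,408-gene matrix in
  which the default thresholds remove exactly 2 nuclei and 3 tracked
  genes; with only 6 nuclei no gene could survive a 5-cell filter after
  removing 2, so a larger fixture is the smallest coherent construction.
* Rank-sum p-values use the normal approximation with tie correction;
  fully tied columns return p = 1.  The ASE binomial test and the
  hypergeometric test are exact everywhere.
* Result tables are TSV with ≥ 6 significant digits and documented sort
  keys; floats round-trip to within half an ulp of the sixth digit.
* All α/FDR thresholds default to 0.05; fold thresholds: marker log2FC
  0.58 (1.5-fold), DEG fold 1.5, pattern factor k = 3 — all exposed in
  `PipelineConfig`.
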