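# Methods

`preneo-atlas` models the progression of pancreatic tissue through three
disease stages — normal pancreas (Normal), preneoplastic lesions (PRE) and
pancreatic ductal adenocarcinoma (PDAC) — and provides every analysis stage
needed to characterise that progression from transcriptomic data: quality
control and clustering of single-cell counts, stage-pair differential
expression with persistent-dysregulation calls, copy-number-based
malignancy inference and malignant-preneoplastic cluster designation,
pseudotime ordering, immune abundance networks, ligand–receptor crosstalk
scoring, bulk consensus subtyping, and a signature-reversal drug screen.
Because the real cohorts behind such an atlas are hundreds of thousands of
cells across many repositories, the package ships a synthetic-cohort
generator whose planted structure makes every stage verifiable end to end
on a laptop.

## The synthetic cohort

Counts are negative binomial: cell *c*, gene *g* has mean
`s_c · exp(λ_{t(c),g}) · d_{c,g} · b_{batch(c),g}` and shared dispersion
0.3 (`1/size = 0.3`), where `λ` is the log-space program of the cell's
(type, stage, malignancy) combination, `s_c` a lognormal cell-size factor
(log-SD 0.2), `d` the copy-number dosage multiplier and `b` a mild
per-batch gene multiplier (log-SD 0.1, four batches). The default genome
has 2 000 genes on 10 pseudo-chromosomes with unit-spaced starts; planted
marker, program, persistent and ligand–receptor genes are scattered across
the non-CNV chromosomes by a fixed layout permutation, so that isolated
planted genes do not mimic a contiguous copy-number segment under
positional smoothing.

Planted structure, with defaults and the reasoning behind them:

* **Composition.** Per-stage cell-type proportions follow the atlas
  dynamics: immune 69.5 / 15.7 / 54.3 % of cells in Normal / PRE / PDAC,
  ductal + acinar 19.2 / 68.6 / 21.4 % (acinar-dominant in PRE), and
  macrophages 0.6 / 19.3 / 20.9 % of immune cells. Finer splits (B,
  plasma, CD4 and CD8 T, NKT) are package choices. Each stage has 30
  samples of ~50 cells (1 500 cells per stage); the macrophage and NKT
  fractions share a fixed pool whose split is jittered per sample
  (mean-one lognormal, log-SD 0.7), the planted anti-correlated pair.
* **Persistent genes.** 40 up and 40 down, fold 2 per stage transition,
  on a 2× elevated baseline so the down direction stays detectable at
  PDAC depth.
* **Malignancy.** 80 % of PDAC ductal cells are malignant: a 150-gene
  expression program at fold 3 plus dosage segments (chr1 ×2 gain, chr3
  and chr5 ×0.5 losses — count-balanced so the planted dosage does not
  shift library sizes). Malignant-PRE cells (18 % of PRE ductal, 15 % of
  PRE acinar) mix the malignant and their own program with weight
  α = 0.6 in log space and carry segment log-multipliers attenuated by
  0.5. These settings put the malignant-PRE mean-expression correlation
  with the malignant profile near 0.93 while normal-PRE clusters stay
  near 0.55–0.67, and keep the PRE/NOR ductal mixture fold below the
  0.5 log2 DE threshold so program genes are not mis-called persistent.
* **Crosstalk.** 30 ligand–receptor pairs at low baseline expression;
  five channels are active with stage-doubling intensity
  (macrophage ligand, ductal receptor), five are constitutively active,
  the rest silent.
* **Bulk.** 77 / 72 / 84 samples (Normal / PRE / PDAC) in four batches
  with additive per-gene shifts (SD 0.5). Four subtypes are archetype
  activation blocks (+2 log2 on a quarter of the LR genes); each sample
  mixes in the other archetypes with uniform loadings up to 0.55 and
  carries Gaussian noise (SD 0.9). The continuous mixing models
  within-subtype tissue heterogeneity and is what makes coarse
  consensus merges genuinely ambiguous, so that cluster-number selection
  has something to discriminate.
* **Perturbagens.** 100 compounds × 3 replicate z-score profiles;
  5 planted reversers are anti-correlated (r = −0.9) with a designated
  query signature, the rest are independent noise.

All randomness flows from one root seed through named substreams
(`cells`, `bulk`, `reference`), so each component can be regenerated
independently and byte-identically.

What the generator does **not** emulate: ambient RNA, doublets, chemistry
batch effects beyond multiplicative shifts, branching trajectories,
receptor complexes with co-factors, and the gene-gene correlation fabric
of real tissue. Passing tests therefore demonstrate that the algorithms
recover the planted effects under overdispersed counting noise at
realistic compositional imbalance — not that they would meet the same
numbers on real cohorts.

## Stage algorithms and numerical choices

**QC and normalisation.** Cells are retained with detected genes in the
inclusive band [200, 5000] and mitochondrial fraction strictly below 10 %
("ranging from" is read as inclusive, "less than" as strict).
Normalisation is `ln(1 + 10⁴·c/T)`.

**HVGs.** A quadratic trend of log10 variance on log10 mean over raw
counts; genes ranked by the variance of trend-standardised counts clipped
at √n_cells; ties break by gene identifier.

**DE.** Wilcoxon rank-sum with the expressing-fraction filter applied to
the higher-expressing group and |log2FC| > 0.5 on de-logged normalised
means (ε = 10⁻⁹). Groups of ≤8 cells use the exact permutation
distribution (two-sided p as twice the smaller tail); larger groups the
tie-corrected normal approximation. The default multiple-testing
correction is Bonferroni over **all** genes in the matrix, the convention
of the standard single-cell toolchain; BH restricted to tested genes is
available but anticonservative here, because the fold-change pre-filter
selects noise-shifted genes and a single spurious small-group call can
complete a persistent triple.

**Persistence.** A gene is persistently dysregulated when it appears with
the same direction in all three contrast unions (PRE/NOR, PDA/PRE,
PDA/NOR) pooled over cell types; genes appearing in both directions
(through different cell types) are dropped and reported.

**Clustering.** Deterministic PCA (eigendecomposition of the smaller Gram
matrix, sign-fixed loadings) on scaled, clipped HVGs, optionally with
per-batch mean-centering; kNN (k = 20) → shared-nearest-neighbour Jaccard
weights pruned at 1/15 → modularity community detection (Leiden optimiser
with explicit seed) at resolution 0.9.

**CNV.** Per-gene log2 ratio to the reference-population mean
(pseudocount 1, clip ±3) in genomic order, 51-gene centred moving average
truncated at chromosome ends, denoising by zeroing values within one
reference-residual SD of zero, per-cell median re-centering. Burden is the
mean squared profile deviation; malignant ⇔ burden above the reference
mean + 3 SD, restricted to PDAC-stage cells. Preneoplastic subclusters
(> 50 % PRE cells, strict) whose mean log-normalised expression profile
over the HVGs correlates with the malignant mean profile above r = 0.75
(strict) are malignant-PRE; correlation on CNV profiles is available as an
option since "expression profile" is ambiguous in the source design.

**Pseudotime.** A deliberate simplification of tree-based trajectory
embedding: ordering genes by expression filters (≥10 cells, mean ≥ 0.1,
both inclusive) plus cluster-wise Kruskal–Wallis (BH q < 0.01); 2-D PCA;
minimum spanning tree over cluster centroids; pseudotime is the geodesic
coordinate of each cell's projection onto its nearest tree edge,
normalised to [0, 1]. The root is the cluster richest in non-malignant
PRE cells. Trajectories are inferred per lineage (ductal, acinar): the
two lineages are transcriptionally distant, and a joint tree would place
one lineage's root mid-path of the other.

**Abundance networks.** Sample-wise immune-subtype fractions per stage;
Spearman correlations across samples; edges classed positive (ρ > 0.5),
negative (ρ < −0.5) or weak. Correlating across samples (rather than
between cell-type centroids) is this package's reading of the design.

**Crosstalk.** P = L·R/(0.5 + L·R) with L, R the 25 %-truncated means of
log-normalised ligand/receptor expression in sender/receiver groups
(≥10 cells each); Hill coefficient 1. Significance by shuffling the
sender/receiver split (add-one rule, default 100 permutations). Stage
totals sum P over significant pairs.

**Consensus subtyping.** Monti resampling: 450 iterations, 80 % sample
subsampling, average-linkage hierarchical clustering of 1 − Pearson on
gene-median-centred expression (centering focuses the correlation on
deviation structure; it is the standard pre-processing of the reference
implementation). k ∈ 2..8 chosen by minimal PAC over (0.1, 0.9), ties to
the smaller k; final labels from hierarchical clustering of
1 − consensus.

**Subtype DE and signatures.** One-vs-rest Welch t-tests with BH (a
documented simplification of moderated linear models; at ≥20 samples per
group moderation changes little). Query signatures keep genes with BH
p < 0.05 and |log2FC| strictly > 0.15, capped at the top 200 per
direction; a side below 5 genes excludes the signature (recorded, not
raised).

**Reversal screen.** Weighted-KS enrichment: hits advance the running sum
by |z|^1 normalised over hits, misses retreat by 1/(N − n); ES is the
extremum of largest magnitude, with magnitude ties resolved to the
extremum reached earlier in the ranked walk. WTCS = (ES_up − ES_down)/2
when the two disagree in sign, else 0; NCS normalises WTCS by the mean
|WTCS| of same-sign scores within a reference annotation group; the
perturbagen score is the mean NCS over replicates with the minimum
permutation p across replicates (1 000 random disjoint gene-set pairs of
matched sizes; the same random sets are reused across profiles as common
random numbers, which leaves each p-value marginally valid). Perturbagens
with mean NCS < 0 are retained and ranked by (p, mean NCS, name).

## Problem sizes

Defaults were chosen so a full pipeline run (4 500 cells × 2 000 genes,
233 bulk samples, 300 reference profiles) completes in well under a
minute on one CPU and the whole verification suite in a few minutes,
while keeping per-sample immune counts large enough for sample-wise
correlation networks.

## Known limitations

* The PAC minimum discriminates the planted number of subtypes only when
  within-subtype heterogeneity makes coarse merges unstable; on noiseless
  block data every k ≤ k_true is perfectly stable and the tie rule
  returns the smallest k.
* Malignancy calling presumes the reference population (B cells) is
  copy-number neutral; a contaminated reference shifts the burden
  threshold.
* The trajectory is one-dimensional by construction; branching topologies
  are out of scope.
* Ligand–receptor scoring is strictly pairwise; multi-subunit receptor
  complexes and antagonists are not modelled.
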