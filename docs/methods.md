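# Methods

## Scope and model of the data

The package analyses pooled knockout screens read out by droplet
single-cell RNA-seq with direct sgRNA capture. Each droplet yields a gene
UMI vector and an sgRNA UMI vector; each infecting vector carries two
guides against one gene (or two non-targeting controls, NTC). The analysis
unit is the *singlet*: a cell whose detected guides all target one gene.
All perturbation effects are expressed relative to the NTC population.

## Guide detection and singlet calling

Droplets need more than one sgRNA UMI in total to be assignable
(`min_total_umi = 2`). Within an assignable droplet a guide is detected
when its UMI count is ≥ 2, or ≥ 1 **and** ≥ 10% of the droplet's top guide
(the *dominance rule*). Direct-capture libraries always carry ambient
guide molecules; the dominance rule removes single-molecule strays next to
a strongly captured guide while keeping genuinely co-captured pairs. Both
thresholds are configurable; disabling the rule can only increase the
multi-gene discard count (tested as a monotonicity property). Cells whose
two detected guides target the same gene from different constructs remain
singlets — gene-level analyses need the target, not the vector.

Expression QC keeps cells with mitochondrial fraction < 10% (prefix
`mt-`), detected features < 6,000 and total UMIs < 60,000, all strict
inequalities, with per-filter removal counts reported.

## Differential expression

For each retained perturbation (≥ 48 singlets; below that the target is
excluded with an explicit flag) every gene is compared against NTC
singlets with the two-sided Wilcoxon rank-sum test: exact enumeration of
all C(n+m, n) rank splits when n + m ≤ 12, otherwise the tie-corrected
normal approximation with a 0.5 continuity correction. The exactness
threshold is a package decision — the test's regime is rarely stated in
practice — chosen so toy examples are exact and screen-scale calls are
fast. log2 fold-changes compare de-logged means of log-CPM expression
(`ln(1 + c/C × 10⁶)`) with an ε = 1e-9 guard so 0/0 is defined. FDR is
Benjamini–Hochberg within each table (step-up, ties broken by input order
after a stable sort).

## The perturbation map

The effect matrix holds panel-gene × perturbation log2 fold-changes, NTC
never being a column. Gene programmes cluster rows by 1 − Pearson
correlation, TF modules cluster columns by 1 − Spearman correlation, both
with average linkage (UPGMA) — the standard, noise-stable choice for
correlation distances; the linkage was an open design point and is
recorded in the partition objects. Constant rows/columns get the
zero-correlation convention (distance 1 to everything, warned). The
primary API takes explicit cluster counts; an automatic mode cuts the
dendrogram at the highest-silhouette K over a configured range.

Module→programme strength is the mean over a module's perturbations of the
mean log2FC of a programme's genes. TF→TF edges exist when the source's DE
table moves the target TF's gene past |log2FC| > 0.5 (no FDR gate by
default — an optional gate is available); the sign is −sign(log2FC) under
the knockout convention. Connectivity between modules divides the directed
edge count by the product of module sizes (|i|·(|i|−1) on the diagonal),
giving an edge density bounded in [0, 1]; a sum-normalized variant is
available by flag. Hubs rank module members by the number of genes altered
past the threshold, ties by total |log2FC| then lexicographically.

## Abundance and state statistics

Perturbation abundance is log2 of per-sgRNA cell yield versus the NTC
per-sgRNA yield — dividing each side by its guide count is what makes a
4-guide gene comparable to an 80-guide NTC pool. A default pseudocount of
1 on cell counts keeps fully depleted targets finite; results at c = 0 are
also available. State enrichment compares a target's frequency inside one
state against the complement (or one other state, pairwise; antisymmetric
by construction).

Signature scores use expression-matched binned controls: genes are binned
into 24 equal-frequency bins of mean expression and each signature gene is
compared with 100 same-bin draws; the per-cell score is mean(signature) −
mean(controls). State gating is a deterministic surrogate for
cluster-and-inspect annotation: Tox-negative cells are excluded, the
Tcf7-vs-Havcr2 margin splits precursor from terminal exhaustion, and Mki67
splits each into quiescent/proliferative (Tpex1/Tpex2, Tex2/Tex1).
Thresholds default to per-gene medians and should be set explicitly when
the marker distribution is not balanced.

## Bulk interaction screens

"Normalization against median read counts" is implemented as
median-of-ratios to a geometric-mean pseudo-reference (zero-containing
rows excluded from the median) — the robust estimator standard for count
screens; a plain median-count scaling is available by flag. Gene log2
fold-changes are means of sgRNA lfcs (pseudocount 1), centered by the
median NTC sgRNA lfc. FC/FC nomination has two rule variants:
*strict-order* (lfc_pert < −1 and lfc_pert < lfc_ctrl < 1) and *window*
(lfc_pert < −1 and −1 < lfc_ctrl < 1); a screen's parameters are
intersected with per-parameter provenance retained.

## Library design

A TF is flagged per dataset when |log2FC| > 0.5 and FDR < 0.05 (DE and
chromatin accessibility) or OR > 1.5 and FDR < 0.05 (motif enrichment) —
all strict — and nominated when ≥ 2 of 3 channels flag it. Ranking is by
the number of nominating datasets, ties by total |lfc| evidence then
lexicographic (no tie rule is standard; this one is deterministic). The
final list is the ranked top-N merged with a curated list, overlaps
counted once as "ranked". Control regions for the motif test are sampled
uniformly (seeded, without replacement) from regions with |log2FC| < 0.05
and FDR > 0.5 — "unchanged" is read as bounded both ways; the literal
one-sided reading is a flag.

## The synthetic-data generator

`simulate_screen` draws: cell state ~ planted prevalences; target ~
planted abundance profile; expression ~ NegBin(mean = L·μ_g·2^E·state
multiplier, dispersion θ) with lognormal library factors L; captured
guides ~ Poisson(λ_true = 15) and every guide ~ Poisson(λ_background);
doublets carry a second construct; a fraction of cells fail capture.
Effects are multiplicative on the mean, so the DE log2FC estimand equals
the planted E directly, making parameter recovery a clean test surface.

Two identifiability points shaped the planted structures:

* **Compositional shift.** Per-cell normalization measures *relative*
  expression: if a perturbation scales many genes in one direction, the
  library total moves and every gene's normalized value shifts by
  −log2(total ratio). A module whose effect is uniform across the whole
  panel is therefore invisible after normalization. Planted module
  signatures are sum-zero sign patterns over programmes (modules
  *redirect* expression), and calibration fixtures embed the panel in an
  unaffected background transcriptome, as in real cells where a panel is
  a small fraction of the library. The residual ≈ 0.1–0.2 offset visible
  on null programme cells in recovered strengths is this shift.
* **Marker dropout.** Gate-based state labels degrade when a "low" marker
  mode still yields occasional counts; planted states use clearly bimodal
  markers so gating tests logic rather than imputation.

The generator emulates the statistical structure of a screen — counting
noise, capture noise, planted effect geometry — not the biology of any
particular system: passing recovery tests shows the estimators invert the
generative model at realistic sizes, not that real-data conclusions are
correct.

### Packaged fixtures (seeds pinned in YAML)

* `abundance_v1` — 180 targets, 24,000 cells, seed 101; eight targets at
  8% of normal abundance (expected ≈ 8 singlets, far below the 48-cell
  filter), the rest ≈ 95–100 singlets (far above); NTC weight equivalent
  to 24 targets (≈ 12% of singlets); λ_background = 0.0005/guide (≈ 0.4
  ambient UMI/cell), doublet rate 8%, capture failure 12%, 3% dead cells
  at 8× mitochondrial load. With these margins the retained-perturbation
  count is stable across seeds, and at the pinned seed it is exact.
* `truth_v1` — 9 modules × 5 targets, 4 programmes × 30 genes, effect
  ±1 log2, 6,500 cells, noiseless capture, seeds 201–205. Sized so each
  target keeps ≈ 100–120 singlets against ≈ 1,100 NTC cells; five seeds
  run in well under a minute each.
* `candidates_v1` — 220-TF universe (the 180 library targets plus 40
  extras); every library target except the nine curated TFs is nominated
  in 1–4 datasets, curated and extra TFs never reach two channels.

## Numerical conventions

Fisher's exact test reports the sample odds ratio ad/bc, with the
Haldane–Anscombe 0.5 correction (flagged by a warning) only when a zero
cell makes the ratio undefined; the two-sided p sums hypergeometric
probabilities ≤ the observed table's. Effect matrices must be finite;
genes missing from a DE table are filled with 0 and warned. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
the pipeline fans one global seed into per-stage seeds by stable hashing.

## Known limitations

No expression-based doublet detection or ambient-RNA correction; no
graph-based cell clustering, UMAP, pseudotime or running-sum GSEA (their
outputs are consumed as inputs where needed); no guide design or motif
scanning (manifests and hit matrices are inputs); abundance ratios carry
no significance test. The state-gating surrogate reproduces annotation
logic, not the cluster-then-inspect procedure it stands in for.
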