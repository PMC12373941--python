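# Methods

## Scientific setting

Placentation across eutherian mammals ranges from non-invasive
(epitheliochorial: cow, pig, horse) to deeply invasive (hemochorial: human,
mouse), and this variation is graded by an ordinal *placental invasion
index* taking values 0–3. The ELI (Evolved Levels of Invasibility)
framework holds that endometrial stromal fibroblasts (ESFs) of
epitheliochorial species evolved resistance to trophoblast invasion, with a
correlated systemic effect on cancer invasibility. This package implements
the computational chain that turns that comparative signal into candidate
stromal vulnerability genes and quantifies their downstream consequences:

1. **ELI scoring** — per-gene correlation of cross-species ESF expression
   with the invasion index.
2. **Candidate set construction** — intersection of high-scoring genes with
   decidualization pathway sets (prostaglandin biosynthesis, cAMP/PKA
   signaling, progesterone signaling), yielding an ELI-D1-style set.
3. **Stage-transition enrichment** — a from-scratch GSEA of that set on
   tumor cohorts stratified by stage, including a fibroblast/CAF-restricted
   pseudobulk path for single-cell cohorts.
4. **TFBS copy-number regression** — PWM scanning of promoter windows per
   species and OLS of expression on binding-site copy number, per
   (TF, gene), to nominate regulators of the candidate set.
5. **Invasion-front profiling** — per-position invasion depth, depth
   histograms and deep-fork counts from scratch-assay masks, with
   replicate-level condition comparisons.

## Models and procedures

### ELI score

The ELI score of gene *g* is corr(x_g, I) across species, where x_g is log2
expression and I the invasion index. The default is Spearman rank
correlation: the phenotype is ordinal with only four levels, so a rank
statistic is the natural choice; Pearson is selectable via `method=`.
Zero-variance genes are flagged degenerate (score 0, p 1) rather than
dropped. Selection uses a strict `score > threshold` inequality with
threshold 0.5 by default.

P-values: for up to 8 species the two-sided p comes from the exact
permutation null — all n! relabelings of the index ranks, evaluated for all
genes at once as a single centered matrix product (valid because the null
statistic depends only on the two fixed rank multisets). Above that, the
usual t approximation with n−2 degrees of freedom is used. The score itself
(what selection and ranking use) is exact at any n.

No phylogenetic correction is applied: correlations treat species as
exchangeable. A generalized-least-squares extension over a species tree is
a documented extension point, not implemented.

### Candidate set (ELI-D1 style)

Selected ELI genes are intersected with the union of the decidual pathway
sets; a gene in several pathways counts once in the set but once per
pathway in the overlap table (so per-pathway counts need not sum to the set
size). Matching is exact on upper-cased symbols, with an optional alias-map
hook; cross-species orthology resolution is out of scope. Genes missing
from the decidualization fold-change table are annotated as missing, never
silently dropped.

### GSEA engine

Genes are ranked by a later-vs-earlier stage metric (positive = up in the
later stage). Default is the classic signal-to-noise statistic
(μ₂−μ₁)/(σ₂+σ₁) with each σ floored at 0.2·|μ|; log2 fold change and Welch
t are selectable. Ties (including all-zero degenerate rankings) break
lexicographically by gene id, which makes every ranking a strict total
order and every run reproducible.

The running sum gains |m_i|^p / Σ_members |m_j|^p at members and loses
1/(N−N_H) at non-members; ES is the signed maximal deviation, and at p=0
this is exactly the two-sample Kolmogorov–Smirnov running statistic (a lone
top-ranked member gives ES = +1). If all member weights are zero (possible
under a degenerate metric), member increments fall back to the unweighted
1/N_H. The leading edge is the members at/before the peak (ES>0) or
at/after the trough (ES<0). The weight exponent defaults to 1.

Significance: phenotype (stage-label) permutation by default, with
p = (1 + #{same-sign permutation ES at least as extreme}) / (1 + #same-sign
permutations) — never exactly 0 — and NES = ES / mean |same-sign
permutation ES|. When either group has fewer than 7 samples, phenotype
permutation is unreliable and the engine falls back to gene-set permutation
with a logged warning; `perm_type="phenotype_exact"` instead enumerates
every distinct relabeling (intended for tiny cohorts, where the permutation
p is then exact). Transition scans run every consecutive stage pair in the
declared order, skip underpopulated transitions with a logged reason, and
Benjamini–Hochberg-correct p across transitions.

### Pseudobulk path

For cell-level cohorts, cells of one annotated type (fibroblasts/CAFs) are
averaged per patient into one pseudobulk sample carrying the patient's
stage; patients with fewer than 10 such cells (configurable) are dropped
with a logged count. Restricting to the stromal compartment before
enrichment is what lets a fibroblast-specific signal survive: in
whole-tissue aggregates the same shift is diluted by the unshifted cell
types.

### PWM scanning and the exact score null

Promoter windows default to [TSS−5000, TSS+1000) on the coding strand
(0-based half-open; TSS = translation start). Match scores are log2-odds of
the pseudocounted position probabilities ((p + 0.1·bg)/1.1) against the
background; N bases contribute 0 log-odds. Scores are discretized to
integer units of 10⁻³ and the exact null distribution of the window score
under the background model is computed by dynamic programming (position-by-
position convolution of the four-point score distributions). A window is a
hit when its null tail probability is ≤ the match p-value threshold
(default 10⁻⁴, the conventional scanner default); both strands are scanned
and overlapping hits all count. Note that short motifs bound the attainable
p from below at (max bg probability)^L — a length-4 motif can never reach
10⁻⁴, which is a property of the statistic, not a bug.

Counts are assembled over the full (TF, gene, species) grid with explicit
zeros; a missing promoter is flagged missing, never silently counted as 0.

### TF–gene regression

Per (TF, gene), expression is regressed on copy number across species by
univariate OLS (β in log2-expression units per site; a joint multi-TF model
is deliberately out of scope). Pairs need ≥4 species with both values;
zero count variance marks the fit degenerate with no p. Benjamini–Hochberg
at α=0.05 across all tested pairs sets the `significant` flag, and TFs are
ranked by their number of significant target genes (ties broken by TF id).

### Invasion-front profiling

Masks are binary images with label 1 = invading compartment advancing
downward; the baseline row (undisturbed time-0 front, defined by the
scratch edge) is supplied per image — an Otsu-based estimator exists as a
convenience only. Per sampled column, depth = (deepest labeled row −
baseline row)·pixel size, floored at 0. The deepest-pixel rule (rather
than the contiguous-front boundary) is the default because detached
invading columns would otherwise undercount deep forks; `contiguous=True`
gives the alternative. Deep-fork counts use strict `depth > threshold` at
100 and 200 µm. Depth histograms use half-open bins [lo, hi) and conserve
the position count.

Noise handling: because the deepest-pixel rule is maximally sensitive to
salt noise, despeckling is done spatially (`despeckle_px`, a 2-D median on
the mask) — a 1-D median over the depth profile (`smooth`) cannot remove
noise that hits most columns, and is kept for ridge smoothing only.
Conditions are compared replicate-wise: each profile collapses to one
summary (mean depth or deep fraction) and the two replicate sets are
compared by an exact two-sided Mann–Whitney test (p unavailable with a
single replicate per arm; with 3 replicates per arm the smallest attainable
two-sided p is 0.1).

## Synthetic data: what it emulates and what it does not

The generators produce every input class with planted truth:

- `gen_species_expression` — log2 expression with planted genes following
  baseline + a·index + N(0, σ); the slope a is set from the realized index
  spread so the expected correlation equals the requested ρ.
- `gen_stage_cohort` — per-gene Gaussian baselines; the target set drops by
  shift_d·SD from the later stage of the named transition onward
  (cumulative, so all other consecutive pairs stay exchangeable).
- `gen_single_cell_cohort` — adds a per-patient random effect (default
  SD 0.5) so pseudobulk variance is patient-dominated, as in real cohorts;
  the shift lives only in the target cell type.
- `gen_promoters_and_pwms` — exact-consensus motif occurrences embedded
  non-overlapping in random background that is scrubbed of chance
  consensus/reverse-complement matches, so scan counts equal planted counts
  identically; expression = baseline + Σ β·count + noise.
  (`gen_tf_counts_expression` is the sequence-free fast path with the same
  statistical model.)
- `gen_invasion_mask` — filled front down to the baseline row plus
  rectangular forks occupying round(depth/pixel) rows below it, optional
  salt noise.

All generators are pure functions of their arguments including the seed
(single RNG stream, no global state), and each returns a truth record that
independent brute-force re-measurement reproduces (tested).

What the synthetic data does *not* model — hence what green tests do not
establish about real data: phylogenetic covariance between species, count
overdispersion and normalization artifacts of real RNA-seq, dropout and
library-size structure of real scRNA-seq, motif affinity variation (planted
sites are exact consensus), promoter extraction from real assemblies, and
optics/segmentation noise beyond pixel flips.

## Study-scale defaults used by tests and the acceptance script

Calibration replicate counts follow the design: 200 null and 100 power
replicates for GSEA (1000 genes, 20 samples/stage, 30-gene set, 2-SD
shift), 50 seeds for ELI recovery (1000 genes, 10 planted at ρ=0.9, 9
species), 500 seeds for β recovery (β=1.5, 9 species, noise SD 0.5) and
type-I control, and 50 seeded end-to-end bundles (500 genes, 12 planted
candidates, 2 planted regulators among 4 decoys, 3 stages × 20 samples).
Permutation counts of 200 per GSEA run give p-resolution ~5·10⁻³, ample
for α=0.05 decisions at these effect sizes.

## Numerical choices and degenerate inputs

- All float comparisons against oracles are at 10⁻¹²; the DP score null is
  exact (probabilities sum to 1 by construction) and compares to exhaustive
  enumeration at 10⁻¹².
- Permutation-extremeness comparisons use a 10⁻¹² slack so float jitter
  never flips a count.
- Degenerate paths are explicit: constant genes (flagged), empty
  intersections (warned), no-overlap gene sets (error), zero count variance
  (degenerate flag), stages with too few samples (skipped with reason),
  empty masks (all-zero profile), single replicates (p unavailable).
- The pipeline manifest records sha256 of every artifact; reruns with the
  same config are byte-identical.

## Known limitations

- ELI scoring treats species as independent draws; shared ancestry inflates
  effective correlations for clades of related species.
- The exact Spearman permutation null is used only up to 8 species; at 9+
  the t approximation is the same one standard tools use but is not exact.
- Gene-set permutation (the small-group fallback) tests a different null
  than phenotype permutation and tends to be anti-conservative for
  correlated sets.
- The scanner counts overlapping hits on both strands; palindromic motifs
  therefore count twice per site, as FIMO-style scanners do.
- Condition comparison treats replicates (not positions) as the sampling
  unit; with 3 replicates per arm the exact rank test cannot go below
  p = 0.1, matching the assay's statistical reality.
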