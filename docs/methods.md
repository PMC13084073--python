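# Methods

This note documents the models behind `orthocoex`, the parameters that
matter, what the synthetic benchmark does and does not emulate, and the
design choices made where the design was genuinely open.

## Differential expression over ripening

Counts for gene g in sample j are modeled negative-binomial with
variance mu + alpha mu^2 and

    log mu_gj = log s_j + beta_g0 + block_{b(j)} + condition_{c(j)}

Library size factors `s_j` are DESeq-style median-of-ratios: reference
genes are those with nonzero counts in every sample, and each sample's
factor is the median (taken on the log scale, as DESeq2 defines it) of
its counts over the per-gene geometric means. Factors are defined up to
a common scale; multiplying one sample's counts by c multiplies its
factor *relative to the others* by exactly c.

Per-gene GLMs are fit by batched IRLS (shared design matrix, per-gene
dispersion; log link; eta clipped to +/-30; ridge 1e-10; convergence
1e-8 on the log-likelihood, max 100 iterations, step-halving on the
rare non-improving update). The condition effect is tested by
likelihood ratio between the full model and one without condition.

**Dispersion.** alpha_g is the moment estimator solved from the Pearson
chi-square identity sum_j (y-mu)^2/(mu + alpha mu^2) = n - p against
the full-model fitted means, with one NB refit of the means at the
estimated alpha. This is the pooled, fitted-df-corrected generalization
of the within-cell rule (var - mean)/mean^2; a per-cell version is
impossible in the blocked time course, where each block x timepoint cell
has one library. Estimates are shrunk toward the gene-wise median with
weight w = 0.5 and floored at 1e-8. On data simulated at alpha = 0.2
with n = 30 the median estimate is ~0.18 (the suite asserts [0.1, 0.3]).

**Reference distribution.** The chi-square reference for the LRT is
anticonservative at this design size (30 libraries, 10 fitted mean
parameters): simulated null data give ~7-9% of p-values below 0.05.
LRT/df is therefore referred to a moderated F(df, (n-p)/(1-w)): the
denominator df credits the residual df plus the information borrowed by
shrinking dispersions toward the median, and tends to the chi-square as
w -> 1. Measured type-I fractions are 0.05-0.06 at nominal 0.05, and the
power to call a 4-fold monotone change at FDR < 0.01 with n = 30 is
~0.95. Genes with total count below `min_total_count = 10` are reported
as `low_count` and excluded from testing and from the BH universe
(p-values floored at 1e-300 before adjustment).

This engine deliberately approximates the DESeq2 LRT workflow: no
trended/MAP dispersion shrinkage, no Cook's outlier refitting, no
independent filtering. It is used only to gate genes at a fixed FDR.

## Expression patterns

Genes are summarized as condition-mean log2(TPM+1) profiles (means are
taken over whatever replicates exist, so a dropped replicate simply
reduces n for that condition), then row Z-scored with the n-1 standard
deviation; constant rows are flagged and excluded from mapping.

The SOM is the batch variant on a 20 x 20 rectangular grid (400 nodes).
Each epoch assigns every gene to its best-matching unit (minimal
Euclidean distance; ties to the lowest node index) and replaces each
codebook vector with the neighborhood-weighted mean of the assigned
profiles, with a Gaussian kernel of sigma = radius/2 truncated at grid
distance >= radius. The radius decays linearly from max(grid)/2 to 1
over the first 80% of epochs (default 100) and is then held constant —
the classic ordering/convergence two-phase schedule. At the final
radius of 1 the truncation leaves only each node's own assignments, so
the convergence phase performs per-node mean (Lloyd) updates and the
quantization error is non-increasing there; training stops early when
assignments stabilize. PCA initialization spreads the codebook over the
first two principal axes with a deterministic sign convention, so the
whole stage is bit-reproducible given the seed (random initialization
draws genes with the seeded generator and is equally reproducible).

Codebook vectors are Ward-clustered (Euclidean) and cut into k = 8
patterns; genes inherit their BMU's cluster. For ordered designs each
cluster is labeled by the Spearman correlation of its mean profile with
the condition rank: above +0.3 increasing, below -0.3 decreasing,
otherwise flat. The ripening species' "downregulated" set is the union
of its decreasing clusters. Neither the linkage nor the Z-scoring axis
is canonical in the field; both are configurable
(`PatternParams.linkage`, and Z-scores are computed over condition
means rather than samples because condition-level patterns are what the
heatmaps and the cluster selection operate on).

For tissue-panel species there is no DE gate, so genes whose
condition-profile log2 standard deviation falls below 0.5 (roughly less
than a 2.5-fold spread across tissues) are excluded before mapping —
the standard variance filter of co-expression analysis. Without it,
pure-noise profiles are Z-scored onto the unit sphere and blur the
cluster structure.

## Bait assignment and cluster selection

Per bait and species, the best hit passing identity >= 40% and bit
score >= 100 wins (bit score, then percent identity, then
lexicographic gene id). The pathway-carrying cluster is found by
counting assigned bait genes per cluster. `selected_cluster` is the
argmax (ties to the lowest id, logged); the *candidate set* is the
union of every cluster whose bait count reaches half the maximum.
When the baits agree this reduces exactly to the single bait-richest
cluster. The union matters because a fixed k = 8 cut of a 400-node
codebook can over-partition one coherent pattern: the bait patch then
splits into two near-identical clusters with the baits divided between
them (3/3 or 4/2), and selecting either half alone would drop genes
whose pattern is indistinguishable from the baits'. A fixed
`top_n_clusters` override is available.

## Integration and triage

Candidate genes are mapped to orthogroups (genes absent from the table
are counted as unmapped and cannot survive the intersection). The
shared set is the strict AND over all species; the final candidates are
the ripening species' downregulated genes whose orthogroup is shared.
Venn region sizes are reported for audit. Candidates are partitioned
into ordered annotation classes by case-insensitive regex over Pfam
term names (P450, 2OG-Fe(II) dioxygenase, multicopper oxidase, Rieske,
peroxidase, UDP-glucosyltransferase, O-methyltransferase, polyphenol
oxidase, then other_annotated / unannotated); the first matching class
wins. Within tiers, a deterministic ranking by descending mean Pearson
correlation with the bait genes' profiles is provided as a convenience.

## Mass targeting and metabolite scaling

Monoisotopic masses use most-abundant-isotope values (C = 12 exactly,
H 1.00782503207, O 15.99491461956, N 14.0030740048, S 31.97207100,
P 30.97376163). Adduct deltas are -1.007276 for [M-H]- and +44.998203
for [M+formate]- (HCOOH 46.005479 minus a proton; the electron mass is
neglected, consistent with 4-dp instrument output). Values are rounded
half-up to 4 decimals and EIC windows default to +/-0.05. Metabolite
AUC series are scaled to percent of the per-series (species/cultivar)
maximum — the maximum is exactly 100 by construction — then averaged
across series per compound and timepoint with an n-1 standard deviation.

## The synthetic benchmark

`SynthConfig` defaults define the study-like conditions: three species
(one ripening time course with 6 cultivar blocks x 5 ordered timepoints,
one library each; two 4-tissue panels with 3 replicates), 2 500
orthogroups and 6 000 genes per species (the surplus are unassigned
singletons), per-species copy number 0/1/2 with loss probability 0.1
and duplication probability 0.05, a 40-orthogroup planted module forced
present everywhere, 6 bait orthogroups inside it, and one planted,
unbaited target orthogroup annotated with 2OG-Fe(II) dioxygenase Pfam
terms. The target is simulated as a two-copy paralog family in every
species: known pathway dioxygenases are typically small paralog
families, and a benchmark whose recovery hinges on a single noisy gene
profile per species measures count noise rather than the method.

Counts are negative-binomial (shared dispersion 0.2) around log-normal
baselines (ln-mean 4.0, sd 1.5; planted-module genes draw from a
well-expressed regime, ln-mean 5.0, sd 1.0 — detectable expression is a
premise of guilt-by-association), with per-gene cultivar effects
(ln-sd 0.25) and library depth spread (ln-sd 0.2); TPM is column
scaling to 1e6. Planted genes decline monotonically over ripening with
a total fold change equal to `effect_size` (default 4) and per-gene
curvature, and in the panels are high everywhere except one designated
off tissue. Background structure: 70% of genes carry smooth maturation
trends (linear + quadratic, coefficient ln-sd 0.7) in the ripening
species — yielding roughly 40% DEGs and 20% downregulated at FDR 0.01,
the same order as real fruit-ripening transcriptomes — and in the
panels are drawn from a rank-2 model (two canonical tissue contrasts
per species, loading sd 0.6, idiosyncratic sd 0.15). The low-rank
choice matters: independent per-tissue noise would place Z-scored
background profiles uniformly on the sphere, a covariance structure no
real tissue panel has, and would erase the density gaps that make
pattern clusters meaningful. Metabolites decay multiplicatively with
maturation (one OME-like compound rises), with log-normal noise.

What the generator does **not** emulate: transcript isoforms and
quantification uncertainty, mean-dependent dispersion trends, correlated
background modules (background genes are independent given the low-rank
factors), annotation errors beyond decoy sprinkling, orthology errors,
and any sequence-level signal. Passing tests therefore demonstrate the
pipeline's logic and statistical calibration under its stated model,
not robustness to misassembly or misannotation.

## Problem sizes used

The benchmark runs at 6 000 genes x 3 species with a 400-node SOM;
one full pipeline run takes a few seconds, and the test suite sweeps
20 seeds for the recovery-rate check. Statistical checks use 1 000-2 000
simulated genes. These sizes make every assertion reproducible on a
single CPU in minutes while keeping each estimator in its intended
regime.

## Known limitations

- The NB engine is an approximation of DESeq2's LRT; exact count parity
  with DESeq2 output is out of scope by design.
- The moderated-F denominator df is a heuristic calibration; it is
  validated by simulation at the benchmark's design size, not derived.
- Cluster count k = 8 and the 400-node grid are taken as fixed
  conventions; no model selection is performed.
- With only 4-5 conditions per species, Z-scored profiles are
  low-dimensional and pattern clusters are coarse; the intersection step
  carries most of the specificity.
- The EIC machinery computes targets and windows only; no spectra are
  parsed.
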