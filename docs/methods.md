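# Methods

This note documents the statistical procedures `szsubtypes` implements, the
synthetic data model used to exercise them, the numerical conventions, and
the design decisions that were genuinely open.

## The analysis model

**Differential expression.** Expression values are assumed log-scale and
already normalized (background correction, variance-stabilizing transform
and between-array normalization are upstream concerns). For a contrast of
groups A and B, each gene gets a Welch (unequal-variance) two-sample
*t*-test; logFC is defined as mean(A) − mean(B) on the log scale, and
*q*-values come from Benjamini–Hochberg over all genes in the matrix. Genes
with |logFC| > 0.1 **and** *q* < 0.05 (strict inequalities) form the
clustering feature set. The Welch choice is deliberate: applied to the
per-cluster age summaries (42.8 ± 9.8, n = 33 vs 38.1 ± 10.9, n = 73) it
yields p = 0.031 → 0.03 at two decimals, whereas a pooled-variance test
yields 0.036 → 0.04; only the Welch form is consistent with the reference
per-cluster demographics table this package mirrors. Degenerate genes
(zero variance in both groups) get p = 1 when the means agree (t = 0
convention) and p = 0 otherwise.

**Subtype clustering.** Patients (cases only) are clustered by Lloyd's
k-means, best of `n_init = 50` restarts, on the DE-gene matrix, z-scored
per gene across patients by default so no high-variance gene dominates the
Euclidean metric (`standardize` flag). The cluster count is selected by a
deterministic surrogate of the visual elbow: k maximizing the second
difference I(k−1) − 2I(k) + I(k+1) of the within-cluster sum-of-squares
curve over k = 2..k_max−1, ties to the smallest k (default k_max = 6).
Sample order is canonicalized before fitting, so label assignments are
invariant to input permutations. Cluster indices are oriented by distance
from the control centroid (projected into the same standardized space):
index 0, "Cluster I", is always the control-distal — molecularly distinct —
cluster.

**Gene importance.** With cluster labels held fixed, the mean silhouette
s̄ = mean over patients of (b − a)/max(a, b) is recomputed once per gene
with that gene's column removed; importance is Δ(g) = s̄_full − s̄_without(g),
ranked descending with gene-id tie-breaks, and the top ⌈n/3⌉ genes are
flagged. Holding labels fixed makes the procedure deterministic and O(genes)
cheaper than re-clustering per gene; a re-clustering variant is available
behind the `recluster_loo` flag for sensitivity analysis. Removing gene g
only subtracts its per-pair squared differences from the squared Euclidean
distances, so the sweep reuses a single O(n²·G) distance computation; the
incremental update is verified against naive recomputation to 1e−9 in the
test suite. Singleton clusters contribute s = 0.

**Enrichment.** The top-third gene list is tested for overrepresentation in
each GMT set by the upper-tail hypergeometric probability
P[X ≥ overlap], X ~ HG(N = universe, K = set∩universe, n = list), with
Bonferroni adjustment over the number of sets and significance at adjusted
p < 0.05. The universe is all genes surviving preprocessing (not the DE
subset): the list was drawn from the measured population, so that is the
correct sampling frame; a flag exposes the choice. This is equivalent to a
one-sided Fisher exact test on the 2×2 overlap table (asserted in tests).

**Confounders.** Age is compared between clusters by the Welch *t* from
summary statistics (Satterthwaite df); sex by the two-sided Fisher exact
test under the probability-mass rule. To ask whether the subtype signal is
an age artifact, each panel gene is regressed (OLS) on age (years) and a
Cluster-I indicator; a genuine subtype effect shows cluster coefficients
(expression units) dwarfing age coefficients (units per year).

**Cross-cohort prediction.** The panel is the union of the
enrichment-significant sets intersected with the genes shared by the
training and each test platform (the model is refit per train-test pair at
a common penalty). Features are harmonized within each dataset by per-gene
robust standardization — centered at the gene's median, scaled by
1.4826·MAD. The robust location/scale is important: a shifted minority
subtype moves per-gene means and SDs in proportion to its (cohort-specific)
share of samples, so mean/SD scaling misaligns cohorts with different
subtype fractions, while medians and MADs track the unshifted majority.
Mean/SD (`zscore_per_gene`) and identity (`none`) harmonizations remain
available. The classifier is L1-penalized logistic regression (saga
coordinate solver, unpenalized intercept; C = 1/λ). λ is chosen by
5-fold stratified cross-validated log-loss under the one-standard-error
rule: the largest λ whose mean CV loss is within one SE of the minimum.
With ~200 training samples, ~200 panel genes, and ~85% of samples carrying
no panel signal at all, the loss-minimizing λ reliably memorizes noise in
the non-subtype samples (it can nearly separate the training bulk, which is
impossible out of sample); the 1-SE rule is the standard parsimony remedy.
λ is cross-validated once on the training panel and reused for the per-pair
refits, since the penalty is a property of the training problem and
re-selecting it per pair only adds selection noise.

Samples with fitted case probability > 0.5 are predicted positive. Because
only the distinct subtype is recognizable, recall is structurally low and
the natural score is precision: PPV = TP/(TP + FP) per test dataset, with
per-dataset TP/FP pooled and compared to the pooled case prevalence by an
exact one-sided binomial test. A dataset with zero predicted positives has
undefined PPV and is excluded from pooling with a warning.

## The synthetic cohort model

The generator emulates the structure of multi-cohort blood microarray
case-control studies; it is a stand-in (the underlying studies are
observational and specify no generative model), and all distributional
choices below are explicit.

Per gene, control expression is N(μ_g, σ_g) with μ_g ~ N(7, 1) and
σ_g ~ |N(0.5, 0.1)| — positive log-scale intensities with realistic
spread, not a model of any specific platform. Planted structure, per the
default design:

| component | size | effect (units of σ_g) | applied to |
|---|---|---|---|
| ribosome-like module | 69 genes (63↑, 5↓, 1 silent) | 1.5 (subtype I), 0.25 (subtype II) | patients |
| UPS-like module | 144 genes (117↑, 27↓) | 1.5 | subtype I only |
| disease-wide background | 1000 genes (500↑, 500↓) | 0.6 | all patients |
| low-variance genes | 50% of non-planted genes | σ_g scaled ×0.3 | everyone |

The small subtype-II ribosomal shift (one sixth of the subtype-I effect)
encodes that the majority subtype is *near* controls but not identical to
them on the ribosomal module, while the UPS module stays at control level
in subtype II: per-cluster contrasts then show the ribosomal set partially
significant and the UPS set at the false-positive floor for the majority
cluster, alongside near-complete significance of both modules for the
distinct cluster — the qualitative asymmetry the pipeline is designed to
surface. It also means case status carries a weak panel-gene signal even
outside the distinct subtype, so cross-cohort prediction has a real, if
modest, footing in the majority of patients.

The default cohort is 96 controls and 106 patients with
round(33/106·106) = 33 subtype-I patients; 5000 genes; 30% of genes carry a
second probe equal to the gene value plus N(0, noise_sd/2) noise
(noise_sd = 0.5), so probe collapsing is testable (the collapsed value
converges to the gene value). Ages are truncated normals (≥18 years) with
per-group means/SDs matching the reference demographics (controls
39.5 ± 12.5; subtype I 42.8 ± 9.8; subtype II 38.1 ± 10.9); sex is
Bernoulli (60%, 79%, 68% male respectively).

The **disease-wide background** deserves its own justification: real
case-control blood signatures involve thousands of modestly shifted genes,
of which curated modules are a small fraction. Because these genes shift in
*both* patient subtypes, they pass DE selection (per-gene t ≈ 4) but carry
no cluster-discriminative signal, so they populate the lower ranks of the
silhouette-importance list — exactly the backdrop against which module
enrichment in the top third is meaningful. Without it, the DE set would be
nearly all module genes and "top third" membership would be arithmetically
incapable of containing most of them. At default scale the filtered
universe is 2500 genes of which ~1150 pass DE selection (roughly half
scale of the reference analysis, for runtime).

The **five-platform design** mirrors the reference multi-cohort layout:
a 398-sample pool (186 controls, 212 patients) split into disjoint cohorts
of (96, 106), (29, 43), (22, 15), (8, 13), (31, 35) samples; the training
platform retains full gene coverage and each test platform a random 90% —
matching a panel of ~190 of 213 module genes shared between train and test.

What the generator does **not** emulate — and what green tests therefore do
not establish about real data: batch and site effects, platform-specific
probe biases beyond white noise, correlated gene-gene structure within
modules (genes are conditionally independent given group), non-Gaussian
intensity distributions, medication effects, or any count-based (RNA-seq)
noise model. Recovery rates on synthetic cohorts are upper bounds on what
identically parameterized real cohorts would yield.

## Numerical conventions and degenerate inputs

* Variance-filter and importance ties break by gene id; k-means restarts
  and CV folds derive from the config seed; all outputs are byte-stable
  under a fixed config (asserted in tests).
* BH is the step-up procedure as implemented in statsmodels; it matches a
  brute-force implementation on random p-vectors in tests.
* Fisher's two-sided p uses the probability-mass rule (tables no more
  probable than observed), matching full enumeration for small tables.
* Hypergeometric p at zero overlap is 1; Bonferroni caps at 1.
* Zero-spread genes under harmonization are set to 0 with a warning;
  a gene constant in both contrast groups gets p = 1 (t = 0 convention).
* Leave-one-out squared distances are clipped at 0 before the square root
  to absorb negative round-off.
* saga runs at tol = 1e-4, max_iter = 3000: coefficient changes below that
  tolerance are orders of magnitude smaller than the CV noise that drives
  λ selection.

## Problem sizes used in tests and the acceptance script

Unit tests run on scaled-down cohorts (≈400 genes, 85 samples). The
acceptance suite runs the full default design: 10 discovery seeds
(202 samples × 5000 genes), 10 five-platform validation seeds, and 20
zero-effect calibration seeds (fitting one model per seed on the planted
panel, since with zero effects no set is enriched and no data-driven panel
exists). The acceptance script reports 5 seeds per stochastic block; sizes
were chosen so a complete run stays comfortably within a typical CI budget
while keeping Monte-Carlo noise well below the asserted margins.

## Known limitations

* The elbow surrogate (maximum second difference) is one of several
  formalizations of a visual heuristic; on curves without a clear knee it
  defaults to small k.
* Importance deltas are computed under fixed labels; if the clustering
  itself is unstable, the re-clustering variant may rank differently.
* The enrichment test treats genes as exchangeable (no gene-length or
  expression-level bias terms, no annotation clustering).
* PPV-based validation is blind to recall by design; a model that finds
  only the distinct subtype scores well, which is the intended behavior but
  means sensitivity claims are out of scope.
* With zero predicted positives in every dataset the pooled PPV is
  undefined and validation aborts with an explanatory error.
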