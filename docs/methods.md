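# Methods

This note records the models implemented in `ribopp`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter when comparing against other
implementations.

## Translation efficiency

TE for gene *g* in one (condition, replicate) pair is
`CPM_rpf(g) / CPM_rna(g)`, where CPM is computed on `counts + pseudocount`
over the library total of adjusted counts. The pseudocount (default 1)
guarantees strictly positive, finite TE even at zero counts; because both
assays are normalized to CPM, TE is invariant to per-library sequencing
depth up to the (vanishing) bite of the pseudocount.

Differential TE is tested per gene on per-replicate log2 TE. The default
test is the **pooled-variance (Student) t-test**; Welch's unequal-variance
test is available via `differential_te(..., test="welch")`. The pooled
test is the default because under the TE null the two conditions share a
distribution — hence a variance — and the pooled test holds its nominal
size at very small replicate numbers, whereas the Welch–Satterthwaite
degrees-of-freedom approximation is markedly conservative at 3 + 3
replicates (empirical type I ≈ 0.033 at nominal 0.05 on normal data).
With ribosome-profiling designs of n = 3 per group this difference is
material. Raw p-values (not FDR-adjusted) are thresholded, matching the
classification rule |log2FC| > 1.5 and p < 0.05; the sign convention is
treated − control, so inhibited translation is negative.

Genes failing the minimum-count filter (mean raw RNA count ≥ 5 across all
RNA libraries, configurable) keep their log2FC but are excluded from
testing (`tested = False`, class `ns`). With a single replicate per
condition no test is possible: p is missing and all classes are forced
`ns` with a warning.

Reporter TE is the dual-luciferase formula
`(F-luc/R-luc activity) / (F-luc/R-luc mRNA)`; polysome distributions are
per-fraction relative quantities normalized to sum to one.

## Polyproline motif scanning

PP, PPG and PPP are counted with **overlapping** windows: a run of *p*
prolines contributes *p − 1* PP and max(*p* − 2, 0) PPP. Overlap handling
is a genuine convention choice; overlapping counting is the conservative
superset and is the count the bin labels {0, 1, 2, 3, ≥4} refer to. A
`overlapping=False` flag switches to greedy non-overlapping counting.
Binning uses the PP dipeptide count only; PPG/PPP and the longest proline
run are reported alongside. When several FASTA records map to one gene the
default policy scans the longest isoform (`first` and `error` policies
available). Sequences are case-folded, one trailing `*` is stripped, and
any other non-amino-acid character is an error naming its position.

## Enrichment statistics

* 2×2 association: Pearson chi-square **without** continuity correction
  (the large-sample setting of proportion comparisons between TE classes);
  `method="auto"` falls back to Fisher's exact test when any expected cell
  is below 5. A zero margin is an explicit error, not a silent p = 1.
* Mann–Whitney: exact by full enumeration of label assignments on pooled
  mid-ranks when both groups have ≤ 8 observations (ties handled exactly;
  two-sided p = twice the smaller tail, capped at 1); otherwise the normal
  approximation with tie correction.
* ORA: one-sided hypergeometric upper tail `P(X ≥ k)`,
  `X ~ Hypergeom(N, K, n)`, per gene set; BH adjustment across tested sets;
  zero-overlap sets are reported with p = 1. The default universe is the
  set of genes with a computed TE (tested genes), not the whole genome —
  a whole-genome background inflates enrichment of any expression-biased
  set. Identifier matching is case-insensitive with whitespace stripping;
  duplicates collapse with a warning.

## Trajectory clustering

Profiles are group means, row z-scored with the n−1 denominator; constant
rows become all-zero and are flagged. z-scoring group means (rather than
per-sample values) matches the heat-trajectory convention; sample-level
data feed PERMANOVA instead.

Fuzzy c-means uses Euclidean distance on the z-scored profiles, fuzzifier
m = 2.0 (the common default for soft time-course clustering; configurable),
alternating closed-form updates, convergence when the relative objective
drop falls below 1e−9 (max 300 iterations), and 10 random restarts per fit
with deterministic child seeds; the best objective is kept. A profile
coinciding with a center receives full membership there (limit
convention). Hard assignment is argmax membership with lowest-index
tie-break; reported cluster members additionally need membership ≥ 0.5.

The cluster number is the elbow of J(k): both axes of the (k, J) curve are
normalized to [0, 1] and the k farthest from the chord joining the first
and last points is selected (Kneedle-style). Normalizing the axes makes
the criterion scale-free; without it the objective's units would dominate.
A k-range of length 2 has a degenerate chord and returns k_min with a
warning.

Monotone-trajectory selection takes every cluster whose center vector is
strictly increasing (or decreasing) along the ordered groups; a flat
center is never selected. Cross-cohort intersection is exact name matching
after case/whitespace normalization.

## PCoA and PERMANOVA

PCoA is classical scaling: eigendecomposition of the double-centered Gram
matrix B = −½ J D² J; axes are ordered by eigenvalue, negative eigenvalues
(non-Euclidean inputs) are reported but never embedded. PERMANOVA follows
the between/within sum-of-squared-distances partition: pseudo-F =
(SS_b/(a−1))/(SS_w/(N−a)), R² = SS_b/SS_total, and
p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1) under label permutation. Note
that permutations reproducing the observed partition tie the observed F
and are counted, so the attainable minimum p exceeds 1/(n_perm+1) for
small balanced designs. The default distance is Euclidean on standardized
sample profiles; any precomputed distance matrix is accepted (e.g.
Bray–Curtis from scipy), since the metric behind published ordinations of
this kind is rarely stated.

## Assay formulas

Migration rate = (W₀ − W₁)/W₀ × 100 (%); invasion area = I₁ − I₀ (sign
preserved); both report negative values with a warning rather than
clamping. The IHC composite multiplies the stained-area grade — 0: (0, 5%],
1: (5%, 25%], 2: (25%, 50%], 3: (50%, 75%], 4: > 75% — by the intensity
grade 0–3, giving 0–12. The published band endpoints overlap (5% belongs
to two bands as written); this implementation fixes left-open/right-closed
intervals, so exactly 5% is grade 0 and grade 1 starts strictly above 5%.
2^−ΔΔCt uses ΔΔCt = (Ct_target,case − Ct_ref,case) − (Ct_target,ctrl −
Ct_ref,ctrl).

## Synthetic generator: what it emulates, and what it does not

The generator plants: (a) a proteome whose PP content is exact by
construction — background sequence is drawn from the 19 non-proline amino
acids and proline runs are inserted at distinct cut points, so a rescan
always equals the planted count; (b) NB counts, mean μ_g from lognormal
weights (σ = 0.8) scaled so each library's expected total equals
`lib_size` (default n_genes × baseline_mu = 10⁶), variance μ(1 + φμ) with
φ = 0.1 — a common bulk RNA-seq regime; (c) treated-RPF repression
t_g = 2^(−β·PP) for responsive genes. The treated RPF library is *not*
renormalized — its total reflects the repressed mass, ~7% below target at
the defaults (within 10%), as a real re-sequenced library would only after
depth matching. Default bin probabilities (0.66, 0.15, 0.08, 0.05, 0.06
for PP = 0/1/2/3/≥4) were set so this depth property holds with margin
while keeping ≥ 100 high-PP genes for effect-size recovery.

Panels plant shapes on a z-like scale (amplitude 1.2, Gaussian noise
sd 0.3 on group means, 6 replicate samples per group). The default shape
mix is increasing / decreasing / peaked / valley — four shapes that remain
well separated **after row z-scoring**. A "flat" shape is supported but
not planted by default: a constant row plus noise z-scores to an arbitrary
direction, so flat metabolites cannot form a coherent cluster and would
only blur the elbow signal. The shared increasing subset defaults to ten
amino-acid names (led by proline, serine, alanine, histidine, threonine,
methionine, isoleucine), present in every cohort with the same shape.

Features of real data deliberately *not* emulated: read-level structure
(no FASTQ, no P-site offsets, no codon-resolution occupancy), UTR/ORF
architecture, between-replicate batch effects, correlated gene-gene
expression, compositional coupling beyond the shared library totals, and
metabolite covariance. Passing tests therefore demonstrate correctness of
the statistical machinery and recoverability of planted effects under an
idealized generative model — not performance on any real dataset.

## Problem sizes and seeds

Defaults: 2,000 genes × (2 assays × 2 conditions × 3 replicates) = 12
libraries of ~10⁶ reads; 70 metabolites per cohort across two cohorts
(3 and 4 ordered groups). Null calibrations use 2,500 genes (≥ 2,000
tested after filtering) and 200 PERMANOVA simulations at 199 permutations;
oracle equivalences use 1,000 random sequences and 100 random ORA
configurations. These sizes give stable estimates while keeping the full
suite fast on a single CPU. One global seed expands into fixed
per-component child seeds (proteome 0, counts 1, panels 2, gene sets 3),
so every sub-generator is independently reproducible; all CLI stages take
an explicit `--seed`.

## Known limitations

* The differential-TE test treats replicates as independent and gene-wise
  tests as exchangeable; no variance shrinkage across genes is applied
  (a deliberate simplicity/transparency trade-off; the plug point accepts
  alternative tests).
* The elbow criterion needs a k-range wide enough to bracket the true k;
  with fewer than three candidate k values it degenerates.
* Exact Mann–Whitney enumeration is limited to ≤ 8 observations per group
  (C(16, 8) = 12,870 assignments); beyond that the tie-corrected normal
  approximation is used.
* PERMANOVA assumes exchangeable samples under the null; group-structured
  covariates are out of scope.
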