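# ribopp

Analysis toolkit linking **polyproline-motif content to translation-efficiency
change under prolyl-tRNA-synthetase inhibition**, together with
**metastasis-associated metabolite trajectory clustering** across ordered
cohorts — the two computational arms of a hepatocellular-carcinoma (HCC)
proline-metabolism study design. A first-class synthetic-data module
replaces the wet-lab inputs, so the entire pipeline runs, and is tested,
from a single seed.

## Who this is for

Computational biologists analysing paired RNA-seq / Ribo-seq experiments
(starting from gene-level count matrices), and anyone reproducing the
trajectory-clustering / enrichment workflow on metabolite panels or their
own data in the same plain-text formats (TSV/CSV/FASTA/GMT).

## The model

**Translation efficiency.** For gene *g* in one (condition, replicate),

    TE_g = CPM_RPF(g) / CPM_RNA(g)

with a pseudocount of 1 added to raw counts before CPM normalization.
Differential TE between treated and control is tested per gene on
per-replicate log2 TE (pooled-variance t-test by default, Welch optional)
and classified **up** / **down** / **ns** at |log2FC| > 1.5 and p < 0.05.
Consecutive prolines stall elongating ribosomes, so when prolyl-tRNA
charging is inhibited, genes rich in Pro–Pro (PP) dipeptides are expected
to dominate the TE-down class. The motif scanner counts overlapping PP,
PPG and PPP motifs and bins genes by PP count into {0, 1, 2, 3, ≥4};
enrichment of PP-containing genes among TE-down genes is tested by
chi-square (Fisher fallback), PP counts per gene by Mann–Whitney (exact by
enumeration for small samples), gene-set over-representation by the
hypergeometric upper tail P(X ≥ k), X ~ Hypergeom(N, K, n), with
Benjamini–Hochberg correction.

**Trajectory clustering.** Metabolite group-mean profiles are row z-scored
and clustered by fuzzy c-means (fuzzifier m = 2), minimizing
J = Σ_i Σ_j u_ij^m ‖x_i − c_j‖²; the cluster number is chosen by the elbow
of the objective curve (maximum chord distance), members are assigned by
maximum membership (cutoff 0.5), clusters with strictly monotone centers
give the progressively increasing/decreasing metabolite sets, and those
sets are intersected across cohorts. Sample-level panels are summarized by
PCoA (classical scaling) and tested by PERMANOVA (pseudo-F, R²,
permutation p).

**Synthetic study.** Counts are negative binomial with mean μ and variance
μ(1 + φμ), φ = 0.1. The treated RPF mean of a *responsive* gene is
multiplied by 2^(−β·PP-count) (β = 1 by default; 30% of PP-containing
genes responsive; 3 replicates per condition) — so the planted log2 TE
change is −β·PP-count. Panels plant increasing / decreasing / peaked /
valley shapes plus a shared increasing subset across cohorts; gene sets
plant a metastasis-style set enriched among responsive genes and one
pathway enriched among the truly repressed genes.

Closed-form assay helpers are included: wound-healing migration rate,
spheroid invasion area, the composite IHC score (area grade 0–4 ×
intensity grade 0–3, range 0–12) and 2^−ΔΔCt qPCR fold changes.

## Worked example

```python
import pandas as pd
from ribopp import (SimConfig, generate_study, compute_te, differential_te,
                    contingency_test, scan_motifs)
from ribopp.translation_efficiency import min_count_mask

study = generate_study(SimConfig(seed=1))
te = compute_te(study.counts)
de = differential_te(te, "control", "treated",
                     tested=min_count_mask(study.counts))
print(de["class"].value_counts().to_dict())

pp = pd.Series(study.truth["pp_counts"])
down = de.index[de["class"] == "down"]
other = de.index[(de["class"] != "down") & de["tested"]]
table = [[(pp[down] >= 1).sum(), (pp[down] == 0).sum()],
         [(pp[other] >= 1).sum(), (pp[other] == 0).sum()]]
stat, p = contingency_test(table, method="auto")
print(f"chi2={stat:.1f} p={p:.3g}")

print(scan_motifs("MAPPPGSTPPA"))
```

prints

```
{'ns': 1875, 'down': 118, 'up': 7}
chi2=239.7 p=4.65e-54
MotifProfile(gene='', length=11, pp_count=3, ppg_count=1, ppp_count=1,
             max_run=3, bin='3', contains_pp=True)
```

Of 2,000 simulated genes, 118 lose translation efficiency in the treated
condition and 7 gain it; 116 of the 118 TE-down genes contain PP motifs
versus 548/1,882 among the rest — the planted motif-dependent repression
is recovered as a massive PP enrichment. The scanner output shows a PPP
run counted as two overlapping PP and one PPP motif.

The same workflow is available from the shell:

```sh
ribopp pipeline run --out run1 --seed 1       # full pipeline, one directory
ribopp simulate --out sim --seed 1            # or stage by stage
ribopp scan-motifs --fasta sim/proteome.fasta --out motifs.tsv
ribopp te --counts sim/counts.tsv --meta sim/samples.csv --out te.tsv
```

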