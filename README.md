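# tmedissect

Dissect bulk tumor cohorts into **inflamed ("hot")** and **noninflamed
("cold")** immune microenvironments using immune-cell signatures derived
from annotated single-cell RNA-seq, then characterize the two phenotypes
across multi-omics layers.  Intended for computational oncologists who want
a fully specified, testable version of this common TCGA-style analysis:

1. **Marker derivation** — per immune cell type, one-vs-rest Wilcoxon on
   log-normalized single-cell counts; keep genes with log2FC > 0 and BH
   adj. p < 0.05; rank by |PCT_type − PCT_malignant| and keep the top 1%.
2. **Scoring & classification** — a single-sample weighted-KS enrichment
   score per signature (rank-based, bounded in [−1, 1], invariant to
   monotone transforms), then per-tumor-type k-means (k = 3) into
   inflamed / median / noninflamed; median samples are excluded.
3. **Differential multi-omics** — TMM-normalized log-CPM Welch tests for
   mRNA/miRNA/lncRNA with the pan-cancer rule (|log2FC| > 1.5, FDR < 0.05
   in ≥ 4 tumor types); promoter-probe differential methylation on M-values
   (|Δβ| > 0.1, adj. p < 0.05); hypergeometric over-representation.
4. **Noncoding regulation** — Spearman-based lncRNA partner (top 1% by mean
   |ρ| of significant correlates) and miRNA target (database ∩ ρ < 0 ∩
   FDR < 0.05) selection, emitted as a signed coexpression network.
5. **Drug connectivity** — classic tag-list KS connectivity against a drug
   rank-profile database; positive normalized score = candidate cold→hot
   converter.
6. **Survival** — Kaplan–Meier / log-rank, Cox PH (Efron ties, via
   lifelines), maximally selected log-rank-score cutpoints, and fixed-effect
   inverse-variance pooling of per-tumor-type hazard ratios.

A first-class **synthetic-data module** generates every pipeline input with
planted ground truth (negative-binomial single-cell counts with planted
markers, bulk mixtures driven by a trimodal infiltration fraction,
Beta-distributed methylation with planted promoter differences, a drug
database with a planted converter, and survival times whose hazard falls
with infiltration), so each stage has a parameter-recovery test.  See
`docs/methods.md` for the models, defaults, and design decisions.

## Worked example

```python
from tmedissect import (SimulationConfig, simulate_scrna, simulate_cohort,
                        qc_filter, derive_marker_sets, score_matrix,
                        classify_tme, pooled_tme_hazard)

cfg = SimulationConfig(seed=1)
adata, sc_truth = simulate_scrna(cfg)          # 1000 cells x 3000 genes
markers = derive_marker_sets(qc_filter(adata)) # ~10-gene signatures / type

cohort, truth = simulate_cohort(cfg)           # 3 tumor types x 100 samples
scores = score_matrix(cohort.mrna, markers, tumor_type=cohort.tumor_type)
labels = classify_tme(scores, seed=1)
pooled, forest = pooled_tme_hazard(cohort.survival, labels.labels,
                                   labels.retained, cohort.tumor_type)
print(f"pooled inflamed HR {pooled['hr']:.2f} "
      f"({pooled['ci_lower']:.2f}-{pooled['ci_upper']:.2f})")
```

prints (seed 1):

```
pooled inflamed HR 0.60 (0.41-0.88)
```

i.e. samples the pipeline classifies as inflamed have ~40% lower death
hazard than noninflamed ones — the protective direction planted by the
generator (log hazard = −1.0 × infiltration fraction, so the true
hot-vs-cold HR is ≈ 0.67) and recovered through the whole chain
(markers → scores → clustering → Cox → pooling).

The same stages are available as a CLI for file-based use
(`tmedissect simulate|markers|score|classify|de|aggregate|methyl|ora|`
`targets|connectivity|survival`); run `tmedissect --help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic world from the given seed and runs the
entire pipeline from scratch — marker derivation, scoring and
classification, pan-cancer differential expression, promoter methylation,
noncoding target selection, drug-connectivity screening, and pooled
survival — printing what each stage recovered against the planted ground
truth and writing its JSON result to `--out`.
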