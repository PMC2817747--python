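# breastmarker

Marker discovery for breast cancer from quantitative PCR expression data,
built as a reusable, fully tested analysis pipeline. The scientific question:
which genes discriminate invasive breast cancer tissue from healthy breast
tissue well enough to be candidate serum markers for early detection — and do
histologically *normal* tissues from a cancer-bearing breast sometimes carry a
cancer-like expression profile?

The pipeline has five computational stages, each a library module under
`src/breastmarker/` with a numbered driver under `analysis/`:

1. **Normal-tissue variability** (`varcomp`). Expression of each gene in
   healthy tissue (bilateral reduction-mammaplasty donors: women *w*, breasts
   *b* within woman, tissue slices *s* within breast) is modelled as
   `y_wbs = μ + W_w + B_wb + ε_wbs` and decomposed by nested ANOVA
   (method-of-moments with unbalanced-design coefficients; REML cross-check)
   into between-women, between-breasts-within-woman and within-breast
   components. Shares are reported on the SD scale,
   `σ_c / (σ_w + σ_b + σ_s)`, so they sum to 100%.
2. **Candidate mining** (`mining`). A reduction cascade over a discretized
   gene expression/annotation database: drop genes confined to
   nucleus/mitochondrion/ribosome, drop housekeeping genes, drop genes
   expressed ≥10× the median in high-cardiac-output organs, keep genes with
   low expression in normal tissues, and prioritize secreted/membrane
   proteins; a literature list is unioned in at the end.
3. **qPCR preprocessing** (`qpcr`). CT → linear via a dilution-standard curve
   (efficiency `exp(-1/slope)` from CT regressed on log dilution) or the fixed
   OpenArray transform `1.735^(32−CT)`; replicate averaging with %CV
   flagging; housekeeping normalization; median-centered log2; cross-platform
   %CV concordance.
4. **Differential expression** (`decall`). A control-referenced threshold
   rule: over-cutoff = control mean + 3 SD, under-cutoff = control minimum; a
   gene is called when ≥20% of cancers and ≤5% of controls lie beyond. A
   stricter 1.2-fold / >30%-of-tumors ratio rule covers single-replicate data.
5. **Clustering** (`clustering`). Two-way agglomerative clustering with
   Spearman rank correlation between cluster *centroids* (centroid linkage on
   mean-normalized log2 data), a two-cluster cut at the root, classification
   of each normal-tissue category into the cancer- vs control-enriched
   cluster, and a composition summary of the cancer sub-clusters.

`synthetic` generates every input at the study design's conditions (the real
93-tissue expression table is not redistributable): the nested mammaplasty
design, the 24 cancer / 38 ipsilateral / 3 contralateral / 28 mammaplasty
cohort with 67 differentially expressed genes among 126 evaluable and a 7/38
cancer-like ipsilateral fraction, raw CT plates, and a toy annotation
database with a planted cascade-surviving subset. `studydata` bundles the
published 18-gene normal-breast variability panel.

## Worked example

```bash
python analysis/04_differential_expression.py --seed 1
python analysis/05_cluster_classification.py --seed 1
```

prints

```
126 evaluable genes (8 inconclusive removed)
67 genes discriminate cancers from mammaplasty controls (34 over-, 33 under-expressed; planted truth: 67)
...
                n  in_cancer_cluster  in_control_cluster
cancer         24                 24                   0
ipsilateral    38                  7                  31
contralateral   3                  1                   2
mammaplasty    28                  0                  28

7 of 38 ipsilateral normals show a cancer-like profile (planted truth: 7)
```

Reading: of the 126 genes with conclusive assays, 67 separate cancers from
healthy controls under the 20%/5% threshold rule. Clustering the 93 tissues
on those 67 genes splits them into a cancer and a control cluster; 7 of the
38 histologically normal tissues from cancer-bearing breasts fall in the
cancer cluster — molecularly cancer-like tissue, the planted
predisposition signal — while the mammaplasty controls all cluster together.

The same steps are available as a CLI (`breastmarker normalize | varcomp |
mine | decall | cluster | simulate`) over the CSV/JSON-lines formats
described in `breastmarker.io`.

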