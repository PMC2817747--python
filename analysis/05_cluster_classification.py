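#!/usr/bin/env python
"""Clustering the cohort on the discriminating genes; cancer-like normals.

Restricts the synthetic cohort to the genes called differentially expressed,
clusters the tissues with Spearman similarity and centroid linkage, cuts the
tree at the root into a cancer-enriched and a control-enriched cluster, and
counts each normal-tissue category per cluster: ipsilateral normals landing
in the cancer cluster are the molecularly "cancer-like" tissues.  Also
summarizes the two sub-clusters of the cancer cluster (subtype / outcome
composition) and exports the dendrogram as Newick.
"""

import argparse
from pathlib import Path

from breastmarker import clustering, decall, qpcr
from breastmarker import synthetic as syn

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg = syn.study_cohort_config(seed=args.seed)
    matrix, ann = syn.gen_cohort(cfg)
    centered = qpcr.median_center(matrix)
    cancers = ann.loc[ann["tissue_class"] == "cancer", "tissue"].tolist()
    controls = ann.loc[ann["tissue_class"] == "mammaplasty", "tissue"].tolist()
    called = decall.called_genes(decall.call_de(centered, cancers, controls))
    print(f"clustering {matrix.shape[1]} tissues on {len(called)} discriminating genes")

    sub = qpcr.median_center(matrix.loc[called], center="mean")
    dendro = clustering.cluster(sub, axis="tissues")
    (RESULTS / "tissue_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    assign = clustering.cut_two(dendro)
    report = clustering.classify_normals(assign, ann)
    report.to_csv(RESULTS / "cluster_classification.csv")
    print("\ntissues per cluster:")
    print(report.to_string())
    n_cl = int(report.loc["ipsilateral", "in_cancer_cluster"])
    print(f"\n{n_cl} of {int(report.loc['ipsilateral', 'n'])} ipsilateral normals "
          "show a cancer-like profile (planted truth: 7); "
          f"{int(report.loc['contralateral', 'in_control_cluster'])} of "
          f"{int(report.loc['contralateral', 'n'])} contralateral normals sit in "
          "the control cluster")

    table = clustering.subcluster_summary(dendro, assign, ann)
    table.to_csv(RESULTS / "cancer_subclusters.csv")
    print("\ncancer-cluster sub-clusters (subtype / outcome composition):")
    print(table.to_string())
    print(f"\nwrote {RESULTS / 'cluster_classification.csv'}")


if __name__ == "__main__":
    main()
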