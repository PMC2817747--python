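"""Two-way hierarchical clustering with Spearman similarity and centroid linkage.

Agglomerative clustering over tissues (or genes) where the similarity between
two clusters is the Spearman rank correlation between their *centroid*
profiles — the arithmetic mean of member profiles on the (mean-normalized)
log2 scale — recomputed after every merge.  This is the convention of the
classic gene-expression clustering programs; it is not average pairwise
correlation, and because centroid similarities can exceed those of the merged
parents, occasional inversions are expected and logged rather than fatal.

The two-cluster cut removes the root merge; with a cancer/control cohort this
separates a cancer-enriched from a control-enriched cluster, and histologically
normal tissues landing in the cancer cluster are flagged as "cancer-like".

Determinism: ties in similarity are broken by merging the pair with the
smallest (cluster id, cluster id), ids being assigned by input order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dendrogram",
    "DendroNode",
    "ClusterAssignment",
    "spearman_similarity",
    "cluster",
    "cut_two",
    "classify_normals",
    "subcluster_summary",
]

log = logging.getLogger(__name__)


@dataclass
class DendroNode:
    """A node of the binary merge tree; leaves carry item labels."""

    id: int
    label: str | None = None
    left: "DendroNode | None" = None
    right: "DendroNode | None" = None
    similarity: float | None = None  # similarity at which children merged

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.left.leaves() + self.right.leaves()


@dataclass
class Dendrogram:
    """Merge tree over items with per-merge similarities."""

    root: DendroNode
    items: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    def leaf_order(self) -> list[str]:
        """Display order of items (left-to-right tree traversal)."""
        return self.root.leaves()

    def to_newick(self) -> str:
        """Newick export; branch lengths are 1 - merge similarity."""

        def fmt(node: DendroNode, parent_sim: float) -> str:
            length = max((node.similarity or 1.0) - parent_sim, 0.0) if not node.is_leaf else 1.0 - parent_sim
            if node.is_leaf:
                return f"{node.label}:{length:.6g}"
            inner = ",".join(fmt(c, node.similarity or 0.0) for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        sim = self.root.similarity or 0.0
        inner = ",".join(fmt(c, sim) for c in (self.root.left, self.root.right)) \
            if not self.root.is_leaf else self.root.label
        return f"({inner});"


@dataclass
class ClusterAssignment:
    """Two-cluster labelling of items with optional class enrichment."""

    labels: pd.Series  # item id -> "A" | "B"
    enrichment: dict = field(default_factory=dict)  # cluster label -> class name

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _pairwise_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation on pairwise-complete observations; 0 when undefined."""
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        return 0.0
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return 0.0
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def spearman_similarity(m: pd.DataFrame, axis: str = "tissues") -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix between items.

    ``axis="tissues"`` correlates columns (tissue profiles over genes);
    ``axis="genes"`` correlates rows.  Missing values are handled
    pairwise-complete; ties receive mid-ranks.  Items with zero variance get
    NaN correlations and a warning (their ranking is undefined).
    """
    if axis not in ("tissues", "genes"):
        raise ValueError("axis must be 'tissues' or 'genes'")
    data = m if axis == "tissues" else m.T
    if data.shape[1] < 2:
        raise ValueError("need >=2 items")
    degenerate = [c for c in data.columns if data[c].dropna().nunique() <= 1]
    if degenerate:
        warnings.warn(
            f"zero-variance item(s), correlations undefined: {degenerate}",
            stacklevel=2,
        )
    sim = data.corr(method="spearman")  # pairwise-complete, mid-ranks
    np.fill_diagonal(sim.values, 1.0)
    return sim


def cluster(m: pd.DataFrame, axis: str = "tissues") -> Dendrogram:
    """Agglomerate items by Spearman similarity between cluster centroids.

    ``m`` should hold mean-normalized log2 expression.  At each step the pair
    of clusters with the highest centroid Spearman correlation merges
    (smallest-id pair on ties); the merged cluster's centroid is the NaN-aware
    mean of its member profiles, and its similarities to all surviving
    clusters are recomputed.

    Raises
    ------
    ValueError
        Fewer than 2 items on the chosen axis.
    """
    if axis not in ("tissues", "genes"):
        raise ValueError("axis must be 'tissues' or 'genes'")
    data = (m if axis == "tissues" else m.T).to_numpy(dtype=float)
    items = list((m.columns if axis == "tissues" else m.index).astype(str))
    n = len(items)
    if n < 2:
        raise ValueError("need >=2 items to cluster")

    nodes: dict[int, DendroNode] = {
        i: DendroNode(id=i, label=items[i]) for i in range(n)
    }
    centroids: dict[int, np.ndarray] = {i: data[:, i].copy() for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    sim: dict[tuple[int, int], float] = {}
    active = sorted(nodes)
    for ai, i in enumerate(active):
        for j in active[ai + 1:]:
            sim[(i, j)] = _pairwise_spearman(centroids[i], centroids[j])

    merges: list[tuple[int, int, float]] = []
    next_id = n
    last_sim = None
    while len(active) > 1:
        best = max(
            ((s, -i, -j) for (i, j), s in sim.items()),
        )
        best_sim, bi, bj = best[0], -best[1], -best[2]
        if last_sim is not None and best_sim > last_sim + 1e-12:
            log.info(
                "centroid-linkage inversion: merge at %.4f after %.4f",
                best_sim, last_sim,
            )
        last_sim = best_sim

        merged = DendroNode(
            id=next_id, left=nodes[bi], right=nodes[bj], similarity=best_sim
        )
        # NaN-aware size-weighted mean of member profiles
        stacked = np.vstack([centroids[bi], centroids[bj]])
        weights = np.array([sizes[bi], sizes[bj]], dtype=float)
        mask = np.isfinite(stacked)
        wsum = (np.where(mask, stacked, 0.0) * weights[:, None]).sum(axis=0)
        wtot = (mask * weights[:, None]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            centroid = np.where(wtot > 0, wsum / wtot, np.nan)

        for k in (bi, bj):
            active.remove(k)
            del nodes[k], centroids[k], sizes[k]
        sim = {pair: s for pair, s in sim.items()
               if bi not in pair and bj not in pair}
        for k in active:
            sim[(min(k, next_id), max(k, next_id))] = _pairwise_spearman(
                centroids[k], centroid
            )
        nodes[next_id] = merged
        centroids[next_id] = centroid
        sizes[next_id] = int(weights.sum())
        active.append(next_id)
        merges.append((bi, bj, best_sim))
        next_id += 1

    return Dendrogram(root=nodes[active[0]], items=items, merges=merges)


def cut_two(d: Dendrogram) -> ClusterAssignment:
    """Remove the root merge; the two subtrees become clusters ``A`` and ``B``.

    ``A`` is the left subtree (the one whose construction involves the
    smaller cluster id, so the split is deterministic).  All-identical
    profiles still split deterministically; the degenerate case is flagged
    with a warning.
    """
    root = d.root
    if root.is_leaf:
        raise ValueError("cannot cut a single-leaf tree")
    if root.similarity is not None and root.similarity > 0.999:
        warnings.warn("root merge at similarity ~1: degenerate split", stacklevel=2)
    labels = {}
    for leaf in root.left.leaves():
        labels[leaf] = "A"
    for leaf in root.right.leaves():
        labels[leaf] = "B"
    series = pd.Series({item: labels[item] for item in d.items}, name="cluster")
    return ClusterAssignment(labels=series)


def _enrich(assign: ClusterAssignment, ann: pd.DataFrame,
            cancer_class: str = "cancer", control_class: str = "mammaplasty",
            class_col: str = "tissue_class") -> dict:
    """Name the two clusters by their majority known class."""
    ann = ann.set_index("tissue") if "tissue" in ann.columns else ann
    frac = {}
    for lab in ("A", "B"):
        members = assign.members(lab)
        classes = ann.loc[members, class_col]
        n_cancer = int((classes == cancer_class).sum())
        n_control = int((classes == control_class).sum())
        frac[lab] = (n_cancer, n_control)
    # the cluster with the larger share of known cancers is the cancer cluster
    def cancer_share(lab):
        c, m_ = frac[lab]
        return c / (c + m_) if (c + m_) else 0.0

    cancer_label = max(("A", "B"), key=cancer_share)
    control_label = "B" if cancer_label == "A" else "A"
    return {cancer_label: cancer_class, control_label: control_class}


def classify_normals(
    assign: ClusterAssignment,
    ann: pd.DataFrame,
    class_col: str = "tissue_class",
) -> pd.DataFrame:
    """Count each normal-tissue category inside the cancer vs control cluster.

    ``ann`` must annotate every clustered item (column ``tissue`` plus
    ``tissue_class`` in {cancer, ipsilateral, contralateral, mammaplasty}).
    Returns a table indexed by tissue class with columns
    ``in_cancer_cluster`` / ``in_control_cluster``; normals in the cancer
    cluster are the "cancer-like" tissues.

    Raises
    ------
    KeyError
        A clustered item without an annotation.
    """
    table = ann.set_index("tissue") if "tissue" in ann.columns else ann
    unannotated = [i for i in assign.labels.index if i not in table.index]
    if unannotated:
        raise KeyError(f"unannotated item(s): {unannotated}")
    enrichment = _enrich(assign, table.reset_index(), class_col=class_col)
    assign.enrichment = enrichment
    cancer_label = next(k for k, v in enrichment.items() if v == "cancer")

    rows = {}
    for cls in table.loc[assign.labels.index, class_col].unique():
        members = [i for i in assign.labels.index
                   if table.loc[i, class_col] == cls]
        in_cancer = sum(assign.labels[i] == cancer_label for i in members)
        rows[cls] = {
            "n": len(members),
            "in_cancer_cluster": int(in_cancer),
            "in_control_cluster": len(members) - int(in_cancer),
        }
    return pd.DataFrame(rows).T


def subcluster_summary(
    d: Dendrogram,
    assign: ClusterAssignment,
    ann: pd.DataFrame,
    columns: tuple[str, ...] = ("subtype", "histology", "outcome"),
) -> pd.DataFrame:
    """Composition of the two sub-clusters inside the cancer cluster.

    Finds the root child corresponding to the cancer-enriched cluster, cuts
    it into its two children, and tabulates the annotation ``columns``
    (value counts) per sub-cluster.  Columns absent from ``ann`` yield no
    output columns but no failure; a single-item cancer cluster yields one
    sub-cluster of size 1.  No statistical test is attached: the table is
    descriptive.
    """
    table = ann.set_index("tissue") if "tissue" in ann.columns else ann
    if not assign.enrichment:
        assign.enrichment = _enrich(assign, table.reset_index())
    cancer_label = next(k for k, v in assign.enrichment.items() if v == "cancer")
    subtree = d.root.left if cancer_label == "A" else d.root.right

    if subtree.is_leaf:
        groups = {"sub1": subtree.leaves()}
    else:
        groups = {"sub1": subtree.left.leaves(), "sub2": subtree.right.leaves()}

    rows = []
    for name, members in groups.items():
        row: dict[str, object] = {"subcluster": name, "n": len(members)}
        for col in columns:
            if col not in table.columns:
                continue
            counts = table.loc[[m for m in members if m in table.index], col] \
                .dropna().value_counts()
            for val, cnt in counts.items():
                row[f"{col}={val}"] = int(cnt)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subcluster").fillna(0)
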