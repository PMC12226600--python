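"""Within-disease subtyping on the asymmetry index.

Agglomerative-nesting (AGNES) hierarchical clustering of the 1-dimensional
CAI values using Manhattan pairwise dissimilarities and the Ward
(Lance-Williams) merge update, with the number of clusters chosen by the
mean-silhouette criterion.  Cluster 1 is always the higher-mean-CAI
("more asymmetric") cluster.  Subgroups are then characterised against
fluid biomarkers with non-parametric tests on within-disease z-scores.

Rows are sorted by (CAI, subject id) before clustering, so the dendrogram
and labels are invariant to input row order and ties break
deterministically.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "ClusterBiomarkerContrast",
    "CaiClusterModel",
    "cluster_by_cai",
    "contrast_biomarkers",
    "cluster_composition",
]


@dataclass
class ClusterResult:
    """Within-disease cluster assignment with model-selection diagnostics."""

    disease: str
    k: int
    labels: pd.Series = field(repr=False)  # index: subject_id, values: 1..k
    silhouette_by_k: dict[int, float] = field(repr=False)
    cluster_mean_cai: pd.Series = field(repr=False)

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        lines = [f"CAI clustering [{self.disease}]: k = {self.k} (mean silhouette)"]
        for c in sizes.index:
            lines.append(
                f"  cluster {c}: n = {sizes[c]}, mean CAI = {self.cluster_mean_cai[c]:.3f}"
            )
        lines.append(
            "  silhouette by k: "
            + ", ".join(f"{k}: {s:.3f}" for k, s in sorted(self.silhouette_by_k.items()))
        )
        return "\n".join(lines)


@dataclass
class ClusterBiomarkerContrast:
    """Non-parametric cluster contrast for one z-scored biomarker."""

    biomarker: str
    test: str  # "wilcoxon_rank_sum" or "kruskal_wallis"
    statistic: float
    p: float | None
    cluster_mean_z: dict[int, float]
    insufficient: bool = False


class CaiClusterModel:
    """AGNES (Ward update on Manhattan dissimilarities) on 1-D CAI values.

    Parameters
    ----------
    table : DataFrame
        Cohort table; rows are filtered to ``disease`` and the baseline
        visit, and must provide non-missing ``cai``.
    disease : str
        Diagnostic group to cluster (e.g. ``"AD"`` or ``"FTD"``).
    k_range : sequence of int
        Candidate cluster counts (default 2..6); shrunk with a warning when
        the group is too small.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        disease: str,
        k_range: Sequence[int] = tuple(range(2, 7)),
    ) -> None:
        sub = table
        if "group" in table.columns:
            sub = sub[sub["group"] == disease]
        if "visit" in sub.columns:
            sub = sub[sub["visit"] == 1]
        sub = sub.dropna(subset=["cai"])
        if len(sub) < 4:
            raise ValueError(
                f"clustering needs >= 4 subjects with CAI, got {len(sub)} for {disease!r}"
            )
        # deterministic order: sort by value then id, so ties break stably
        sub = sub.sort_values(["cai", "subject_id"], kind="mergesort")
        values = sub["cai"].to_numpy(float)
        if np.allclose(values, values[0]):
            raise ValueError(f"all CAI values identical in {disease!r}; no clustering structure")
        n_distinct = len(np.unique(values))
        max_k = min(max(k_range), len(values) - 1, n_distinct)
        k_range = [k for k in k_range if 2 <= k <= max_k]
        if not k_range:
            raise ValueError("no feasible cluster count in k_range")
        if max(k_range) < 6 and len(values) - 1 < 6:
            warnings.warn(f"k_range shrunk to {k_range} for n = {len(values)}")
        self.disease = disease
        self.k_range = list(k_range)
        self.subject_ids = sub["subject_id"].to_numpy()
        self.values = values

    def fit(self) -> ClusterResult:
        x = self.values.reshape(-1, 1)
        dist = pdist(x, metric="cityblock")
        merge_tree = linkage(dist, method="ward")
        sil: dict[int, float] = {}
        labels_by_k: dict[int, np.ndarray] = {}
        for k in self.k_range:
            lab = fcluster(merge_tree, t=k, criterion="maxclust")
            if len(np.unique(lab)) != k:
                continue
            sil[k] = float(silhouette_score(x, lab, metric="manhattan"))
            labels_by_k[k] = lab
        if not sil:
            raise ValueError("no candidate k produced a valid partition")
        best_k = max(sorted(sil), key=lambda k: sil[k])
        lab = labels_by_k[best_k]
        # relabel so cluster 1 has the highest mean CAI
        means = {c: self.values[lab == c].mean() for c in np.unique(lab)}
        order = sorted(means, key=means.get, reverse=True)
        remap = {old: new for new, old in enumerate(order, start=1)}
        lab = np.array([remap[c] for c in lab])
        labels = pd.Series(lab, index=pd.Index(self.subject_ids, name="subject_id"), name="cluster")
        mean_cai = pd.Series({remap[c]: means[c] for c in means}).sort_index()
        return ClusterResult(
            disease=self.disease,
            k=best_k,
            labels=labels,
            silhouette_by_k=sil,
            cluster_mean_cai=mean_cai,
        )


def cluster_by_cai(
    table: pd.DataFrame, disease: str, k_range: Sequence[int] = tuple(range(2, 7))
) -> ClusterResult:
    """Cluster one disease group on CAI; silhouette picks k; 1 = most asymmetric."""
    return CaiClusterModel(table, disease, k_range).fit()


def contrast_biomarkers(
    table: pd.DataFrame,
    cluster_result: ClusterResult,
    biomarker_columns: Sequence[str],
    bh_adjust: bool = False,
) -> list[ClusterBiomarkerContrast]:
    """Compare z-scored biomarkers between CAI clusters.

    Each biomarker is z-scored within the disease group over its
    non-missing values, then contrasted across clusters with the Wilcoxon
    rank-sum test (two clusters) or Kruskal-Wallis (more).  Biomarkers
    with fewer than 3 non-missing values in any cluster are flagged and
    carry no test.  Raw p-values are reported by default; ``bh_adjust``
    applies a Benjamini-Hochberg correction across the tested biomarkers.
    """
    sub = table
    if "group" in table.columns:
        sub = sub[sub["group"] == cluster_result.disease]
    if "visit" in sub.columns:
        sub = sub[sub["visit"] == 1]
    sub = sub.set_index("subject_id").loc[cluster_result.labels.index]
    clusters = cluster_result.labels
    results: list[ClusterBiomarkerContrast] = []
    for marker in biomarker_columns:
        series = sub[marker]
        ok = series.notna()
        if ok.sum() < 2:
            results.append(
                ClusterBiomarkerContrast(marker, "none", float("nan"), None, {}, insufficient=True)
            )
            continue
        z = pd.Series(np.nan, index=series.index)
        z[ok] = (series[ok] - series[ok].mean()) / series[ok].std(ddof=1)
        groups = []
        mean_z = {}
        insufficient = False
        for c in sorted(clusters.unique()):
            zc = z[(clusters == c) & ok.to_numpy()]
            mean_z[int(c)] = float(zc.mean()) if len(zc) else float("nan")
            if len(zc) < 3:
                insufficient = True
            groups.append(zc.to_numpy())
        if insufficient:
            results.append(
                ClusterBiomarkerContrast(marker, "none", float("nan"), None, mean_z, insufficient=True)
            )
            continue
        if len(groups) == 2:
            res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            test = "wilcoxon_rank_sum"
        else:
            res = sps.kruskal(*groups)
            test = "kruskal_wallis"
        results.append(
            ClusterBiomarkerContrast(
                marker, test, float(res.statistic), float(res.pvalue), mean_z
            )
        )
    if bh_adjust:
        tested = [r for r in results if r.p is not None]
        if tested:
            adj = multipletests([r.p for r in tested], method="fdr_bh")[1]
            for r, p in zip(tested, adj):
                r.p = float(p)
    return results


def cluster_composition(
    cluster_result: ClusterResult, phenotypes: pd.Series
) -> pd.DataFrame:
    """Percentage of each phenotype's subjects falling in each cluster.

    ``phenotypes`` maps subject_id -> phenotype label.  Percentages sum to
    100 across clusters within each phenotype.
    """
    df = pd.DataFrame(
        {
            "cluster": cluster_result.labels,
            "phenotype": phenotypes.reindex(cluster_result.labels.index),
        }
    )
    counts = df.groupby(["phenotype", "cluster"], observed=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=sorted(cluster_result.labels.unique()), fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    out = counts.stack().rename("count").to_frame()
    out["percent"] = pct.stack()
    return out.reset_index()
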