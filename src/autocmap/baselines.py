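"""Classical statistics and baseline classifiers for labelled tables, plus
scoring of record-mode semantic maps against known class labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import davies_bouldin_score, silhouette_score

import networkx as nx

from .dataset import Dataset

__all__ = [
    "ConfusionReport",
    "confusion_report",
    "group_summary",
    "paired_t_profile",
    "r2_vs_class",
    "kmeans_best",
    "pca_lda_loo",
    "graph_label_vote",
]


class ConfusionReport:
    """k×k confusion counts with the two accuracy conventions used for
    small unbalanced clinical samples: the arithmetic mean of the per-class
    correct percentages and the overall (weighted) correct percentage."""

    def __init__(self, counts: pd.DataFrame):
        self.counts = counts

    @classmethod
    def from_labels(cls, predicted, actual) -> "ConfusionReport":
        predicted = list(predicted)
        actual = list(actual)
        if len(predicted) != len(actual):
            raise ValueError("prediction/label length mismatch")
        classes = sorted(set(actual))
        if not set(predicted) & set(classes):
            raise ValueError("predicted labels share no class with actual labels")
        table = pd.DataFrame(0, index=classes,
                             columns=sorted(set(classes) | set(predicted)))
        for p, a in zip(predicted, actual):
            table.loc[a, p] += 1
        return cls(table)

    @property
    def n_records(self) -> int:
        return int(self.counts.to_numpy().sum())

    def per_class_pct(self) -> pd.Series:
        diag = pd.Series(
            [self.counts.loc[c, c] if c in self.counts.columns else 0
             for c in self.counts.index], index=self.counts.index, dtype=float)
        return 100.0 * diag / self.counts.sum(axis=1)

    @property
    def arithmetic_mean_accuracy(self) -> float:
        """Mean of the per-class correct percentages (class-balanced)."""
        return float(self.per_class_pct().mean())

    @property
    def weighted_mean_accuracy(self) -> float:
        """Overall correct percentage (record-weighted)."""
        correct = sum(self.counts.loc[c, c] for c in self.counts.index
                      if c in self.counts.columns)
        return float(100.0 * correct / self.n_records)

    def summary(self) -> str:
        lines = ["Confusion matrix", str(self.counts), ""]
        for c, pct in self.per_class_pct().items():
            lines.append(f"  {c}: {pct:.2f}% correct")
        lines.append(f"  arithmetic mean accuracy: {self.arithmetic_mean_accuracy:.2f}%")
        lines.append(f"  weighted mean accuracy:   {self.weighted_mean_accuracy:.2f}%")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "counts": {str(a): {str(p): int(v) for p, v in row.items()}
                       for a, row in self.counts.iterrows()},
            "per_class_pct": {str(c): float(v) for c, v in self.per_class_pct().items()},
            "arithmetic_mean_accuracy": self.arithmetic_mean_accuracy,
            "weighted_mean_accuracy": self.weighted_mean_accuracy,
        }


def confusion_report(predicted, actual) -> ConfusionReport:
    """Build a :class:`ConfusionReport` from parallel label sequences."""
    return ConfusionReport.from_labels(predicted, actual)


def group_summary(ds: Dataset, variables=None) -> pd.DataFrame:
    """Per-class mean and sample SD (ddof=1) of each quantitative variable.

    Returns a frame indexed by variable with ``mean_<class>``/``sd_<class>``
    columns.  Classes with a single record are rejected (sample SD
    undefined).
    """
    if ds.class_labels is None:
        raise ValueError("dataset has no class labels")
    variables = list(variables) if variables is not None else ds.variable_names
    out = {}
    for label in sorted(ds.class_labels.unique()):
        sub = ds.values.loc[(ds.class_labels == label).to_numpy(), variables]
        if len(sub) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 records")
        out[f"mean_{label}"] = sub.mean()
        out[f"sd_{label}"] = sub.std(ddof=1)
    return pd.DataFrame(out)


def paired_t_profile(a, b) -> tuple[float, float, int]:
    """Paired Student t across a profile of per-variable statistics.

    Compares two equal-length vectors (e.g. the per-variable class means of
    two groups) with a paired t-test; returns ``(t, one-sided p, df)`` where
    the one-sided tail is P(T > t).  Antisymmetric under swapping a and b.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d profiles of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    df = len(diff) - 1
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 0.5, df  # identical profiles: no evidence either way
        raise ValueError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(len(diff)))
    return float(t), float(sps.t.sf(t, df)), df


def r2_vs_class(ds: Dataset, class_indicator: str, variables=None) -> pd.Series:
    """Squared Pearson correlation of each variable with a binary class
    indicator column (the R² of the one-variable linear fit).  Invariant to
    affine rescaling of the variable and to flipping the 0/1 coding."""
    ind = ds.values[class_indicator].to_numpy(float)
    if np.all(ind == ind[0]):
        raise ValueError("class indicator is constant")
    variables = list(variables) if variables is not None else [
        v for v in ds.variable_names if v != class_indicator]
    out = {}
    for v in variables:
        x = ds.values[v].to_numpy(float)
        if x.std() == 0:
            out[v] = 0.0
        else:
            out[v] = float(np.corrcoef(x, ind)[0, 1] ** 2)
    return pd.Series(out, name=f"r2_vs_{class_indicator}")


def kmeans_best(ds: Dataset, k: int = 2, restarts: int = 1000, seed: int = 0,
                silhouette_metric: str = "sqeuclidean"):
    """Best-of-``restarts`` k-means (by within-cluster sum of squares) with
    cluster-validity indexes.

    The silhouette is computed on squared-Euclidean dissimilarities by
    default — the convention of the classic k-means toolboxes in which the
    index was popularised — with plain ``"euclidean"`` available.  Returns
    ``(labels, silhouette, davies_bouldin)``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    if k > ds.n_records:
        raise ValueError("more clusters than records")
    if k == ds.n_records:
        raise ValueError("silhouette undefined with singleton-only clusters")
    arr = ds.to_numpy()
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd").fit(arr)
    labels = pd.Series(km.labels_, index=ds.values.index, name="cluster")
    sil = float(silhouette_score(arr, km.labels_, metric=silhouette_metric))
    db = float(davies_bouldin_score(arr, km.labels_))
    return labels, sil, db


def pca_lda_loo(ds: Dataset, n_components: int = 2) -> ConfusionReport:
    """Leave-one-out PCA→LDA classification.

    For each held-out record the principal components are fitted on the
    remaining records, both are projected, a linear discriminant is fitted
    on the projections and the held-out record classified.
    """
    if ds.class_labels is None:
        raise ValueError("dataset has no class labels")
    if n_components > ds.n_variables:
        raise ValueError("more components than variables")
    arr = ds.to_numpy()
    labels = ds.class_labels.to_numpy()
    n = len(arr)
    preds = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if len(set(labels[mask])) < 2:
            raise ValueError("a class vanished from a training fold")
        pca = PCA(n_components=n_components).fit(arr[mask])
        lda = LinearDiscriminantAnalysis().fit(pca.transform(arr[mask]), labels[mask])
        preds.append(lda.predict(pca.transform(arr[i:i + 1]))[0])
    return ConfusionReport.from_labels(preds, labels)


def graph_label_vote(G: nx.Graph, labels: pd.Series, distances=None) -> ConfusionReport:
    """Classify each record node by the majority label of its neighbours.

    The node itself never votes; ties go to the label of the nearest
    neighbour (smallest edge weight, or smallest entry of ``distances`` if
    given).  Isolated nodes fall back to the global majority label.
    """
    missing = [u for u in G.nodes if u not in labels.index]
    if missing:
        raise ValueError(f"unlabelled nodes: {missing[:5]}")
    global_majority = labels.value_counts().idxmax()
    preds, actual = [], []
    for u in G.nodes:
        nbrs = list(G.neighbors(u))
        if not nbrs:
            preds.append(global_majority)
        else:
            votes = pd.Series([labels[v] for v in nbrs]).value_counts()
            winners = votes[votes == votes.max()].index.tolist()
            if len(winners) == 1:
                preds.append(winners[0])
            else:
                def edge_dist(v):
                    if distances is not None:
                        return float(distances.loc[u, v])
                    return float(G.edges[u, v].get("weight", 1.0))
                preds.append(labels[min(nbrs, key=edge_dist)])
        actual.append(labels[u])
    return ConfusionReport.from_labels(preds, actual)
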