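"""Prediction of remaining population doublings from the LD embedding.

Cells imaged at each passage carry a retrospective integer label: the
cumulative doublings their line still underwent before full growth arrest,
rounded to the nearest whole number.  The predictor embeds cells with the
full discriminant pipeline (z-score -> MRMR top 100 -> PCA -> LDA across the
doubling classes, keeping all ``n_classes - 1`` dimensions) and assigns each
withheld cell the label of the *single-label group* with the smallest mean
distance among its k nearest training points (a deliberately coarse KNN,
k = 400 by default — a large k gives a global view of a heterogeneous
population).  Because single cells within one passage vary widely, the
sample-level estimate is the median of the per-cell predictions, repeated 30
times with fresh random half-sample withholding; accuracy is summarised as
RMSPE and MAE of the mean aggregate prediction per doubling class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .modeling import DiscriminantEmbedding

log = logging.getLogger(__name__)

__all__ = [
    "make_doubling_labels",
    "split_half_sample",
    "CoarseKNNClassifier",
    "coarse_knn_predict",
    "aggregate_score",
    "DoublingsReport",
    "evaluate_doublings",
    "sweep_k",
    "cluster_ages",
]


def make_doubling_labels(
    cells: pd.DataFrame, passage_log: pd.DataFrame
) -> pd.Series:
    """Integer doublings-remaining label per cell.

    ``passage_log`` has columns line_id, passage, cumulative_doublings and
    ends at arrest (the final cumulative value per line is the arrest
    total).  label = round(arrest_total - cumulative_at_imaging); cells of
    one line+passage share a label.
    """
    for col in ("line_id", "passage", "cumulative_doublings"):
        if col not in passage_log.columns:
            raise ValueError(f"passage log missing column {col!r}")
    arrest = passage_log.groupby("line_id")["cumulative_doublings"].max()
    lut = {}
    for _, row in passage_log.iterrows():
        remaining = arrest[row["line_id"]] - row["cumulative_doublings"]
        if remaining < -1e-9:
            raise ValueError(
                f"line {row['line_id']} passage {row['passage']}: cumulative "
                "doublings exceed the arrest total (inconsistent log)"
            )
        lut[(row["line_id"], row["passage"])] = int(round(remaining))
    try:
        labels = [
            lut[(ln, p)] for ln, p in zip(cells["line_id"], cells["passage"])
        ]
    except KeyError as e:
        raise ValueError(f"cell references unknown line/passage {e}") from e
    return pd.Series(labels, index=cells.index, name="doublings_remaining")


def split_half_sample(
    indices: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Withhold floor(n/2) of one class uniformly at random.

    Returns (withheld_test, retained_train) index arrays.
    """
    indices = np.asarray(indices)
    n = len(indices)
    n_test = n // 2
    if n_test == 0:
        warnings.warn("class of 1 cell: nothing withheld", stacklevel=2)
        return indices[:0], indices
    perm = rng.permutation(n)
    return indices[perm[:n_test]], indices[perm[n_test:]]


class CoarseKNNClassifier(ClassifierMixin, BaseEstimator):
    """Closest-average-distance rule over the k nearest training points.

    For a test point, its ``k`` nearest training points (Euclidean) are
    partitioned by label; each label present gets the mean distance of its
    members to the test point, and the label with the smallest mean distance
    wins.  Ties go to the label with more members among the k, then to the
    smaller label value.  ``k`` larger than the training set uses all
    points; ``k=1`` reduces to classic nearest-neighbour classification.
    """

    def __init__(self, k: int = 400):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.X_ = X
        self.classes_, self._y_enc_ = np.unique(y, return_inverse=True)
        self.y_ = y
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = min(self.k, len(self.X_))
        d = cdist(X, self.X_)
        if k < len(self.X_):
            part = np.argpartition(d, k - 1, axis=1)[:, :k]
        else:
            part = np.broadcast_to(np.arange(len(self.X_)), (len(X), len(self.X_)))
        n_classes = len(self.classes_)
        out = np.empty(len(X), dtype=self.classes_.dtype)
        for i in range(len(X)):
            idx = part[i]
            enc = self._y_enc_[idx]
            dist = d[i, idx]
            sums = np.bincount(enc, weights=dist, minlength=n_classes)
            counts = np.bincount(enc, minlength=n_classes)
            present = counts > 0
            means = np.full(n_classes, np.inf)
            means[present] = sums[present] / counts[present]
            best = np.nonzero(means == means.min())[0]
            if len(best) > 1:  # more members, then smaller label value
                best = best[counts[best] == counts[best].max()]
            out[i] = self.classes_[best[0]]
        return out


def coarse_knn_predict(train_coords, train_labels, test_coords, k: int = 400):
    return CoarseKNNClassifier(k=k).fit(train_coords, train_labels).predict(test_coords)


def aggregate_score(predictions) -> float:
    """Median of the per-cell label predictions of one withheld sample."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.size == 0:
        raise ValueError("no predictions to aggregate")
    return float(np.median(predictions))


@dataclass
class DoublingsReport:
    """Sample-level doublings-remaining accuracy summary."""

    classes: np.ndarray  # true doubling values, sorted ascending
    mean_aggregate: np.ndarray  # mean aggregate prediction per class
    interval_low: np.ndarray  # 2.5th percentile of the repeat aggregates
    interval_high: np.ndarray  # 97.5th percentile
    aggregates: np.ndarray  # (repeats, n_classes), NaN where class untestable
    rmspe: float
    mae: float
    k_neighbours: int
    repeats: int
    k_sweep: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_neighbours": self.k_neighbours,
            "repeats": self.repeats,
            "rmspe": float(self.rmspe),
            "mae": float(self.mae),
            "classes": [int(c) for c in self.classes],
            "mean_aggregate": [float(v) for v in self.mean_aggregate],
            "interval_low": [float(v) for v in self.interval_low],
            "interval_high": [float(v) for v in self.interval_high],
            "k_sweep": {str(k): float(v) for k, v in self.k_sweep.items()},
        }

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "doublings_remaining": self.classes,
                "mean_aggregate": self.mean_aggregate,
                "interval_low": self.interval_low,
                "interval_high": self.interval_high,
            }
        )


def _repeat_aggregates(
    X: pd.DataFrame,
    labels: np.ndarray,
    classes: np.ndarray,
    k_values: list[int],
    repeats: int,
    seed: int,
    n_select: int,
    pca_var: float,
    split_fn,
) -> dict[int, np.ndarray]:
    """Aggregate scores per (k, repeat, class); the embedding is refitted on
    the retained cells of every repeat so withheld cells never leak into
    scaling, selection, PCA, LDA or the KNN reference set."""
    per_k = {k: np.full((repeats, len(classes)), np.nan) for k in k_values}
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        test_by_class: dict[int, np.ndarray] = {}
        train_idx: list[np.ndarray] = []
        for c in classes:
            idx = np.nonzero(labels == c)[0]
            te, tr = split_fn(idx, rng)
            test_by_class[c] = te
            train_idx.append(tr)
        train_idx = np.concatenate(train_idx)
        emb = DiscriminantEmbedding(n_select=n_select, pca_var=pca_var).fit(
            X.iloc[train_idx], labels[train_idx]
        )
        z_train = emb.transform(X.iloc[train_idx])
        y_train = labels[train_idx]
        all_test = np.concatenate([test_by_class[c] for c in classes])
        if len(all_test) == 0:
            continue
        z_test = emb.transform(X.iloc[all_test])
        d = cdist(z_test, z_train)
        order = np.argsort(d, axis=1)
        for k in k_values:
            kk = min(k, z_train.shape[0])
            knn = CoarseKNNClassifier(k=kk).fit(z_train, y_train)
            preds = _predict_from_sorted(knn, d, order, kk)
            pos = 0
            for ci, c in enumerate(classes):
                n_te = len(test_by_class[c])
                if n_te == 0:
                    continue
                per_k[k][r, ci] = aggregate_score(preds[pos : pos + n_te])
                pos += n_te
    return per_k


def _predict_from_sorted(knn: CoarseKNNClassifier, d, order, k):
    """Closest-average-distance predictions reusing a precomputed distance
    matrix and its per-row ordering (identical to ``knn.predict``)."""
    n_classes = len(knn.classes_)
    out = np.empty(d.shape[0], dtype=knn.classes_.dtype)
    for i in range(d.shape[0]):
        idx = order[i, :k]
        enc = knn._y_enc_[idx]
        dist = d[i, idx]
        sums = np.bincount(enc, weights=dist, minlength=n_classes)
        counts = np.bincount(enc, minlength=n_classes)
        present = counts > 0
        means = np.full(n_classes, np.inf)
        means[present] = sums[present] / counts[present]
        best = np.nonzero(means == means.min())[0]
        if len(best) > 1:
            best = best[counts[best] == counts[best].max()]
        out[i] = knn.classes_[best[0]]
    return out


def evaluate_doublings(
    X: pd.DataFrame,
    labels,
    k: int = 400,
    repeats: int = 30,
    seed: int = 0,
    n_select: int = 100,
    pca_var: float = 0.99,
    split_fn=None,
) -> DoublingsReport:
    """Repeated half-sample evaluation of the coarse-KNN doublings predictor.

    Per repeat and doubling class, half the class is withheld, the embedding
    refitted on all retained cells, the withheld cells projected and
    predicted, and the class aggregate (median prediction) recorded.  The
    report carries per-class mean aggregates with empirical 95% prediction
    intervals over repeats, and RMSPE / MAE of the mean aggregates.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 3:
        raise ValueError("need >= 3 doubling classes")
    split_fn = split_fn or split_half_sample
    per_k = _repeat_aggregates(
        X, labels, classes, [k], repeats, seed, n_select, pca_var, split_fn
    )
    agg = per_k[k]
    return _summarise(agg, classes, k, repeats)


def _summarise(agg: np.ndarray, classes, k, repeats, k_sweep=None) -> DoublingsReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_agg = np.nanmean(agg, axis=0)
        lo = np.nanpercentile(agg, 2.5, axis=0)
        hi = np.nanpercentile(agg, 97.5, axis=0)
    testable = np.isfinite(mean_agg)
    err = mean_agg[testable] - classes[testable]
    rmspe = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    return DoublingsReport(
        classes=np.asarray(classes),
        mean_aggregate=mean_agg,
        interval_low=lo,
        interval_high=hi,
        aggregates=agg,
        rmspe=rmspe,
        mae=mae,
        k_neighbours=int(k),
        repeats=int(repeats),
        k_sweep=k_sweep or {},
    )


def sweep_k(
    X: pd.DataFrame,
    labels,
    k_grid=(25, 50, 100, 200, 300, 400, 500, 600),
    repeats: int = 30,
    seed: int = 0,
    n_select: int = 100,
    pca_var: float = 0.99,
) -> tuple[dict[int, float], int]:
    """RMSPE as a function of the KNN neighbourhood size.

    Repeat seeds (hence splits and embeddings) are shared across k values,
    so the curve isolates the effect of k.  Returns ({k: rmspe}, argmin_k).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(k_grid) == 0:
        raise ValueError("k_grid must be nonempty")
    k_values = sorted(set(int(k) for k in k_grid))
    per_k = _repeat_aggregates(
        X, labels, classes, k_values, repeats, seed, n_select, pca_var,
        split_half_sample,
    )
    curve = {}
    for k in k_values:
        curve[k] = _summarise(per_k[k], classes, k, repeats).rmspe
    best = min(curve, key=lambda k: (curve[k], k))
    return curve, best


def cluster_ages(
    embedding_coords: np.ndarray,
    labels,
    n_clusters: int = 3,
    seed: int = 0,
    use_dims: int = 2,
):
    """Unsupervised k-means age clusters on the leading LD components.

    Clusters are reindexed by descending mean doublings-remaining (cluster 0
    is the youngest).  Returns (assignments, per-cluster label histograms,
    per-cluster mean label).
    """
    coords = np.asarray(embedding_coords, dtype=float)
    labels = np.asarray(labels)
    if len(coords) < n_clusters:
        raise ValueError("fewer points than clusters")
    sub = coords[:, : min(use_dims, coords.shape[1])]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(sub)
    raw = km.labels_
    means = np.array([labels[raw == c].mean() for c in range(n_clusters)])
    order = np.argsort(-means, kind="stable")
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    assign = remap[raw]
    hists = []
    cluster_means = []
    for c in range(n_clusters):
        vals, counts = np.unique(labels[assign == c], return_counts=True)
        hists.append({int(v): int(n) for v, n in zip(vals, counts)})
        cluster_means.append(float(labels[assign == c].mean()))
    return assign, hists, np.asarray(cluster_means)
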