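"""Supervised classification stack for single-cell spectral phenotypes.

The pipeline mirrors the field's standard hyperspectral-cytometry recipe:
z-scoring, minimum-redundancy-maximum-relevance (MRMR) feature selection,
PCA, then a linear-discriminant projection to ``n_classes - 1`` dimensions;
class imbalance in the *training* fold is handled by ADASYN up-sampling or
random down-sampling; the classifier is a linear/polynomial SVM or an LDA
classifier; accuracy is reported as cross-validated ROC AUC with
sensitivity/specificity at the Youden-optimal threshold.  Nothing from a
test fold ever reaches scaling, selection, embedding, resampling or
classifier fitting.

MRMR here is the MIQ (quotient) greedy variant: relevance is the mutual
information between a feature (10 equal-frequency bins) and the class label;
redundancy is the mean mutual information with already-selected features;
after seeding with the most relevant feature, each step adds
``argmax V(f) / (W(f|S) + eps)`` with deterministic name tie-breaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

__all__ = [
    "MRMRSelector",
    "mrmr_rank",
    "zscore_fit_apply",
    "DiscriminantEmbedding",
    "fit_embedding",
    "ADASYN",
    "adasyn_upsample",
    "downsample_majority",
    "ClassifierSpec",
    "make_classifier",
    "EvaluationReport",
    "auc_from_scores",
    "crossvalidate",
    "HeterogeneityReport",
    "line_heterogeneity",
]


# ---------------------------------------------------------------------------
# mutual information on equal-frequency bins


def _bin_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise a real vector into <= n_bins equal-frequency bins."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, x, side="left")


def _encode(y) -> np.ndarray:
    _, enc = np.unique(np.asarray(y), return_inverse=True)
    return enc


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats between two small-alphabet integer vectors."""
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy MIQ minimum-redundancy-maximum-relevance feature selection.

    Parameters
    ----------
    n_select : int
        Number of features to keep (capped at ``n_features``).
    n_bins : int
        Equal-frequency bins used to discretise features for the mutual
        information estimates.
    epsilon : float
        Guard added to the redundancy denominator of the quotient criterion.

    Attributes
    ----------
    ranking_ : ndarray of int
        Selected feature indices in selection order.
    scores_ : ndarray of float
        Criterion value at each selection step.
    relevance_ : ndarray of float
        MI(feature; class) for every feature.
    """

    def __init__(self, n_select: int = 50, n_bins: int = 10, epsilon: float = 1e-12):
        self.n_select = n_select
        self.n_bins = n_bins
        self.epsilon = epsilon

    def fit(self, X, y):
        names = None
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        y_enc = _encode(y)
        n, p = X.shape
        if self.n_select > p:
            raise ValueError(f"n_select={self.n_select} > n_features={p}")
        if len(np.unique(y_enc)) < 2:
            raise ValueError("need >= 2 classes")
        if names is None:
            names = [f"x{j:05d}" for j in range(p)]
        self.feature_names_in_ = np.asarray(names, dtype=object)

        binned = np.stack([_bin_equal_frequency(X[:, j], self.n_bins) for j in range(p)], axis=1)
        relevance = np.array(
            [_mutual_information(binned[:, j], y_enc) for j in range(p)]
        )
        # candidates examined in name order makes ties deterministic
        name_order = sorted(range(p), key=lambda j: names[j])

        selected: list[int] = []
        scores: list[float] = []
        red_sum = np.zeros(p)
        remaining = set(range(p))
        while len(selected) < self.n_select:
            best_j, best_s = None, -np.inf
            for j in name_order:
                if j not in remaining:
                    continue
                if not selected:
                    s = relevance[j]
                else:
                    s = relevance[j] / (red_sum[j] / len(selected) + self.epsilon)
                if s > best_s:
                    best_j, best_s = j, s
            selected.append(best_j)
            scores.append(best_s)
            remaining.discard(best_j)
            if remaining and len(selected) < self.n_select:
                sel_bin = binned[:, best_j]
                for j in remaining:
                    red_sum[j] += _mutual_information(binned[:, j], sel_bin)
        self.n_features_in_ = p
        self.relevance_ = relevance
        self.ranking_ = np.asarray(selected)
        self.scores_ = np.asarray(scores)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.ranking_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selected_names(self) -> list[str]:
        check_is_fitted(self, "ranking_")
        return [str(self.feature_names_in_[j]) for j in self.ranking_]


def mrmr_rank(table: pd.DataFrame, labels, n_select: int):
    """Ordered (names, scores) of the top ``n_select`` MRMR features."""
    sel = MRMRSelector(n_select=n_select).fit(table, labels)
    return sel.selected_names(), sel.scores_.copy()


# ---------------------------------------------------------------------------
# z-scoring


def zscore_fit_apply(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """Scale train and test with training-set statistics only.

    Zero-SD features are dropped with a warning.  Returns
    (train_scaled, test_scaled, stats_dict).
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    dropped = list(train.columns[sd <= 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features", stacklevel=2)
    keep = [c for c in train.columns if c not in dropped]
    tr = (train[keep] - mean[keep]) / sd[keep]
    te = None if test is None else (test[keep] - mean[keep]) / sd[keep]
    return tr, te, {"mean": mean[keep], "sd": sd[keep], "dropped": dropped}


# ---------------------------------------------------------------------------
# embedding


class DiscriminantEmbedding(TransformerMixin, BaseEstimator):
    """z-score -> MRMR -> PCA -> linear-discriminant projection.

    The projection maximises between-class scatter against within-class
    scatter (generalised eigenproblem); the within-class scatter is
    regularised by ``reg * trace(Sw)/p * I``.  The embedding has
    ``n_classes - 1`` dimensions and is a pure function after fitting.

    Attributes (after ``fit``)
    --------------------------
    kept_features_ : list of str       features surviving the zero-SD drop
    zscore_mean_, zscore_sd_ : ndarray training statistics
    selector_ : MRMRSelector           fitted MRMR ranking
    pca_ : sklearn PCA                 fitted PCA (``pca_var`` retained)
    scalings_ : ndarray                PCA space -> LD coordinates
    eigenvalues_ : ndarray             discriminant eigenvalues (descending)
    classes_ : ndarray
    """

    def __init__(
        self,
        n_select: int = 50,
        pca_var: float = 0.99,
        reg: float = 1e-6,
        n_bins: int = 10,
    ):
        self.n_select = n_select
        self.pca_var = pca_var
        self.reg = reg
        self.n_bins = n_bins

    def fit(self, X, y):
        names = (
            [str(c) for c in X.columns]
            if isinstance(X, pd.DataFrame)
            else None
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        if n <= len(self.classes_):
            raise ValueError("need more rows than classes")
        if names is None:
            names = [f"x{j:05d}" for j in range(p)]

        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance features",
                stacklevel=2,
            )
        self._keep_mask_ = keep
        self.kept_features_ = [nm for nm, k in zip(names, keep) if k]
        self.zscore_mean_ = X[:, keep].mean(axis=0)
        self.zscore_sd_ = X[:, keep].std(axis=0, ddof=1)
        Z = (X[:, keep] - self.zscore_mean_) / self.zscore_sd_

        n_sel = min(self.n_select, Z.shape[1])
        self.selector_ = MRMRSelector(n_select=n_sel, n_bins=self.n_bins).fit(
            pd.DataFrame(Z, columns=self.kept_features_), y
        )
        Zs = Z[:, self.selector_.ranking_]

        max_comp = min(Zs.shape[0] - 1, Zs.shape[1])
        if isinstance(self.pca_var, float) and 0.0 < self.pca_var < 1.0:
            self.pca_ = PCA(n_components=self.pca_var, svd_solver="full")
        elif isinstance(self.pca_var, float):  # 1.0: keep the full rank
            self.pca_ = PCA(n_components=max_comp, svd_solver="full")
        else:  # integer component count, capped
            self.pca_ = PCA(
                n_components=max(min(int(self.pca_var), max_comp), 1),
                svd_solver="full",
            )
        P = self.pca_.fit_transform(Zs)

        # pooled within-class and between-class scatter in PCA space
        d = P.shape[1]
        overall = P.mean(axis=0)
        sw = np.zeros((d, d))
        sb = np.zeros((d, d))
        for c in self.classes_:
            Pc = P[y == c]
            mu = Pc.mean(axis=0)
            diff = Pc - mu
            sw += diff.T @ diff
            delta = (mu - overall)[:, None]
            sb += len(Pc) * (delta @ delta.T)
        sw /= max(n - len(self.classes_), 1)
        sb /= n
        sw_reg = sw + self.reg * (np.trace(sw) / d) * np.eye(d)
        try:
            evals, evecs = linalg.eigh(sb, sw_reg)
        except linalg.LinAlgError as e:  # pragma: no cover
            raise ValueError(f"singular within-class scatter: {e}") from e
        order = np.argsort(evals)[::-1][: len(self.classes_) - 1]
        W = evecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(W.shape[1]):
            i = np.argmax(np.abs(W[:, j]))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        self.scalings_ = W
        self.eigenvalues_ = evals[order]
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "scalings_")
        X = np.asarray(X, dtype=float)
        Z = (X[:, self._keep_mask_] - self.zscore_mean_) / self.zscore_sd_
        Zs = Z[:, self.selector_.ranking_]
        return self.pca_.transform(Zs) @ self.scalings_


def fit_embedding(
    train_table: pd.DataFrame,
    labels,
    n_select: int = 50,
    pca_var_retained: float = 0.99,
) -> DiscriminantEmbedding:
    return DiscriminantEmbedding(n_select=n_select, pca_var=pca_var_retained).fit(
        train_table, labels
    )


# ---------------------------------------------------------------------------
# resampling


class ADASYN(BaseEstimator):
    """Adaptive synthetic oversampling of the minority class (binary).

    Each minority point is weighted by the fraction of majority points among
    its ``k_density`` nearest neighbours; synthetic points are drawn on
    segments between minority points and their minority neighbours,
    allocated proportionally to those weights until the classes balance.
    """

    def __init__(self, k_density: int = 5, random_state: int | None = None):
        self.k_density = k_density
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("ADASYN requires binary labels")
        if counts[0] == counts[1]:
            return X.copy(), y.copy()
        min_label = classes[np.argmin(counts)]
        g = int(counts.max() - counts.min())
        x_min = X[y == min_label]
        n_min = len(x_min)
        if n_min < self.k_density + 1:
            raise ValueError(
                f"minority class has {n_min} points; need >= k_density+1 "
                f"({self.k_density + 1})"
            )
        rng = np.random.default_rng(self.random_state)

        k = min(self.k_density, len(X) - 1)
        nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn_all.kneighbors(x_min)
        neigh_labels = y[idx[:, 1:]]  # self excluded
        r = (neigh_labels != min_label).mean(axis=1)
        if r.sum() == 0:
            warnings.warn(
                "no borderline minority points; uniform ADASYN allocation",
                stacklevel=2,
            )
            r = np.ones(n_min)
        r = r / r.sum()

        alloc = np.floor(r * g).astype(int)
        shortfall = g - alloc.sum()
        if shortfall > 0:
            frac = r * g - alloc
            alloc[np.argsort(-frac, kind="stable")[:shortfall]] += 1

        nn_min = NearestNeighbors(n_neighbors=min(self.k_density + 1, n_min)).fit(x_min)
        _, min_idx = nn_min.kneighbors(x_min)
        synth = []
        for i in np.nonzero(alloc)[0]:
            choices = min_idx[i, 1:]
            for _ in range(alloc[i]):
                z = x_min[rng.choice(choices)] if len(choices) else x_min[i]
                lam = rng.uniform()
                synth.append(x_min[i] + lam * (z - x_min[i]))
        if synth:
            X = np.vstack([X, synth])
            y = np.concatenate([y, np.full(len(synth), min_label, dtype=y.dtype)])
        return X, y


def adasyn_upsample(X, y, k_density: int = 5, seed: int | None = None):
    return ADASYN(k_density=k_density, random_state=seed).fit_resample(X, y)


def downsample_majority(y, seed: int | None = None) -> np.ndarray:
    """Indices of a subset where the majority is down-sampled to match."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("downsampling requires binary labels")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# classifiers and evaluation


@dataclass
class ClassifierSpec:
    kind: str = "linear_svm"  # linear_svm | polynomial_svm | lda
    svm_cost: float = 1.0
    poly_degree: int = 3
    class_weighting: str = "none"  # none | balanced

    def __post_init__(self):
        if self.kind not in ("linear_svm", "polynomial_svm", "lda"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "polynomial_svm" and self.poly_degree < 2:
            raise ValueError("poly_degree must be >= 2")


def make_classifier(spec: ClassifierSpec):
    weight = None if spec.class_weighting == "none" else "balanced"
    if spec.kind == "linear_svm":
        return SVC(kernel="linear", C=spec.svm_cost, class_weight=weight)
    if spec.kind == "polynomial_svm":
        return SVC(
            kernel="poly", degree=spec.poly_degree, C=spec.svm_cost,
            gamma="scale", class_weight=weight,
        )
    return LinearDiscriminantAnalysis()


@dataclass
class EvaluationReport:
    """Cross-validated ROC summary for one binary task."""

    fold_auc: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    confusion: dict
    n_per_class: dict
    resampling: str
    classifier: str

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def sensitivity_mean(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def specificity_mean(self) -> float:
        return float(np.mean(self.fold_specificity))

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "resampling": self.resampling,
            "n_per_class": self.n_per_class,
            "fold_auc": [float(a) for a in self.fold_auc],
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "fold_sensitivity": [float(a) for a in self.fold_sensitivity],
            "sensitivity_mean": self.sensitivity_mean,
            "fold_specificity": [float(a) for a in self.fold_specificity],
            "specificity_mean": self.specificity_mean,
            "confusion": self.confusion,
        }


def auc_from_scores(y_true, scores, pos_label) -> float:
    """ROC AUC of continuous decision values (trapezoidal over the ROC)."""
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=pos_label)
    return float(sk_auc(fpr, tpr))


def _youden(fpr, tpr, thresholds, y_true, scores, pos_label):
    j = np.argmax(tpr - fpr)
    thr = thresholds[j]
    pred_pos = scores >= thr
    is_pos = y_true == pos_label
    tp = int((pred_pos & is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    return sens, spec, {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "threshold": float(thr)}


def crossvalidate(
    X: pd.DataFrame,
    y,
    classifier: ClassifierSpec | None = None,
    embedding: dict | None = None,
    resample: str = "none",
    n_folds: int = 5,
    seed: int = 0,
    cv=None,
) -> EvaluationReport:
    """Stratified cross-validated evaluation of one binary task.

    Per fold the embedding is fitted on the training fold only, the training
    fold (in LD space) is optionally re-balanced, the classifier trained and
    the test fold scored with continuous decision values.  ``cv`` may supply
    explicit (train_idx, test_idx) pairs.
    """
    classifier = classifier or ClassifierSpec()
    embedding = embedding or {}
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("crossvalidate expects a binary task")
    if cv is None:
        small = classes[counts < n_folds]
        if len(small):
            raise ValueError(
                f"class(es) {small.tolist()} have fewer than {n_folds} members"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros(len(y)), y))
    else:
        folds = list(cv)
    pos = classes[1]

    Xv = X.reset_index(drop=True) if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    fold_auc, fold_sens, fold_spec = [], [], []
    pooled_y, pooled_s = [], []
    for f, (tr, te) in enumerate(folds):
        emb = DiscriminantEmbedding(**embedding).fit(Xv.iloc[tr], y[tr])
        ztr, ytr = emb.transform(Xv.iloc[tr]), y[tr]
        if resample == "adasyn":
            _, cts = np.unique(ytr, return_counts=True)
            if cts.min() >= 6:
                ztr, ytr = ADASYN(random_state=seed * 1000 + f).fit_resample(ztr, ytr)
            else:
                warnings.warn(
                    "minority too small for ADASYN; training fold left as is",
                    stacklevel=2,
                )
        elif resample == "downsample":
            idx = downsample_majority(ytr, seed=seed * 1000 + f)
            ztr, ytr = ztr[idx], ytr[idx]
        elif resample != "none":
            raise ValueError(f"unknown resample mode {resample!r}")
        clf = make_classifier(classifier)
        clf.fit(ztr, ytr)
        scores = clf.decision_function(emb.transform(Xv.iloc[te]))
        fpr, tpr, thr = roc_curve(y[te], scores, pos_label=pos)
        fold_auc.append(float(sk_auc(fpr, tpr)))
        s, sp, _ = _youden(fpr, tpr, thr, y[te], scores, pos)
        fold_sens.append(s)
        fold_spec.append(sp)
        pooled_y.append(y[te])
        pooled_s.append(scores)

    pooled_y = np.concatenate(pooled_y)
    pooled_s = np.concatenate(pooled_s)
    fpr, tpr, thr = roc_curve(pooled_y, pooled_s, pos_label=pos)
    _, _, confusion = _youden(fpr, tpr, thr, pooled_y, pooled_s, pos)
    return EvaluationReport(
        fold_auc=fold_auc,
        fold_sensitivity=fold_sens,
        fold_specificity=fold_spec,
        roc_fpr=fpr,
        roc_tpr=tpr,
        confusion=confusion,
        n_per_class={str(c): int(n) for c, n in zip(classes, counts)},
        resampling=resample,
        classifier=classifier.kind,
    )


# ---------------------------------------------------------------------------
# line heterogeneity


@dataclass
class HeterogeneityReport:
    feature_names: list[str]
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float

    @property
    def fraction_significant(self) -> float:
        return float(self.significant.mean())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "fraction_significant": self.fraction_significant,
            "n_features": len(self.feature_names),
            "significant_features": [
                n for n, s in zip(self.feature_names, self.significant) if s
            ],
        }


def line_heterogeneity(
    table: pd.DataFrame,
    line_ids,
    feature_names: list[str] | None = None,
    alpha: float = 0.05,
) -> HeterogeneityReport:
    """Kruskal-Wallis test of per-channel mean intensity across cell lines.

    Benjamini-Hochberg controls the FDR at ``alpha``; the report carries the
    fraction of channel-mean features with significant line differences.
    """
    from statsmodels.stats.multitest import multipletests

    line_ids = np.asarray(line_ids)
    lines, counts = np.unique(line_ids, return_counts=True)
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    if counts.min() < 3:
        raise ValueError("every line needs >= 3 cells")
    if feature_names is None:
        feature_names = [c for c in table.columns if str(c).endswith("_mean")]
    if not feature_names:
        raise ValueError("no channel-mean features found")
    pvals = []
    for name in feature_names:
        groups = [table[name].to_numpy()[line_ids == ln] for ln in lines]
        try:
            _, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            p = 1.0
        pvals.append(p)
    pvals = np.asarray(pvals)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return HeterogeneityReport(
        feature_names=list(map(str, feature_names)),
        pvalues=pvals,
        significant=reject,
        alpha=alpha,
    )
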