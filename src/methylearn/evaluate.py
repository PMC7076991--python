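"""Embedding-space evaluation and score reporting.

Covers the evaluation toolkit around the models: average cosine distances
between labelled groups of embeddings, superclass discovery by cutting an
average-linkage tree over those distances, the v-measure agreement between
two labelings, nonparametric-bootstrap confidence intervals for arbitrary
metrics, standard classification/regression reports, and unsupervised
grouping of CpG features via a low-dimensional embedding + k-means with a
variance filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import confusion_matrix as _sk_confusion

from .arrays import MethylationArray
from .errors import ConfigError, ContractError


# ---------------------------------------------------------------------------
# Group cosine distances + superclassing
# ---------------------------------------------------------------------------

@dataclass
class GroupDistanceMatrix:
    """Mean pairwise cosine distances between (and within) groups."""

    matrix: pd.DataFrame  # symmetric, groups x groups

    @property
    def group_labels(self) -> list[str]:
        return list(self.matrix.index)


def group_cosine_distance(embeddings, labels) -> GroupDistanceMatrix:
    """Entry (g, h) = mean over cross pairs of 1 - cosine similarity;
    the diagonal is the within-group mean over distinct pairs (0 for
    singleton groups)."""
    E = np.asarray(embeddings, dtype=float)
    labels = pd.Series(list(labels))
    if len(labels) != E.shape[0]:
        raise ContractError("labels do not align with embedding rows")
    norms = np.linalg.norm(E, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ContractError(f"zero-norm embedding row at sample index {bad}")
    U = E / norms[:, None]
    D = 1.0 - np.clip(U @ U.T, -1.0, 1.0)

    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ContractError("need >= 2 groups")
    out = np.zeros((len(groups), len(groups)))
    idx = {g: np.flatnonzero((labels == g).to_numpy()) for g in groups}
    for i, g in enumerate(groups):
        for j, h in enumerate(groups):
            if i < j:
                out[i, j] = out[j, i] = D[np.ix_(idx[g], idx[h])].mean()
        gi = idx[g]
        if len(gi) > 1:
            sub = D[np.ix_(gi, gi)]
            out[i, i] = sub[np.triu_indices(len(gi), k=1)].mean()
    return GroupDistanceMatrix(pd.DataFrame(out, index=groups, columns=groups))


def choose_n_superclasses(Z: np.ndarray) -> int:
    """Maximum-curvature (knee) pick on sorted merge heights.

    A standard second-difference knee detector on the linkage merge
    heights, used when the caller does not fix the superclass count.
    """
    heights = Z[:, 2]
    if len(heights) < 3:
        return 2
    d2 = np.diff(heights, 2)
    knee_merge = int(np.argmax(d2)) + 1
    return max(2, len(heights) + 1 - knee_merge)


def superclass_clusters(dm: GroupDistanceMatrix, n_superclasses: int | None = None
                        ) -> pd.Series:
    """Cut an average-linkage tree over the off-diagonal group distances.

    Returns per-group integer superclass labels (1..n).  With
    ``n_superclasses=None`` a knee-point detector chooses the count.
    """
    n_groups = len(dm.group_labels)
    D = dm.matrix.to_numpy().copy()
    np.fill_diagonal(D, 0.0)  # the cut uses only between-group distances
    Z = linkage(squareform(D, checks=False), method="average")
    if n_superclasses is None:
        n_superclasses = min(choose_n_superclasses(Z), n_groups)
    if not 1 <= n_superclasses <= n_groups:
        raise ConfigError(
            f"n_superclasses={n_superclasses} out of [1, {n_groups}]"
        )
    flat = fcluster(Z, t=n_superclasses, criterion="maxclust")
    return pd.Series(flat, index=dm.group_labels, name="superclass")


# ---------------------------------------------------------------------------
# v-measure
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_measure(labels_true, labels_pred) -> float:
    """Harmonic mean of homogeneity and completeness (natural logs).

    homogeneity = 1 - H(C|K)/H(C); completeness = 1 - H(K|C)/H(K); a
    conditional ratio is taken as 0 when the unconditional entropy is 0
    (single-class partition), so two single-class labelings agree at 1.0.
    """
    t = pd.Series(list(labels_true))
    k = pd.Series(list(labels_pred))
    if len(t) != len(k):
        raise ContractError(f"length mismatch: {len(t)} vs {len(k)}")
    n = len(t)
    if n == 0:
        raise ContractError("empty labelings")
    cont = pd.crosstab(t, k).to_numpy().astype(float)
    h_c = _entropy(cont.sum(axis=1))
    h_k = _entropy(cont.sum(axis=0))
    # conditional entropies
    h_c_given_k = 0.0
    for col in cont.T:
        if col.sum() > 0:
            h_c_given_k += (col.sum() / n) * _entropy(col)
    h_k_given_c = 0.0
    for row in cont:
        if row.sum() > 0:
            h_k_given_c += (row.sum() / n) * _entropy(row)
    hom = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    com = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if hom + com == 0:
        return 0.0
    return 2.0 * hom * com / (hom + com)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals and reports
# ---------------------------------------------------------------------------

@dataclass
class ScoreReport:
    metric: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_skipped: int = 0

    def as_dict(self):
        return {
            "metric": self.metric, "point": self.point,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_boot": self.n_boot, "seed": self.seed,
            "n_skipped": self.n_skipped,
        }


def bootstrap_ci(metric, y_true, y_pred, n_boot: int = 1000, seed: int = 0,
                 name: str | None = None) -> ScoreReport:
    """Percentile bootstrap (2.5/97.5) of ``metric(y_true, y_pred)``.

    Sample indices are resampled with replacement ``n_boot`` times;
    resamples on which the metric is undefined (raises, or returns
    non-finite) are skipped and counted.
    """
    if n_boot < 1:
        raise ConfigError(f"n_boot must be >= 1, got {n_boot}")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ContractError("y_true/y_pred must be non-empty and aligned")
    point = float(metric(y_true, y_pred))
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(y_true), size=len(y_true))
        try:
            v = float(metric(y_true[idx], y_pred[idx]))
        except Exception:
            skipped += 1
            continue
        if not np.isfinite(v):
            skipped += 1
            continue
        values.append(v)
    if values:
        lo, hi = np.percentile(values, [2.5, 97.5])
    else:
        lo = hi = point
    return ScoreReport(metric=name or getattr(metric, "__name__", "metric"),
                       point=point, ci_low=float(lo), ci_high=float(hi),
                       n_boot=n_boot, seed=seed, n_skipped=skipped)


def _accuracy(y_true, y_pred):
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def _prf_for(cls):
    def prf(y_true, y_pred):
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return prec, rec, f1
    return prf


def classification_report(y_true, y_prob, class_labels=None, n_boot: int = 1000,
                          seed: int = 0) -> dict:
    """Accuracy, macro precision/recall/F1 (+ per-class breakdown and
    confusion matrix), each with percentile-bootstrap CIs.

    ``y_prob`` may be an (n, k) probability matrix (argmax taken over
    ``class_labels``) or already-predicted labels.  Classes absent from
    y_true are flagged and excluded from the macro average.
    """
    y_true = np.asarray([str(v) for v in y_true])
    y_prob = np.asarray(y_prob)
    if y_prob.ndim == 2:
        if class_labels is None:
            raise ConfigError("class_labels required with a probability matrix")
        class_labels = [str(c) for c in class_labels]
        y_pred = np.asarray(class_labels)[y_prob.argmax(axis=1)]
    else:
        y_pred = np.asarray([str(v) for v in y_prob])
        if class_labels is None:
            class_labels = sorted(set(y_true) | set(y_pred))
        class_labels = [str(c) for c in class_labels]

    present = [c for c in class_labels if (y_true == c).any()]
    absent = [c for c in class_labels if c not in present]

    def macro_f1(t, p):
        vals = [c for c in present if (t == c).any()]
        if not vals:
            raise ValueError("no present class in resample")
        return float(np.mean([_prf_for(c)(t, p)[2] for c in vals]))

    def macro_precision(t, p):
        vals = [c for c in present if (t == c).any()]
        return float(np.mean([_prf_for(c)(t, p)[0] for c in vals]))

    def macro_recall(t, p):
        vals = [c for c in present if (t == c).any()]
        return float(np.mean([_prf_for(c)(t, p)[1] for c in vals]))

    reports = {
        "accuracy": bootstrap_ci(_accuracy, y_true, y_pred, n_boot, seed, "accuracy"),
        "macro_precision": bootstrap_ci(macro_precision, y_true, y_pred, n_boot, seed, "macro_precision"),
        "macro_recall": bootstrap_ci(macro_recall, y_true, y_pred, n_boot, seed, "macro_recall"),
        "macro_f1": bootstrap_ci(macro_f1, y_true, y_pred, n_boot, seed, "macro_f1"),
    }
    per_class = {}
    for c in present:
        prec, rec, f1 = _prf_for(c)(y_true, y_pred)
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1,
                        "support": int((y_true == c).sum())}
    cm = _sk_confusion(y_true, y_pred, labels=class_labels)
    return {
        "scores": reports,
        "per_class": per_class,
        "absent_classes": absent,
        "confusion_matrix": pd.DataFrame(cm, index=class_labels, columns=class_labels),
    }


def regression_report(y_true, y_pred, n_boot: int = 1000, seed: int = 0) -> dict:
    """R^2, MAE and MSE with percentile-bootstrap CIs."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)

    def r2(t, p):
        ss_res = np.sum((t - p) ** 2)
        ss_tot = np.sum((t - t.mean()) ** 2)
        if ss_tot == 0:
            return math.nan
        return float(1.0 - ss_res / ss_tot)

    def mae(t, p):
        return float(np.mean(np.abs(t - p)))

    def mse(t, p):
        return float(np.mean((t - p) ** 2))

    return {
        "scores": {
            "r2": bootstrap_ci(r2, y_true, y_pred, n_boot, seed, "r2"),
            "mae": bootstrap_ci(mae, y_true, y_pred, n_boot, seed, "mae"),
            "mse": bootstrap_ci(mse, y_true, y_pred, n_boot, seed, "mse"),
        }
    }


# ---------------------------------------------------------------------------
# CpG feature grouping
# ---------------------------------------------------------------------------

def cluster_cpg_features(arr: MethylationArray, embed_dims: int = 6,
                         n_clusters: int = 25, variance_cutoff: float = 1.0,
                         seed: int = 0) -> pd.Series:
    """Group CpGs with shared profiles across samples.

    The transposed beta matrix (one row per CpG) is projected to
    ``embed_dims`` dimensions with UMAP, partitioned with k-means into
    ``n_clusters``, and clusters whose embedding variance (trace of the
    per-cluster covariance) exceeds ``variance_cutoff`` are dropped —
    their CpGs stay unassigned (label -1).  Returns a Series mapping
    cpg_id -> cluster label.
    """
    if n_clusters > arr.n_cpgs:
        raise ConfigError(f"n_clusters={n_clusters} exceeds {arr.n_cpgs} CpGs")
    import umap  # deferred: numba compilation is slow at import

    X = arr.values.T  # CpGs as observations
    reducer = umap.UMAP(n_components=embed_dims, random_state=seed,
                        n_jobs=1, min_dist=0.0)
    emb = reducer.fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    raw = km.fit_predict(emb)
    labels = raw.copy()
    for c in range(n_clusters):
        members = emb[raw == c]
        if members.shape[0] and members.var(axis=0).sum() > variance_cutoff:
            labels[raw == c] = -1
    return pd.Series(labels, index=arr.cpg_ids, name="cpg_cluster")
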