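"""Per-CpG Shapley attribution of model predictions.

Shapley values phi_j assign each CpG its average marginal contribution to
a prediction, relative to a base value phi_0 = E[f] over a background set;
they satisfy local accuracy (phi_0 + sum_j phi_j = f(x)), symmetry and the
dummy axiom.  Three estimators of the interventional game
v(S) = E_b[f(x_S, b_{not S})] are provided:

* ``exact`` — full coalition enumeration (2^p subsets, guarded to p <= 20);
* ``kernel`` — the weighted-least-squares approximation on coalition
  indicator vectors (exact when all coalitions are enumerated);
* ``gradient`` — expected gradients: E_{b, a~U(0,1)}[(x - b) *
  grad f(b + a(x - b))], which converges to the Shapley value on
  multilinear models and approximates it elsewhere.

For classifiers the output of interest is the predicted class's
pre-softmax logit, per sample.  Downstream helpers aggregate attributions
by condition, measure top-k overlap against reference CpG sets, cluster
condition profiles by correlation distance, and test rank concordance
against external (EWAS-style) CpG rankings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import h5py
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata

from .arrays import MethylationArray
from .errors import ConfigError, ContractError, InsufficientOverlapError

EXACT_MAX_FEATURES = 20


# ---------------------------------------------------------------------------
# Core estimators (generic callables; model plumbing below)
# ---------------------------------------------------------------------------

def _coalition_values(f, x: np.ndarray, background: np.ndarray,
                      masks: np.ndarray) -> np.ndarray:
    """v(S) = mean over background rows of f with features in S set to x."""
    n_bg = background.shape[0]
    out = np.empty(len(masks))
    for i, mask in enumerate(masks):
        comp = background.copy()
        comp[:, mask] = x[mask]
        out[i] = float(np.mean(f(comp)))
    _ = n_bg
    return out


def exact_shapley(f, x, background) -> tuple[np.ndarray, float]:
    """Full-enumeration Shapley values for one sample.

    Returns (phi, base) with base = mean f(background).  Complexity is
    O(2^p * n_background); refused for p > 20.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.shape[0]
    if p > EXACT_MAX_FEATURES:
        raise ConfigError(
            f"exact enumeration refused for p={p} > {EXACT_MAX_FEATURES} features"
        )
    # v for every subset, keyed by bitmask
    v = np.empty(2 ** p)
    for code in range(2 ** p):
        mask = np.array([(code >> j) & 1 for j in range(p)], dtype=bool)
        comp = background.copy()
        comp[:, mask] = x[mask]
        v[code] = float(np.mean(f(comp)))
    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for subset in combinations(others, size):
                code = sum(1 << i for i in subset)
                phi[j] += w * (v[code | (1 << j)] - v[code])
    return phi, float(v[0])


def kernel_shapley(f, x, background, n_coalitions: int | None = None,
                   seed: int = 0) -> tuple[np.ndarray, float]:
    """Weighted-regression Shapley estimate for one sample.

    All 2^p - 2 proper coalitions are enumerated when feasible (then the
    estimate equals exact enumeration up to solver precision); otherwise
    ``n_coalitions`` masks are drawn with the Shapley kernel size
    distribution.  The efficiency constraint sum phi = f(x) - base is
    enforced by elimination.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.shape[0]
    if p == 1:
        base = float(np.mean(f(background)))
        return np.array([float(np.mean(f(x[None, :]))) - base]), base

    full = 2 ** p - 2
    budget = n_coalitions if n_coalitions is not None else 2 * p + 2048
    if full <= budget:
        masks = []
        for code in range(1, 2 ** p - 1):
            masks.append(np.array([(code >> j) & 1 for j in range(p)], dtype=bool))
        Z = np.array(masks)
    else:
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, p)
        size_w = (p - 1) / (sizes * (p - sizes))
        size_w = size_w / size_w.sum()
        rows = []
        for _ in range(budget):
            s = int(rng.choice(sizes, p=size_w))
            idx = rng.choice(p, size=s, replace=False)
            z = np.zeros(p, dtype=bool)
            z[idx] = True
            rows.append(z)
        Z = np.array(rows)

    base = float(np.mean(f(background)))
    fx = float(np.mean(f(x[None, :])))
    v = _coalition_values(f, x, background, list(Z))

    sizes = Z.sum(axis=1)
    with np.errstate(divide="ignore"):
        w = (p - 1) / (
            np.array([math.comb(p, int(s)) for s in sizes]) * sizes * (p - sizes)
        )
    if full > budget:
        w = np.ones_like(w)  # sampling already followed the kernel law

    # eliminate phi_p via the efficiency constraint
    zf = Z.astype(float)
    A = zf[:, :-1] - zf[:, -1:]
    y = v - base - zf[:, -1] * (fx - base)
    sw = np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(A * sw, y * sw.ravel(), rcond=None)
    phi = np.empty(p)
    phi[:-1] = coef
    phi[-1] = (fx - base) - coef.sum()
    return phi, base


def gradient_shapley(f, grad_f, x, background, n_draws: int = 200,
                     seed: int = 0) -> tuple[np.ndarray, float]:
    """Expected-gradients estimate for one sample.

    Draws (background row b, interpolation a ~ U(0,1)) pairs and averages
    (x - b) * grad f evaluated at b + a (x - b).  ``grad_f(X) -> (n, p)``;
    if None, central finite differences of ``f`` are used.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.shape[0]
    rng = np.random.default_rng(seed)
    bidx = rng.integers(0, background.shape[0], size=n_draws)
    alphas = rng.uniform(size=n_draws)
    B = background[bidx]
    points = B + alphas[:, None] * (x[None, :] - B)
    if grad_f is None:
        eps = 1e-5
        grads = np.empty((n_draws, p))
        for j in range(p):
            up = points.copy()
            dn = points.copy()
            up[:, j] += eps
            dn[:, j] -= eps
            grads[:, j] = (np.asarray(f(up)) - np.asarray(f(dn))) / (2 * eps)
    else:
        grads = np.asarray(grad_f(points))
    phi = ((x[None, :] - B) * grads).mean(axis=0)
    base = float(np.mean(f(background)))
    return phi, base


# ---------------------------------------------------------------------------
# ShapleyData
# ---------------------------------------------------------------------------

@dataclass
class ShapleyData:
    """Signed per-sample, per-CpG attributions with group metadata."""

    scores: np.ndarray          # n_samples x n_cpgs
    base_values: np.ndarray     # expected model output over background, per sample
    cpg_ids: list[str]
    sample_ids: list[str]
    group_col: str | None = None
    groups: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.base_values = np.broadcast_to(
            np.asarray(self.base_values, dtype=float), (self.scores.shape[0],)
        ).copy()
        if not np.isfinite(self.scores).all():
            raise ContractError("attribution scores must be finite")

    def mean_abs_rank(self) -> pd.Series:
        """Rank of mean |score| per CpG (rank 1 = largest; ties averaged)."""
        mean_abs = np.abs(self.scores).mean(axis=0)
        return pd.Series(rankdata(-mean_abs, method="average"), index=self.cpg_ids)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = "1"
            f.create_dataset("scores", data=self.scores.astype(np.float32))
            f.create_dataset("base_values", data=self.base_values)
            sdt = h5py.string_dtype()
            f.create_dataset("cpg_ids", data=np.array(self.cpg_ids, dtype=object), dtype=sdt)
            f.create_dataset("sample_ids", data=np.array(self.sample_ids, dtype=object), dtype=sdt)
            if self.group_col:
                f.attrs["group_col"] = self.group_col
                f.create_dataset("groups",
                                 data=np.array([str(g) for g in self.groups], dtype=object),
                                 dtype=sdt)
        return path


def load_shapley_data(path) -> ShapleyData:
    """Read a ShapleyData container written by :meth:`ShapleyData.save`."""
    with h5py.File(path, "r") as f:
        scores = np.asarray(f["scores"], dtype=float)
        base = np.asarray(f["base_values"], dtype=float)
        dec = lambda s: s.decode() if isinstance(s, bytes) else str(s)
        cpgs = [dec(s) for s in f["cpg_ids"]]
        samples = [dec(s) for s in f["sample_ids"]]
        group_col = str(f.attrs["group_col"]) if "group_col" in f.attrs else None
        groups = None
        if "groups" in f:
            groups = pd.Series([dec(s) for s in f["groups"]], index=samples)
    return ShapleyData(scores=scores, base_values=base, cpg_ids=cpgs,
                       sample_ids=samples, group_col=group_col, groups=groups)


@dataclass
class GroupAttribution:
    """Per-condition mean attribution profiles (groups x CpGs)."""

    table: pd.DataFrame  # index = group labels, columns = cpg ids

    @property
    def group_labels(self) -> list[str]:
        return list(self.table.index)


def produce_shapley_data(model, arr: MethylationArray, method: str,
                         background: MethylationArray, n_background: int = 100,
                         seed: int = 0, group_col: str | None = None,
                         n_draws: int = 200) -> ShapleyData:
    """Attribute each test sample's prediction to its CpGs.

    ``model`` is a fine-tune model; for classifiers the output of interest
    is the predicted class's logit, for (multi-output) regression the first
    output (or the summed outputs of interest can be attributed by calling
    per output).  ``background`` should come from the training split; a
    seeded subsample of ``n_background`` rows marginalises absent features.
    """
    if method not in ("exact", "kernel", "gradient"):
        raise ConfigError(f"method must be exact|kernel|gradient, got {method!r}")
    if background.n_samples == 0:
        raise ConfigError("background must be non-empty")
    if arr.cpg_ids != background.cpg_ids:
        raise ContractError("test and background CpG sets differ")
    p = arr.n_cpgs
    if method == "exact" and p > EXACT_MAX_FEATURES:
        raise ConfigError(
            f"exact enumeration refused for {p} CpGs (> {EXACT_MAX_FEATURES})"
        )
    rng = np.random.default_rng(seed)
    nb = min(n_background, background.n_samples)
    bg_idx = rng.choice(background.n_samples, size=nb, replace=False)
    B = background.values[bg_idx]
    X = arr.values

    # output index per sample: predicted class for classifiers, 0 otherwise
    if model.task.kind == "classification":
        out_idx = model.predict_proba(arr).argmax(axis=1)
    else:
        out_idx = np.zeros(arr.n_samples, dtype=int)

    scores = np.empty((arr.n_samples, p))
    bases = np.empty(arr.n_samples)
    for i in range(arr.n_samples):
        k = int(out_idx[i])

        def f(M, _k=k):
            return model.raw_outputs(M)[:, _k]

        if method == "exact":
            phi, base = exact_shapley(f, X[i], B)
        elif method == "kernel":
            phi, base = kernel_shapley(f, X[i], B, seed=seed + i)
        else:
            def grad_f(M, _k=k):
                return model.input_gradients(M, _k)

            phi, base = gradient_shapley(f, grad_f, X[i], B,
                                         n_draws=n_draws, seed=seed + i)
        scores[i] = phi
        bases[i] = base

    groups = arr.pheno[group_col] if group_col else None
    return ShapleyData(scores=scores, base_values=bases, cpg_ids=arr.cpg_ids,
                       sample_ids=arr.sample_ids, group_col=group_col,
                       groups=groups)


# ---------------------------------------------------------------------------
# Aggregation and downstream analyses
# ---------------------------------------------------------------------------

def aggregate_by_group(shap: ShapleyData, groups=None) -> GroupAttribution:
    """Average attribution rows by condition (first-appearance group order)."""
    if groups is None:
        groups = shap.groups
    if groups is None:
        raise ContractError("no group labels supplied or stored")
    labels = pd.Series(list(groups), index=shap.sample_ids)
    if len(labels) != len(shap.sample_ids):
        raise ContractError("group labels do not align with samples")
    order = list(dict.fromkeys(labels))
    rows = {g: shap.scores[(labels == g).to_numpy()].mean(axis=0) for g in order}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=shap.cpg_ids)
    return GroupAttribution(table=table.loc[order])


def top_k_overlap(ga: GroupAttribution, group, k: int, reference,
                  ranking: str = "signed") -> float:
    """|top-k CpGs by attribution  intersect  reference| / |reference|.

    ``ranking="signed"`` ranks by signed score descending (default, the
    hyper-methylation-driving CpGs); ``"abs"`` ranks by |score|.  Ties are
    broken by CpG order.
    """
    reference = set(reference)
    if not reference:
        raise ConfigError("reference CpG set is empty")
    if k > ga.table.shape[1]:
        raise ConfigError(f"k={k} exceeds {ga.table.shape[1]} CpGs")
    row = ga.table.loc[group].to_numpy()
    keys = -row if ranking == "signed" else -np.abs(row)
    top = np.argsort(keys, kind="stable")[:k]
    top_ids = {ga.table.columns[i] for i in top}
    return len(top_ids & reference) / len(reference)


def correlation_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; zero-variance rows sit at the
    maximum distance 2 (with a warning)."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    D = np.full((n, n), 2.0)
    np.fill_diagonal(D, 0.0)
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn("zero-variance attribution row(s); distance set to 2")
    ok = ~degenerate
    if ok.any():
        C = centered[ok] / norms[ok, None]
        corr = np.clip(C @ C.T, -1.0, 1.0)
        sub = 1.0 - corr
        D[np.ix_(ok, ok)] = sub
    np.fill_diagonal(D, 0.0)
    return D


def attribution_dendrogram(ga: GroupAttribution):
    """Average-linkage tree over groups, correlation distance between
    attribution profiles.  Returns (scipy linkage matrix, group labels)."""
    if ga.table.shape[0] < 2:
        raise ContractError("need >= 2 groups to build a dendrogram")
    D = correlation_distance_matrix(ga.table.to_numpy())
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, ga.group_labels


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    tree = to_tree(Z)

    def rec(node):
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - (node.left.dist if not node.left.is_leaf() else 0.0)
        dr = node.dist - (node.right.dist if not node.right.is_leaf() else 0.0)
        return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"

    return rec(tree) + ";"


def rank_concordance(shap: ShapleyData, external_ranking) -> tuple[float, float]:
    """Pearson r (+ two-sided non-correlation p) between internal SHAP ranks
    and an external CpG ranking.

    The internal ranking is the rank of the per-CpG mean |score| across
    samples (rank 1 = largest, ties averaged), restricted to the CpGs the
    two rankings share.  ``external_ranking`` is an ordered iterable of CpG
    ids (position = rank) or a mapping cpg_id -> rank.
    """
    internal = shap.mean_abs_rank()
    if isinstance(external_ranking, dict):
        ext = pd.Series(external_ranking, dtype=float)
    else:
        ids = list(external_ranking)
        ext = pd.Series(np.arange(1, len(ids) + 1, dtype=float), index=ids)
    common = [c for c in internal.index if c in ext.index]
    if len(common) < 3:
        raise InsufficientOverlapError(
            f"only {len(common)} CpGs shared between rankings (need >= 3)"
        )
    a = rankdata(internal.loc[common].to_numpy())
    b = rankdata(ext.loc[common].to_numpy())
    r, pval = pearsonr(a, b)
    return float(r), float(pval)
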