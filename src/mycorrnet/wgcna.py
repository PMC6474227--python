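"""Weighted co-expression module detection.

The classic pipeline: soft-thresholded correlation adjacency ->
topological overlap matrix (TOM) -> average-linkage clustering of the
TOM dissimilarity -> tree cut just below the dissimilarity saturation
plateau -> module eigengenes -> merging of modules with similar
eigengenes.

Two entry points are provided: per-step functions operating on
gene x sample DataFrames / ExpressionMatrix, and a scikit-learn style
estimator :class:`CoexpressionModules` that clusters the *columns* of a
samples x genes matrix (in the spirit of
:class:`sklearn.cluster.FeatureAgglomeration`) and whose ``transform``
maps samples onto module eigengene scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .containers import ExpressionMatrix

__all__ = [
    "ModulePartition",
    "CoexpressionModules",
    "adjacency",
    "topological_overlap",
    "cluster_genes",
    "dynamic_cut",
    "module_eigengenes",
    "merge_modules",
    "module_membership",
    "detect_modules",
]


@dataclass
class ModulePartition:
    """Gene -> module assignment with eigengenes and memberships.

    ``labels`` maps every gene to a module id (0 = unassigned);
    ``eigengenes`` is samples x modules (columns ``M1``.. ordered by
    decreasing module size); ``kme`` is genes x modules Pearson
    correlation of each gene with each eigengene.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame
    variance_explained: pd.Series
    min_size: int
    merge_cut: float

    @property
    def n_modules(self) -> int:
        return self.eigengenes.shape[1]

    def members(self, module: int) -> pd.Index:
        return self.labels.index[(self.labels == module).to_numpy()]


# ---------------------------------------------------------------------------
# numeric core (genes x samples ndarrays)


def _values(expr) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(expr, ExpressionMatrix):
        return expr.values.to_numpy(dtype=float), expr.gene_ids, expr.sample_ids
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), expr.index, expr.columns
    arr = np.asarray(expr, dtype=float)
    return (
        arr,
        pd.RangeIndex(arr.shape[0]),
        pd.RangeIndex(arr.shape[1]),
    )


def _adjacency(vals: np.ndarray, power: float, mode: str) -> np.ndarray:
    if vals.shape[1] < 3:
        raise ValueError("adjacency needs >= 3 samples")
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(vals)
    if np.isnan(cor).any():
        bad = np.flatnonzero(np.isnan(cor).any(axis=1))
        raise ValueError(f"NaN correlations for gene rows {bad[:5].tolist()}")
    cor = np.clip(cor, -1.0, 1.0)
    if mode == "unsigned":
        adj = np.abs(cor) ** power
    elif mode == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(adj, 1.0)
    return adj


def _tom(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    L_ij the shared-neighbor sum and k the connectivity; TOM_ii = 1.
    """
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have zero diagonal")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _linkage(d: np.ndarray) -> np.ndarray:
    d = _check_dissimilarity(d)
    return _average_linkage(squareform(d, checks=False))


def _height_cut(Z: np.ndarray, min_size: int, cut_quantile: float) -> np.ndarray:
    """Tree cut of the TOM dendrogram: branches below a near-top height.

    The tree is cut at ``hmin + cut_quantile * (hmax - hmin)`` of the
    merge-height range, just below the uninformative top of the tree
    where unrelated genes join at dissimilarity ~1. Resulting clusters
    with at least ``min_size`` leaves become modules; everything else is
    unassigned (label 0). Modules are renumbered 1..K by decreasing
    size, ties by smallest leaf index.

    With soft-thresholded TOM dissimilarities, genuine modules are
    complete just below the saturation plateau while unrelated genes
    only connect on it, so this single cut separates modules from noise
    (noise clusters stay far below any sensible ``min_size``).
    """
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if n < 2:
        return labels
    if min_size > n:
        warnings.warn("min_size exceeds number of genes: all unassigned", stacklevel=2)
        return labels
    heights = Z[:, 2]
    cut = heights.min() + cut_quantile * (heights.max() - heights.min())
    flat = fcluster(Z, t=cut, criterion="distance")
    sizes = np.bincount(flat)
    candidates = [
        np.flatnonzero(flat == c).tolist()
        for c in range(1, len(sizes))
        if sizes[c] >= min_size
    ]
    candidates.sort(key=lambda leaves: (-len(leaves), min(leaves)))
    for k, leaves in enumerate(candidates, start=1):
        labels[leaves] = k
    return labels


def _standardize_rows(vals: np.ndarray) -> np.ndarray:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (vals - mean) / sd


def _eigengene(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a standardized genes x samples block.

    Returns (eigengene over samples with unit variance, gene weights
    such that ``eigengene = weights @ z``, variance explained). Sign is
    anchored so the mean correlation with member genes is positive.
    """
    n_samples = z.shape[1]
    if z.shape[0] == 1:
        e = z[0].copy()
        sd = e.std()
        if sd > 0:
            e = e / sd
        return e, np.asarray([1.0 / (z[0].std() or 1.0)]), 1.0
    U, S, Vt = np.linalg.svd(z, full_matrices=False)
    ve = float(S[0] ** 2 / np.sum(S**2)) if S.sum() > 0 else 0.0
    v = Vt[0]
    s = S[0] if S[0] > 0 else 1.0
    e = v * np.sqrt(n_samples)
    w = U[:, 0] * np.sqrt(n_samples) / s
    # anchor: mean correlation with members > 0
    anchor = float(z.sum(axis=0) @ e)
    if anchor < 0 or (anchor == 0 and e[np.argmax(np.abs(e))] < 0):
        e, w = -e, -w
    return e, w, ve


def _corr_cols_rows(e_cols: np.ndarray, g_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of g_rows with each column of e_cols."""
    n = g_rows.shape[1]
    zg = _standardize_rows(g_rows)
    ze = _standardize_rows(e_cols.T).T
    return (zg @ ze) / n


# ---------------------------------------------------------------------------
# public per-step functions


def adjacency(expr, power: float = 12, mode: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency.

    ``unsigned``: ``|cor|^power``; ``signed``: ``((1 + cor)/2)^power``.
    Zero-variance genes are dropped with a warning before correlation.
    """
    vals, genes, _ = _values(expr)
    var = vals.var(axis=1)
    if (var == 0).any():
        dropped = genes[var == 0]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s) before adjacency",
            stacklevel=2,
        )
        vals, genes = vals[var > 0], genes[var > 0]
    adj = _adjacency(vals, power, mode)
    return pd.DataFrame(adj, index=genes, columns=genes)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency; 1 - TOM is the
    clustering dissimilarity."""
    a = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square symmetric")
    tom = _tom(a)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return pd.DataFrame(tom)


def cluster_genes(dissimilarity) -> np.ndarray:
    """Average-linkage agglomerative clustering; returns a scipy linkage
    matrix over the input rows."""
    d = dissimilarity.to_numpy() if isinstance(dissimilarity, pd.DataFrame) else dissimilarity
    return _linkage(np.asarray(d, dtype=float))


def dynamic_cut(
    linkage_matrix: np.ndarray, min_size: int = 50, cut_quantile: float = 0.995
) -> np.ndarray:
    """Module labels (0 = unassigned) from the near-top tree cut."""
    return _height_cut(np.asarray(linkage_matrix, dtype=float), min_size, cut_quantile)


def module_eigengenes(expr, labels) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes (first PCs) and per-module variance explained.

    Returns a samples x modules DataFrame (columns ``M<k>``) and a
    Series of variance explained. Eigengenes have unit variance over
    samples with the sign anchored so mean member correlation is
    positive.
    """
    vals, genes, samples = _values(expr)
    lab = _align_labels(labels, genes)
    z = _standardize_rows(vals)
    mods = sorted(set(lab[lab > 0]))
    me = {}
    ve = {}
    for m in mods:
        e, _, v = _eigengene(z[lab == m])
        me[f"M{m}"] = e
        ve[f"M{m}"] = v
    me_df = pd.DataFrame(me, index=samples)
    return me_df, pd.Series(ve, dtype=float)


def _align_labels(labels, genes: pd.Index) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.reindex(genes).fillna(0).astype(int).to_numpy()
    return np.asarray(labels, dtype=int)


def merge_modules(expr, labels, merge_cut: float = 0.1, min_size: int = 0) -> ModulePartition:
    """Iteratively merge modules whose eigengenes are nearly collinear.

    Eigengenes are clustered with average linkage on ``1 - cor``; all
    clusters joined below ``merge_cut`` are merged and eigengenes
    recomputed, until no pair falls below the cut. Unassigned genes
    (label 0) never participate. Final modules are renumbered by
    decreasing size.
    """
    vals, genes, samples = _values(expr)
    lab = _align_labels(labels, genes).copy()
    z = _standardize_rows(vals)

    while True:
        mods = sorted(set(lab[lab > 0]))
        if len(mods) < 2:
            break
        es = np.column_stack([_eigengene(z[lab == m])[0] for m in mods])
        cor = np.corrcoef(es.T)
        d = _check_dissimilarity(1.0 - np.clip(cor, -1.0, 1.0))
        Zl = _linkage(d)
        groups = fcluster(Zl, t=merge_cut, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        mod_to_group = dict(zip(mods, groups))
        group_min: dict[int, int] = {}
        for m, g in zip(mods, groups):
            group_min[g] = min(group_min.get(g, m), m)
        lab = np.asarray(
            [group_min[mod_to_group[m]] if m > 0 else 0 for m in lab], dtype=int
        )

    # renumber by decreasing size (ties: first-seen order)
    mods = sorted(set(lab[lab > 0]))
    sizes = {m: int((lab == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    renum = {m: i + 1 for i, m in enumerate(order)}
    lab = np.asarray([renum.get(m, 0) for m in lab])

    me_df, ve = module_eigengenes(
        pd.DataFrame(vals, index=genes, columns=samples), pd.Series(lab, index=genes)
    )
    kme = module_membership(pd.DataFrame(vals, index=genes, columns=samples), me_df)
    return ModulePartition(
        labels=pd.Series(lab, index=genes, name="module"),
        eigengenes=me_df,
        kme=kme,
        variance_explained=ve,
        min_size=min_size,
        merge_cut=merge_cut,
    )


def module_membership(expr, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every eigengene."""
    vals, genes, _ = _values(expr)
    var = vals.var(axis=1)
    kme = _corr_cols_rows(eigengenes.to_numpy(dtype=float), vals)
    kme[var == 0] = np.nan
    return pd.DataFrame(kme, index=genes, columns=eigengenes.columns)


# ---------------------------------------------------------------------------
# estimator


class CoexpressionModules(TransformerMixin, ClusterMixin, BaseEstimator):
    """Detect co-expression modules among the columns of ``X``.

    scikit-learn estimator in the style of ``FeatureAgglomeration``:
    ``fit`` takes ``X`` of shape (n_samples, n_genes), clusters genes
    into modules, and ``transform`` maps samples to module eigengene
    scores using the fitted per-gene standardization and PC weights.

    Parameters
    ----------
    power : float, default 12
        Soft-thresholding exponent of the correlation adjacency.
    mode : {"unsigned", "signed"}
        Adjacency flavor; unsigned uses ``|cor|^power``.
    min_module_size : int, default 50
        Smallest branch accepted as a module.
    merge_cut : float, default 0.1
        Eigengene dissimilarity (1 - cor) below which modules merge.
    cut_quantile : float, default 0.995
        Position of the tree cut within the merge-height range, just
        below the saturation plateau of the TOM dissimilarity.

    Attributes
    ----------
    labels_ : ndarray (n_genes,) — module id per gene, 0 = unassigned.
    eigengenes_ : ndarray (n_samples, n_modules)
    kme_ : ndarray (n_genes, n_modules)
    variance_explained_ : ndarray (n_modules,)
    linkage_ : scipy linkage matrix over the retained genes.
    """

    def __init__(
        self,
        power: float = 12,
        mode: str = "unsigned",
        min_module_size: int = 50,
        merge_cut: float = 0.1,
        cut_quantile: float = 0.995,
    ):
        self.power = power
        self.mode = mode
        self.min_module_size = min_module_size
        self.merge_cut = merge_cut
        self.cut_quantile = cut_quantile

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2d (samples x genes)")
        n_samples, n_genes = X.shape
        vals = X.T  # genes x samples
        var = vals.var(axis=1)
        keep = var > 0
        if (~keep).any():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance gene(s)", stacklevel=2
            )
        core = vals[keep]
        adj = _adjacency(core, self.power, self.mode)
        tom = _tom(adj)
        Z = _linkage(1.0 - tom)
        raw = _height_cut(Z, self.min_module_size, self.cut_quantile)
        part = merge_modules(
            pd.DataFrame(core),
            raw,
            merge_cut=self.merge_cut,
            min_size=self.min_module_size,
        )

        labels = np.zeros(n_genes, dtype=int)
        labels[keep] = part.labels.to_numpy()
        kme = np.full((n_genes, part.n_modules), np.nan)
        kme[keep] = part.kme.to_numpy()

        self.n_features_in_ = n_genes
        self.gene_mask_ = keep
        self.labels_ = labels
        self.linkage_ = Z
        self.eigengenes_ = part.eigengenes.to_numpy()
        self.kme_ = kme
        self.variance_explained_ = part.variance_explained.to_numpy()
        self.module_names_ = list(part.eigengenes.columns)
        self.n_modules_ = part.n_modules

        # transform weights: eigengene = w @ standardized member genes
        self.gene_mean_ = vals.mean(axis=1)
        sd = vals.std(axis=1)
        sd[sd == 0] = 1.0
        self.gene_scale_ = sd
        z = (vals - self.gene_mean_[:, None]) / self.gene_scale_[:, None]
        weights = np.zeros((part.n_modules, n_genes))
        for j, m in enumerate(sorted(set(labels[labels > 0]))):
            idx = np.flatnonzero(labels == m)
            _, w, _ = _eigengene(z[idx])
            weights[j, idx] = w
        self.weights_ = weights
        return self

    def transform(self, X) -> np.ndarray:
        """Project samples onto the fitted module eigengene axes."""
        X = np.asarray(X, dtype=float)
        z = (X - self.gene_mean_[None, :]) / self.gene_scale_[None, :]
        return z @ self.weights_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).eigengenes_


def detect_modules(
    expr,
    power: float = 12,
    mode: str = "unsigned",
    min_module_size: int = 50,
    merge_cut: float = 0.1,
    cut_quantile: float = 0.995,
) -> ModulePartition:
    """Full module-detection pipeline on a genes x samples expression
    matrix; returns a :class:`ModulePartition` with gene/sample ids."""
    vals, genes, samples = _values(expr)
    est = CoexpressionModules(
        power=power,
        mode=mode,
        min_module_size=min_module_size,
        merge_cut=merge_cut,
        cut_quantile=cut_quantile,
    ).fit(vals.T)
    me = pd.DataFrame(est.eigengenes_, index=samples, columns=est.module_names_)
    kme = pd.DataFrame(est.kme_, index=genes, columns=est.module_names_)
    return ModulePartition(
        labels=pd.Series(est.labels_, index=genes, name="module"),
        eigengenes=me,
        kme=kme,
        variance_explained=pd.Series(est.variance_explained_, index=est.module_names_),
        min_size=min_module_size,
        merge_cut=merge_cut,
    )
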