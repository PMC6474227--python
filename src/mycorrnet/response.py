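"""Per-gene transcriptional response classification.

Each gene's log2-CPM profile is fit with a two-factor linear model
(cultivar + fungal treatment + cultivar x treatment). Per-term F tests
with Benjamini-Hochberg FDR control across genes then assign each gene
to one of four response classes, in priority order:

``interaction``
    the cultivar x treatment term is significant: the response to the
    fungus differs in magnitude or direction among host genotypes
    (a genotype x genotype interaction);
``mycorrhiza_conserved``
    the treatment term is significant and the dominant single-df
    contrast is mock vs pooled-AMF: a conserved response to symbiosis;
``isolate_conserved``
    the treatment term is significant via the isolate-vs-isolate
    contrast: a conserved response to fungal genotype;
``cultivar_only``
    only the cultivar term is significant;
``none``
    otherwise.

The model is fit by ordinary least squares per gene, vectorized across
genes; with a balanced factorial design the per-term F tests coincide
with classical two-way ANOVA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .simulate import MOCK_LEVEL

__all__ = [
    "ResponseClassifier",
    "classify_responses",
    "select_by_fold_change",
    "RESPONSE_PRIORITY",
]

RESPONSE_PRIORITY = (
    "interaction",
    "mycorrhiza_conserved",
    "isolate_conserved",
    "cultivar_only",
    "none",
)

# absolute floor below which a sum of squares is treated as exactly zero
_SS_RTOL = 1e-9


def _dummies(values: np.ndarray) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(values))
    mat = np.column_stack([(values == lv).astype(float) for lv in levels])
    return mat, levels


def _proj(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _rss(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of Y after projection on Q."""
    fitted = (Y @ Q) @ Q.T
    resid = Y - fitted
    return np.einsum("ij,ij->i", resid, resid)


class ResponseClassifier(BaseEstimator):
    """Classify per-gene responses in a crossed two-factor design.

    scikit-learn style estimator. ``fit`` takes ``X`` of shape
    (n_samples, n_genes) and a per-sample design table with columns
    ``cultivar`` and ``fungal_treatment``.

    Parameters
    ----------
    alpha : float
        BH-FDR level applied within each model term across genes.
    mock_level : str
        Treatment level denoting the non-inoculated control, if present.

    Attributes
    ----------
    classes_ : ndarray of str, shape (n_genes,)
        Assigned response class per gene.
    pvalues_ : DataFrame (gene x term raw p-values)
    qvalues_ : DataFrame (gene x term BH-adjusted p-values)
    results_ : DataFrame with p/q per term, contrast p-values and class.
    """

    def __init__(self, alpha: float = 0.05, mock_level: str = MOCK_LEVEL):
        self.alpha = alpha
        self.mock_level = mock_level

    def fit(self, X, design: pd.DataFrame, gene_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2d (samples x genes)")
        n, n_genes = X.shape
        if len(design) != n:
            raise ValueError("design rows must match samples")
        cv = np.asarray(design["cultivar"])
        tr = np.asarray(design["fungal_treatment"])
        cv_levels = list(pd.unique(cv))
        tr_levels = list(pd.unique(tr))
        if len(cv_levels) < 2 or len(tr_levels) < 2:
            raise ValueError("need >= 2 cultivars and >= 2 fungal levels")
        cell_ids = np.asarray([f"{c}|{t}" for c, t in zip(cv, tr)])
        counts = pd.Series(cell_ids).value_counts()
        if (counts < 2).any():
            warnings.warn(
                "some design cells have < 2 samples; tests proceed with reduced df",
                stacklevel=2,
            )

        Y = X.T  # genes x samples
        D_cv, _ = _dummies(cv)
        D_tr, _ = _dummies(tr)
        D_cell, _ = _dummies(cell_ids)
        Q_cv = _proj(D_cv)
        Q_tr = _proj(D_tr)
        Q_add = _proj(np.hstack([D_cv, D_tr]))
        Q_full = _proj(D_cell)
        df_full = Q_full.shape[1]
        df_add = Q_add.shape[1]
        df_resid = n - df_full
        if df_resid < 1:
            raise ValueError("singular design: no residual degrees of freedom")

        rss_cv = _rss(Y, Q_cv)
        rss_tr = _rss(Y, Q_tr)
        rss_add = _rss(Y, Q_add)
        rss_full = _rss(Y, Q_full)

        mean = Y.mean(axis=1, keepdims=True)
        total_ss = np.einsum("ij,ij->i", Y - mean, Y - mean)
        tol = _SS_RTOL * (total_ss + 1.0)

        def term_p(
            rss_reduced: np.ndarray, rss_nested: np.ndarray, df_num: int
        ) -> np.ndarray:
            """F test of one term: extra SS of the nested pair over the
            full-model mean squared error."""
            num = np.maximum(rss_reduced - rss_nested, 0.0)
            ms_err = rss_full / df_resid
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (num / df_num) / ms_err
                p = stats.f.sf(F, df_num, df_resid)
            # degenerate (noise-free) genes: decide by the numerator alone
            zero_err = rss_full <= tol
            p = np.where(zero_err & (num > tol), 0.0, p)
            p = np.where(num <= tol, 1.0, p)
            return p

        p_int = term_p(rss_add, rss_full, max(df_full - df_add, 1))
        p_tr = term_p(rss_cv, rss_add, len(tr_levels) - 1)
        p_cv = term_p(rss_tr, rss_add, len(cv_levels) - 1)

        # single-df treatment contrasts on treatment-level means
        ms_err = rss_full / df_resid
        zero_err = rss_full <= tol
        group_means = {}
        group_n = {}
        for lv in tr_levels:
            mask = tr == lv
            group_means[lv] = Y[:, mask].mean(axis=1)
            group_n[lv] = int(mask.sum())
        iso_levels = [lv for lv in tr_levels if lv != self.mock_level]
        has_mock = self.mock_level in tr_levels

        def contrast_p(est: np.ndarray, var_coef: float) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = est / np.sqrt(ms_err * var_coef)
                p = 2.0 * stats.t.sf(np.abs(t), df_resid)
            scale_tol = np.sqrt(tol)
            p = np.where(zero_err & (np.abs(est) > scale_tol), 0.0, p)
            p = np.where(np.abs(est) <= scale_tol, 1.0, p)
            return p

        if has_mock and len(iso_levels) >= 1:
            amf_mean = np.mean([group_means[lv] for lv in iso_levels], axis=0)
            est = group_means[self.mock_level] - amf_mean
            var_coef = 1.0 / group_n[self.mock_level] + sum(
                1.0 / group_n[lv] for lv in iso_levels
            ) / len(iso_levels) ** 2
            p_mock_amf = contrast_p(est, var_coef)
        else:
            p_mock_amf = np.ones(n_genes)
        if len(iso_levels) >= 2:
            a, b = iso_levels[0], iso_levels[1]
            est = group_means[a] - group_means[b]
            p_iso = contrast_p(est, 1.0 / group_n[a] + 1.0 / group_n[b])
        else:
            p_iso = np.ones(n_genes)

        def bh(p: np.ndarray) -> np.ndarray:
            return multipletests(p, method="fdr_bh")[1]

        q_int, q_tr, q_cv = bh(p_int), bh(p_tr), bh(p_cv)

        classes = np.full(n_genes, "none", dtype=object)
        sig_int = q_int < self.alpha
        sig_tr = ~sig_int & (q_tr < self.alpha)
        conserved_myc = sig_tr & has_mock & (p_mock_amf <= p_iso)
        conserved_iso = sig_tr & ~conserved_myc
        sig_cv = ~sig_int & ~sig_tr & (q_cv < self.alpha)
        classes[sig_int] = "interaction"
        classes[conserved_myc] = "mycorrhiza_conserved"
        classes[conserved_iso] = "isolate_conserved"
        classes[sig_cv] = "cultivar_only"

        if gene_ids is None:
            gene_ids = pd.Index([f"g{i}" for i in range(n_genes)])
        self.results_ = pd.DataFrame(
            {
                "p_cultivar": p_cv,
                "p_treatment": p_tr,
                "p_interaction": p_int,
                "q_cultivar": q_cv,
                "q_treatment": q_tr,
                "q_interaction": q_int,
                "p_mock_vs_amf": p_mock_amf,
                "p_isolate_vs_isolate": p_iso,
                "response_class": classes,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        self.classes_ = np.asarray(classes)
        self.pvalues_ = self.results_[["p_cultivar", "p_treatment", "p_interaction"]]
        self.qvalues_ = self.results_[["q_cultivar", "q_treatment", "q_interaction"]]
        return self


def classify_responses(
    expr: ExpressionMatrix, design: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify every gene's response; returns the per-gene result table.

    The caller is expected to pass host expression over all samples and
    symbiont expression restricted to inoculated samples (see
    :func:`mycorrnet.preprocess.analysis_samples`).
    """
    sub = design.loc[expr.sample_ids]
    clf = ResponseClassifier(alpha=alpha).fit(
        expr.values.to_numpy().T, sub, gene_ids=expr.gene_ids
    )
    return clf.results_


def select_by_fold_change(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    group_a,
    group_b,
    min_abs_log2fc: float = 2.0,
    classification: pd.DataFrame | None = None,
    response_class: str | None = "interaction",
) -> tuple[pd.Index, pd.DataFrame]:
    """Genes with a large isolate-vs-isolate fold change in some cultivar.

    ``group_a`` / ``group_b`` are treatment level names (or explicit
    sample-id lists). The log2 fold change is the difference of group
    mean log2-CPM, computed overall and within each cultivar; a gene is
    selected when its largest per-cultivar |log2FC| exceeds
    ``min_abs_log2fc``, optionally intersected with a response class
    from a classification table.

    Returns
    -------
    (selected gene index, fold-change DataFrame)
        The DataFrame has one row per gene and one column per cultivar
        plus ``overall``.
    """
    sub = design.loc[expr.sample_ids]

    def _samples(group) -> pd.Index:
        if isinstance(group, str):
            sel = expr.sample_ids[(sub["fungal_treatment"] == group).to_numpy()]
        else:
            sel = pd.Index(group)
        if len(sel) == 0:
            raise ValueError(f"empty sample group {group!r}")
        return sel

    samples_a = _samples(group_a)
    samples_b = _samples(group_b)
    vals = expr.values
    fc = pd.DataFrame(index=expr.gene_ids)
    fc["overall"] = vals[samples_a].mean(axis=1) - vals[samples_b].mean(axis=1)
    for cvl in pd.unique(sub["cultivar"]):
        cv_samples = set(sub.index[(sub["cultivar"] == cvl).to_numpy()])
        sa = [s for s in samples_a if s in cv_samples]
        sb = [s for s in samples_b if s in cv_samples]
        if not sa or not sb:
            continue
        fc[cvl] = vals[sa].mean(axis=1) - vals[sb].mean(axis=1)
    per_cultivar = fc.drop(columns="overall")
    passes = per_cultivar.abs().max(axis=1) > min_abs_log2fc
    genes = expr.gene_ids[passes.to_numpy()]
    if classification is not None and response_class is not None:
        keep = classification.index[
            (classification["response_class"] == response_class).to_numpy()
        ]
        genes = genes.intersection(keep)
    return genes, fc
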