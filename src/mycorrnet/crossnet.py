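"""Cross-organism module correlation network and key-gene extraction.

Host and symbiont module eigengenes are correlated pairwise (Pearson,
two-sided t-test p-values); module pairs below the edge threshold form
a bipartite module network. Within each significantly correlated pair,
"key genes" are the module members most correlated to the partner
module (top 10% quantile of |gene significance|) that are also strongly
connected to their own module (kME > 0.8). A random gene-to-module
relabeling null checks that the observed edge count is not a chance
artifact of the module size spectrum.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .wgcna import ModulePartition, _eigengene, _standardize_rows, _values

__all__ = [
    "correlate_module_sets",
    "build_bipartite_network",
    "gene_significance",
    "key_genes",
    "key_gene_filter",
    "permutation_null",
]


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation of two samples x k arrays."""
    n = a.shape[0]
    za = _standardize_rows(a.T).T
    zb = _standardize_rows(b.T).T
    return np.clip((za.T @ zb) / n, -1.0, 1.0)


def _cor_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _subset(me: pd.DataFrame, sample_subset) -> pd.DataFrame:
    if sample_subset is None:
        return me
    return me.loc[[s for s in sample_subset if s in me.index]]


def correlate_module_sets(
    me_host: pd.DataFrame,
    me_symbiont: pd.DataFrame,
    sample_subset=None,
    edge_alpha: float = 0.001,
) -> pd.DataFrame:
    """Score every host x symbiont module pair by eigengene correlation.

    Both eigengene tables are samples x modules; they are aligned on
    their shared samples (optionally restricted to ``sample_subset``,
    conventionally the inoculated samples). Significance is raw
    ``p < edge_alpha``; BH-adjusted p-values are reported alongside.
    """
    mh = _subset(me_host, sample_subset)
    ms = _subset(me_symbiont, sample_subset)
    shared = mh.index.intersection(ms.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples for module correlations")
    mh, ms = mh.loc[shared], ms.loc[shared]
    n = len(shared)
    r = _pearson_matrix(mh.to_numpy(dtype=float), ms.to_numpy(dtype=float))
    p = _cor_pvalues(r, n)
    rows = []
    for i, a in enumerate(mh.columns):
        for j, b in enumerate(ms.columns):
            rows.append((a, b, r[i, j], p[i, j]))
    out = pd.DataFrame(rows, columns=["module_host", "module_symbiont", "r", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["n"] = n
    out["significant"] = out["p"] < edge_alpha
    return out


def build_bipartite_network(
    edges: pd.DataFrame,
    host_modules=None,
    symbiont_modules=None,
) -> nx.Graph:
    """Bipartite graph of significantly correlated module pairs.

    Nodes are ``host:<module>`` / ``symbiont:<module>`` with an
    ``organism`` attribute; modules without any significant edge are
    included (when listed) and flagged ``isolated=True``. Edges carry
    the Pearson r as ``weight`` and ``r``.
    """
    g = nx.Graph()
    if host_modules is None:
        host_modules = list(pd.unique(edges["module_host"]))
    if symbiont_modules is None:
        symbiont_modules = list(pd.unique(edges["module_symbiont"]))
    for m in host_modules:
        g.add_node(f"host:{m}", organism="host", module=str(m), isolated=True)
    for m in symbiont_modules:
        g.add_node(f"symbiont:{m}", organism="symbiont", module=str(m), isolated=True)
    for _, row in edges[edges["significant"]].iterrows():
        u, v = f"host:{row.module_host}", f"symbiont:{row.module_symbiont}"
        g.add_edge(u, v, weight=float(row.r), r=float(row.r), p=float(row.p))
        g.nodes[u]["isolated"] = False
        g.nodes[v]["isolated"] = False
    return g


def gene_significance(expr, partner_profile, sample_subset=None) -> pd.Series:
    """Pearson correlation of every gene with a partner-organism
    eigengene (or any per-sample profile such as a trait).

    Zero-variance genes get NaN and are excluded from key-gene
    quantiles downstream.
    """
    vals, genes, samples = _values(expr)
    prof = pd.Series(np.asarray(partner_profile, dtype=float).ravel(), index=samples) \
        if not isinstance(partner_profile, pd.Series) else partner_profile
    if sample_subset is not None:
        cols = [s for s in sample_subset if s in samples and s in prof.index]
    else:
        cols = [s for s in samples if s in prof.index]
    if len(cols) < 4:
        raise ValueError("need >= 4 shared samples for gene significance")
    idx = [list(samples).index(s) for s in cols]
    sub = vals[:, idx]
    y = prof.loc[cols].to_numpy(dtype=float)
    n = len(cols)
    zy = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    var = sub.var(axis=1)
    zg = _standardize_rows(sub)
    gs = (zg @ zy) / n
    gs[var == 0] = np.nan
    return pd.Series(np.clip(gs, -1.0, 1.0), index=genes, name="GS")


def key_gene_filter(
    gs: pd.Series, kme: pd.Series, quantile: float = 0.90, kme_min: float = 0.8
) -> pd.Series:
    """Boolean mask of the key-gene rule over one module's members.

    A gene passes iff |GS| is at or above the module's ``quantile`` of
    |GS| (linear-interpolation quantile; boundary ties included) and
    its own-module kME exceeds ``kme_min``. NaN GS/kME never pass and
    are excluded from the quantile.
    """
    abs_gs = gs.abs()
    valid = abs_gs.dropna()
    if len(valid) == 0:
        return pd.Series(False, index=gs.index)
    cut = float(np.quantile(valid.to_numpy(), quantile))
    passes = (abs_gs >= cut) & (kme.reindex(gs.index) > kme_min)
    return passes.fillna(False)


def key_genes(
    expr_own,
    partition_own: ModulePartition,
    me_partner: pd.DataFrame,
    edges: pd.DataFrame,
    organism: str,
    quantile: float = 0.90,
    kme_min: float = 0.8,
    sample_subset=None,
) -> pd.DataFrame:
    """Key genes of one organism toward all its correlated partner modules.

    ``edges`` is the cross-edge table; only significant pairs are
    scanned. Returns one row per (member gene x significant pair) with
    the gene significance, own-module kME and the ``passes`` flag.
    """
    own_col = "module_host" if organism == "host" else "module_symbiont"
    partner_col = "module_symbiont" if organism == "host" else "module_host"
    pairs = [
        (row[own_col], row[partner_col])
        for _, row in edges[edges["significant"]].iterrows()
    ]
    return _key_genes_table(
        expr_own,
        partition_own,
        me_partner,
        pairs,
        organism,
        quantile,
        kme_min,
        sample_subset,
    )


def _key_genes_table(
    expr_own,
    partition_own: ModulePartition,
    me_partner: pd.DataFrame,
    pairs,
    organism: str,
    quantile: float,
    kme_min: float,
    sample_subset,
) -> pd.DataFrame:
    """Shared key-gene machinery for partner modules and traits: the
    partner profile is any column of ``me_partner``."""
    rows = []
    for own_module, partner in pairs:
        members = partition_own.members(_module_number(own_module))
        if len(members) < 2:
            warnings.warn(
                f"module {own_module} has < 2 members; skipped", stacklevel=2
            )
            continue
        gs_all = gene_significance(
            expr_own, me_partner[partner], sample_subset=sample_subset
        )
        gs = gs_all.loc[members]
        kme = partition_own.kme.loc[members, _module_name(own_module)]
        passes = key_gene_filter(gs, kme, quantile=quantile, kme_min=kme_min)
        for g in members:
            rows.append(
                (
                    g,
                    organism,
                    _module_name(own_module),
                    str(partner),
                    float(gs.loc[g]) if np.isfinite(gs.loc[g]) else np.nan,
                    float(kme.loc[g]) if np.isfinite(kme.loc[g]) else np.nan,
                    bool(passes.loc[g]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "organism",
            "own_module",
            "partner_module",
            "GS",
            "kME",
            "passes",
        ],
    )


def _module_number(module) -> int:
    if isinstance(module, str) and module.startswith("M"):
        return int(module[1:])
    return int(module)


def _module_name(module) -> str:
    if isinstance(module, str):
        return module
    return f"M{int(module)}"


def permutation_null(
    labels_host: pd.Series,
    labels_symbiont: pd.Series,
    expr_host,
    expr_symbiont,
    n_perm: int = 100,
    seed: int = 0,
    edge_alpha: float = 0.001,
    sample_subset=None,
) -> dict:
    """Random gene-to-module relabeling null for the cross network.

    Genes are reassigned to modules uniformly at random, preserving each
    organism's module size spectrum; eigengenes are recomputed and
    significant cross edges counted. Returns the null distribution of
    edge counts, the observed count, and the empirical p-value
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def _me_from_labels(vals, lab) -> np.ndarray:
        z = _standardize_rows(vals)
        mods = sorted(set(lab[lab > 0]))
        return np.column_stack([_eigengene(z[lab == m])[0] for m in mods])

    vals_h, genes_h, samples_h = _values(expr_host)
    vals_s, genes_s, samples_s = _values(expr_symbiont)
    lab_h = labels_host.reindex(genes_h).fillna(0).astype(int).to_numpy()
    lab_s = labels_symbiont.reindex(genes_s).fillna(0).astype(int).to_numpy()

    if sample_subset is None:
        shared = samples_h.intersection(samples_s)
    else:
        shared = pd.Index([s for s in sample_subset if s in samples_h and s in samples_s])
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    col_h = [list(samples_h).index(s) for s in shared]
    col_s = [list(samples_s).index(s) for s in shared]
    n = len(shared)

    def _count_edges(lh, ls) -> int:
        me_h = _me_from_labels(vals_h[:, col_h], lh)
        me_s = _me_from_labels(vals_s[:, col_s], ls)
        if me_h.size == 0 or me_s.size == 0:
            return 0
        r = _pearson_matrix(me_h, me_s)
        p = _cor_pvalues(r, n)
        return int((p < edge_alpha).sum())

    observed = _count_edges(lab_h, lab_s)
    null_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null_counts[i] = _count_edges(rng.permutation(lab_h), rng.permutation(lab_s))
    p_emp = (1.0 + float((null_counts >= observed).sum())) / (n_perm + 1.0)
    return {
        "observed_edges": observed,
        "null_counts": null_counts,
        "p_empirical": p_emp,
        "edge_alpha": edge_alpha,
        "n_perm": n_perm,
    }
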