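"""Count normalization and low-expression filtering.

Counts are normalized to log2-counts-per-million with a prior count to
keep zeros finite:

    log2cpm = log2( (count + prior) / (library_size + 2*prior) * 1e6 )

For the symbiont matrix, mock (non-inoculated) samples carry only trace
contamination and are excluded from the expression filter and from all
downstream symbiont analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix
from .simulate import MOCK_LEVEL

__all__ = ["log2_cpm", "filter_genes", "analysis_samples"]


def log2_cpm(counts: CountMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """Normalize a count matrix to log2-counts-per-million.

    Parameters
    ----------
    counts : CountMatrix
    prior : float
        Prior count added to every entry; the library size is offset by
        ``2 * prior`` so a gene at exactly half the library lands on the
        same value regardless of prior.
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[np.flatnonzero(lib <= 0)[0]]
        raise ValueError(f"zero library size for sample {bad!r}")
    c = counts.counts.to_numpy(dtype=float)
    vals = np.log2((c + prior) / (lib + 2.0 * prior)[None, :] * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        organism=counts.organism,
    )


def analysis_samples(counts_or_expr, design: pd.DataFrame) -> pd.Index:
    """Samples entering the analysis for this organism.

    Host: all samples. Symbiont: inoculated samples only (mock roots
    contain no fungus).
    """
    ids = counts_or_expr.sample_ids
    sub = design.loc[ids]
    if counts_or_expr.organism == "symbiont":
        return ids[(sub["fungal_treatment"] != MOCK_LEVEL).to_numpy()]
    return ids


def filter_genes(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    design: pd.DataFrame | None = None,
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    If ``design`` is given and the matrix is a symbiont matrix, mock
    samples are dropped from the matrix entirely (filter and downstream
    analyses both exclude them).
    """
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    if design is not None:
        keep_samples = analysis_samples(counts, design)
        counts = counts.subset_samples(keep_samples)
    lib = counts.library_sizes.to_numpy(dtype=float)
    cpm = counts.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("all genes removed by expression filter", stacklevel=2)
    return counts.subset_genes(counts.gene_ids[keep])
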