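"""Module-trait association and trait key genes.

Module eigengenes of either organism are correlated with quantitative
phenotypic traits (e.g., percent root-length colonization, dry
weights). The gene-level analysis reuses the cross-network key-gene
machinery with the trait column standing in for a partner eigengene, so
a gene's trait significance is its Pearson correlation with the trait
and the same top-quantile |GS| with kME cut-off rule applies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .crossnet import _cor_pvalues, _key_genes_table
from .wgcna import ModulePartition

__all__ = ["correlate_modules_traits", "key_genes_for_trait"]


def correlate_modules_traits(
    me: pd.DataFrame, traits: pd.DataFrame, sample_subset=None
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of every module x trait.

    Returns a tidy table (module, trait, r, p, q, n); BH adjustment is
    across all module x trait pairs. A trait that is constant over the
    used samples yields NaN with a warning.
    """
    if sample_subset is not None:
        keep = [s for s in sample_subset if s in me.index]
    else:
        keep = [s for s in me.index if s in traits.index]
    rows = []
    for mod in me.columns:
        for trait in traits.columns:
            pair = pd.concat(
                [me.loc[keep, mod], traits.reindex(keep)[trait]], axis=1
            ).dropna()
            n = len(pair)
            if n < 4:
                raise ValueError(
                    f"fewer than 4 complete samples for {mod} x {trait}"
                )
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if y.std() == 0 or x.std() == 0:
                warnings.warn(f"constant values for {mod} x {trait}", stacklevel=2)
                rows.append((mod, trait, np.nan, np.nan, n))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            p = float(_cor_pvalues(np.asarray([r]), n)[0])
            rows.append((mod, trait, r, p, n))
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p", "n"])
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out


def key_genes_for_trait(
    expr,
    partition: ModulePartition,
    traits: pd.DataFrame,
    trait: str,
    organism: str = "host",
    alpha: float = 0.001,
    quantile: float = 0.90,
    kme_min: float = 0.8,
    sample_subset=None,
    module_trait: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Key genes for one trait: same rule as cross-module key genes.

    Modules whose eigengene correlates with the trait at ``p < alpha``
    are scanned; within each, gene significance is the gene-trait
    Pearson correlation and a gene passes at the top-``quantile`` of
    |GS| with kME > ``kme_min``.
    """
    if module_trait is None:
        module_trait = correlate_modules_traits(
            partition.eigengenes, traits, sample_subset=sample_subset
        )
    sig = module_trait[
        (module_trait["trait"] == trait) & (module_trait["p"] < alpha)
    ]
    pairs = [(mod, trait) for mod in sig["module"]]
    trait_df = traits[[trait]]
    return _key_genes_table(
        expr,
        partition,
        trait_df,
        pairs,
        organism,
        quantile,
        kme_min,
        sample_subset,
    )
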