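"""In-memory containers for count and expression data.

Both containers wrap a pandas DataFrame oriented genes x samples (the
orientation of the on-disk TSV interchange format). Estimator classes
in this package follow the scikit-learn convention instead
(samples x features); the thin wrapper functions transpose at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "ExpressionMatrix"]


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample matrix with an organism tag.

    Parameters
    ----------
    counts : DataFrame
        Genes as rows (index = gene ids), samples as columns.
    organism : str
        Free-form tag, conventionally ``"host"`` or ``"symbiont"``.
    library_sizes : Series, optional
        Per-sample library sizes. Defaults to the column sums, which is
        the right choice after in-silico read separation where each
        organism's library is the total of its own assigned reads.
    """

    counts: pd.DataFrame
    organism: str = "host"
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene id {dup!r}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[genes], self.organism, self.library_sizes.copy()
        )

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[:, samples], self.organism, self.library_sizes.loc[samples]
        )


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix (log2-CPM) with an organism tag."""

    values: pd.DataFrame
    organism: str = "host"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("non-finite entries in expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.organism)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, samples], self.organism)
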