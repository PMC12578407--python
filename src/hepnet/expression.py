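"""Gene-by-sample expression container.

All pipeline stages operate on :class:`ExpressionMatrix`, a thin validated
wrapper around a pandas DataFrame whose index holds gene identifiers and
whose columns hold sample identifiers. Values are continuous and assumed to
be on log2 scale throughout the package (array-style intensities); missing
entries may be NaN and are handled pairwise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one cohort.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids, entries are
        log2 expression values. NaN marks a missing measurement; infinities
        are rejected.
    cohort_id
        Label of the cohort the samples belong to.
    """

    values: pd.DataFrame
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite (NaN allowed for missing)")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.cohort_id)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(samples)].copy(), self.cohort_id)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.cohort_id)
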