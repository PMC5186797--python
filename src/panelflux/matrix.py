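"""Log2 expression matrices and probe-to-gene summarization.

The central container is :class:`LogExpressionMatrix`, a genes × samples
frame of log2 expression values tagged with the measurement platform
(``"array"`` or ``"rnaseq"``). All downstream statistics assume log base 2,
so a distance of 1 between two log expression values corresponds to a
2-fold difference on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

PLATFORMS = ("array", "rnaseq")


@dataclass
class LogExpressionMatrix:
    """Genes × samples matrix of log2 expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene (or probeset) id, columns by sample id.
        All values must be finite.
    platform : str
        Either ``"array"`` or ``"rnaseq"``.
    """

    values: pd.DataFrame
    platform: str = "array"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if len(self.values.index) == 0:
            raise ValueError("expression matrix has no genes")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def gene_means(self) -> pd.Series:
        """Per-gene mean log2 expression across all samples."""
        return self.values.mean(axis=1)

    def subset_samples(self, samples) -> "LogExpressionMatrix":
        return LogExpressionMatrix(self.values.loc[:, list(samples)].copy(), self.platform)

    def subset_genes(self, genes) -> "LogExpressionMatrix":
        return LogExpressionMatrix(self.values.loc[list(genes), :].copy(), self.platform)

    def samples_frame(self) -> pd.DataFrame:
        """Samples × genes orientation (the scikit-learn convention)."""
        return self.values.T


def summarize_to_gene_level(
    probe_matrix: LogExpressionMatrix,
    probe_gene_map: Mapping[str, str],
    replicate_map: Mapping[str, str] | None = None,
) -> LogExpressionMatrix:
    """Collapse a probeset-level matrix to gene level by mean log expression.

    Each gene's value in a sample is the arithmetic mean of the log values of
    all probesets mapped to it; probesets without a mapping are dropped.
    If ``replicate_map`` (column id → biological sample id) is given,
    replicate columns are afterwards averaged the same way.
    """
    mapped = [p for p in probe_matrix.gene_ids if p in probe_gene_map]
    if not mapped:
        raise ValueError("no probeset in the matrix is covered by the probe→gene mapping")
    sub = probe_matrix.values.loc[mapped]
    genes = pd.Index([probe_gene_map[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes).mean()
    if replicate_map is not None:
        missing = [s for s in collapsed.columns if s not in replicate_map]
        if missing:
            raise ValueError(f"samples without replicate mapping: {missing[:5]}")
        groups = pd.Index([replicate_map[s] for s in collapsed.columns])
        collapsed = collapsed.T.groupby(groups).mean().T
    return LogExpressionMatrix(collapsed, probe_matrix.platform)
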