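"""In-memory containers: the labelled expression matrix and query profiles.

An :class:`ExpressionMatrix` is a genes x samples table of non-negative
expression values on a common normalized scale, with NaN marking missing
measurements, plus one tissue label per sample.  A query profile is simply a
``pandas.Series`` mapping gene ids to values.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .exceptions import InputError

log = logging.getLogger(__name__)

#: tolerance below zero accepted as numerical noise and clamped
NEGATIVE_TOL = 1e-9


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample tissue labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns; NaN marks a
        missing measurement.
    tissue_labels
        Series indexed by sample id giving each sample's tissue class.
    """

    values: pd.DataFrame
    tissue_labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise InputError(f"duplicate sample ids: {list(dupes[:5])}")
        missing_labels = self.values.columns.difference(self.tissue_labels.index)
        if len(missing_labels):
            raise InputError(
                f"samples without tissue label: {list(missing_labels[:5])}"
            )
        self.tissue_labels = self.tissue_labels.reindex(self.values.columns)
        vals = self.values.to_numpy(dtype=float)
        neg = vals < -NEGATIVE_TOL
        if neg.any():
            raise InputError(
                f"{int(neg.sum())} negative expression values; "
                "inputs must be on a non-negative scale"
            )
        if (vals < 0).any():
            self.values = self.values.clip(lower=0.0)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance."""
        return list(dict.fromkeys(self.tissue_labels))

    def tissue_counts(self) -> dict[str, int]:
        return self.tissue_labels.value_counts().to_dict()

    def samples_of(self, tissue: str) -> list[str]:
        mask = self.tissue_labels == tissue
        return list(self.tissue_labels.index[mask])

    def drop_sample(self, sample_id: str) -> "ExpressionMatrix":
        if sample_id not in self.values.columns:
            raise KeyError(sample_id)
        return ExpressionMatrix(
            self.values.drop(columns=[sample_id]),
            self.tissue_labels.drop(sample_id),
        )

    def query_of(self, sample_id: str) -> pd.Series:
        """Extract one sample as a query profile (missing genes dropped)."""
        return self.values[sample_id].dropna()


def clean_query(query: pd.Series) -> pd.Series:
    """Validate a query profile: drop missing entries, clamp tiny negatives.

    Negative values can arise upstream of agep (e.g. after background
    subtraction); densities are only defined on [0, inf) so they are clamped
    to zero with a warning.
    """
    if query.index.duplicated().any():
        raise InputError("duplicate gene ids in query profile")
    query = query.astype(float).dropna()
    n_neg = int((query < 0).sum())
    if n_neg:
        log.warning("clamping %d negative query values to 0", n_neg)
        query = query.clip(lower=0.0)
    return query
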