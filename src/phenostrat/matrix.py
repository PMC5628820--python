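"""Sample-by-feature tables of categorical phenotypes.

The :class:`PhenotypeMatrix` is the common currency of the whole pipeline: a
rectangular table of unordered categorical trait values (questionnaire
answers), one row per individual, with an optional per-sample class label
(a constitution type such as ``Vata``/``Pitta``/``Kapha``, or a mixture name
such as ``Vata+Pitta``).  Missing answers are carried as ``NaN`` in memory
and serialized as the literal string ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "NA"

__all__ = ["PhenotypeMatrix", "MISSING"]


@dataclass
class PhenotypeMatrix:
    """Samples x categorical features, with optional class labels.

    Parameters
    ----------
    data :
        DataFrame indexed by unique sample ids, columns are unique feature
        ids; cells hold level strings or ``NaN`` for missing.
    labels :
        Optional Series aligned to ``data.index`` giving each sample's class.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample_ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("feature_ids must be unique")
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.data.index)

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "PhenotypeMatrix":
        return PhenotypeMatrix(
            self.data.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def select_features(self, feature_ids) -> "PhenotypeMatrix":
        return PhenotypeMatrix(self.data.loc[:, list(feature_ids)].copy(),
                               None if self.labels is None else self.labels.copy())

    def select_samples(self, sample_ids) -> "PhenotypeMatrix":
        ids = list(sample_ids)
        return PhenotypeMatrix(self.data.loc[ids].copy(),
                               None if self.labels is None else self.labels.loc[ids].copy())

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def concat(self, other: "PhenotypeMatrix") -> "PhenotypeMatrix":
        """Stack two cohorts sharing the same feature set (row-wise)."""
        if list(self.data.columns) != list(other.data.columns):
            raise ValueError("feature sets differ; harmonize first")
        data = pd.concat([self.data, other.data], axis=0)
        labels = None
        if self.labels is not None and other.labels is not None:
            labels = pd.concat([self.labels, other.labels])
        return PhenotypeMatrix(data, labels)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: sample_id, optional label, then feature columns."""
        out = self.data.copy()
        if self.labels is not None:
            out.insert(0, "label", self.labels)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep=MISSING)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col="sample_id",
                         dtype=str, keep_default_na=False)
        df = df.replace(MISSING, np.nan)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label")
        return cls(df, labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeMatrix):
            return NotImplemented
        same_data = self.data.equals(other.data)
        if self.labels is None or other.labels is None:
            return same_data and self.labels is None and other.labels is None
        return same_data and self.labels.equals(other.labels)


def _as_series(values, index) -> pd.Series:
    return pd.Series(values, index=index)
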