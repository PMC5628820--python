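"""Cleaning of raw categorical questionnaire tables.

Three steps, applied in order: (1) drop features with strictly more than a
threshold fraction (default 5%) of missing values; (2) impute remaining
missing cells with the feature's modal level (ties broken lexicographically);
(3) drop features that no longer vary.  Step 3 runs after imputation so a
feature made constant by imputation is removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .matrix import PhenotypeMatrix

__all__ = [
    "PreprocessReport",
    "filter_missing",
    "impute_mode",
    "drop_nonvarying",
    "preprocess_pipeline",
]


@dataclass
class PreprocessReport:
    removed_missing: list = field(default_factory=list)
    removed_nonvarying: list = field(default_factory=list)
    imputed: dict = field(default_factory=dict)  # feature -> (mode, n_cells)
    n_features_in: int = 0
    n_features_out: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "removed_missing": self.removed_missing,
                    "removed_nonvarying": self.removed_nonvarying,
                    "imputed": {k: list(v) for k, v in self.imputed.items()},
                    "n_features_in": self.n_features_in,
                    "n_features_out": self.n_features_out,
                },
                fh,
                indent=2,
            )


def filter_missing(m: PhenotypeMatrix, threshold: float = 0.05):
    """Remove features whose missing fraction strictly exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if m.n_samples == 0 or m.n_features == 0:
        raise ValueError("empty matrix")
    frac = m.data.isna().mean(axis=0)
    removed = [f for f in m.feature_ids if frac[f] > threshold]
    kept = [f for f in m.feature_ids if frac[f] <= threshold]
    return m.select_features(kept), removed


def _mode_level(col: pd.Series) -> str:
    counts = col.dropna().value_counts()
    if counts.empty:
        raise ValueError(f"feature {col.name!r} has no observed values")
    best = counts[counts == counts.max()]
    return sorted(best.index)[0]  # lexicographic tie-break


def impute_mode(m: PhenotypeMatrix):
    """Replace every missing cell with its feature's modal observed level."""
    out = m.copy()
    imputed: dict[str, tuple[str, int]] = {}
    for f in out.feature_ids:
        col = out.data[f]
        n_miss = int(col.isna().sum())
        if n_miss == 0:
            continue
        mode = _mode_level(col)
        out.data[f] = col.fillna(mode)
        imputed[f] = (mode, n_miss)
    return out, imputed


def drop_nonvarying(m: PhenotypeMatrix):
    """Remove features whose observed values are all a single level."""
    nun = m.data.nunique(dropna=True)
    removed = [f for f in m.feature_ids if nun[f] <= 1]
    kept = [f for f in m.feature_ids if nun[f] > 1]
    return m.select_features(kept), removed


def preprocess_pipeline(m: PhenotypeMatrix, threshold: float = 0.05):
    """filter_missing -> impute_mode -> drop_nonvarying, with a full report."""
    filtered, removed_missing = filter_missing(m, threshold)
    imputed_m, imputed = impute_mode(filtered)
    clean, removed_nonvarying = drop_nonvarying(imputed_m)
    report = PreprocessReport(
        removed_missing=removed_missing,
        removed_nonvarying=removed_nonvarying,
        imputed=imputed,
        n_features_in=m.n_features,
        n_features_out=clean.n_features,
    )
    return clean, report
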