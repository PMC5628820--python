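"""Unsupervised random-forest dissimilarities between samples.

A forest is trained to separate the real samples from a synthetic contrast
class obtained by permuting every feature column independently (marginals
preserved, joint structure destroyed).  The proximity of two real samples is
the fraction of trees in which they land in the same terminal node; the
dissimilarity is 1 - proximity.  By default proximity is counted over all
trees; an ``oob_only`` switch restricts the count to trees where both samples
are out-of-bag, the alternative convention of the classic implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier

from .matrix import PhenotypeMatrix

__all__ = [
    "ForestConfig",
    "DissimilarityMatrix",
    "synthetic_contrast",
    "fit_unsupervised_forest",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters for the proximity construction.

    ntree defaults to 10,000 — large enough for stable proximities at cohort
    scale while staying interactive; mtry=None means sqrt(p) columns per
    split; min_node_size is the minimum leaf size.
    """

    ntree: int = 10_000
    mtry: int | None = None
    seed: int = 0
    min_node_size: int = 1
    oob_only: bool = False

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity in [0, 1] with zero diagonal."""

    sample_ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity must be square over sample_ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("dissimilarity must be symmetric")
        if (self.d < -1e-10).any() or (self.d > 1 + 1e-10).any():
            raise ValueError("entries must lie in [0, 1]")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids) \
            .rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def subset(self, sample_ids) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DissimilarityMatrix(list(sample_ids), self.d[np.ix_(idx, idx)])


def synthetic_contrast(m: PhenotypeMatrix, seed: int) -> PhenotypeMatrix:
    """Independently permute every column (the contrast class of the forest)."""
    if m.has_missing():
        raise ValueError("contrast construction requires a complete matrix")
    rng = np.random.default_rng(seed)
    data = m.data.copy()
    for f in data.columns:
        data[f] = rng.permutation(data[f].to_numpy())
    return PhenotypeMatrix(data, None if m.labels is None else m.labels.copy())


def _one_hot(m: PhenotypeMatrix) -> pd.DataFrame:
    return pd.get_dummies(m.data, prefix_sep="=").astype(np.float32)


def fit_unsupervised_forest(m: PhenotypeMatrix, cfg: ForestConfig) -> DissimilarityMatrix:
    """Forest-based dissimilarity among the samples of ``m``.

    Real samples are class 1, a column-permuted contrast cohort of equal size
    is class 2; the forest's terminal-node co-occupancy of the real samples
    yields the proximity.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if m.has_missing():
        raise ValueError("preprocess first: missing values present")
    contrast = synthetic_contrast(m, seed=cfg.seed)
    X_real = _one_hot(m)
    X_contrast = pd.get_dummies(contrast.data, prefix_sep="=") \
        .reindex(columns=X_real.columns, fill_value=0).astype(np.float32)
    X = np.vstack([X_real.to_numpy(), X_contrast.to_numpy()])
    y = np.r_[np.zeros(m.n_samples), np.ones(m.n_samples)]
    max_features = "sqrt" if cfg.mtry is None else min(cfg.mtry, X.shape[1])
    forest = RandomForestClassifier(
        n_estimators=cfg.ntree,
        max_features=max_features,
        min_samples_leaf=cfg.min_node_size,
        bootstrap=True,
        n_jobs=1,
        random_state=cfg.seed,
    ).fit(X, y)
    leaves = forest.apply(X_real.to_numpy())  # (n, ntree)
    if cfg.oob_only:
        prox = _oob_proximity(forest, leaves, m.n_samples, len(y))
    else:
        prox = _cooccupancy(leaves) / cfg.ntree
    d = 1.0 - prox
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(m.sample_ids, np.clip(d, 0.0, 1.0))


def _cooccupancy(leaves: np.ndarray) -> np.ndarray:
    """Count, over trees, how often each sample pair shares a terminal node."""
    n, t = leaves.shape
    # sparse indicator over (tree, leaf) pairs: same-leaf pairs via S @ S.T
    cols = leaves + np.cumsum(np.r_[0, leaves.max(axis=0)[:-1] + 1])[None, :]
    S = sparse.csr_matrix(
        (np.ones(n * t, dtype=np.float64),
         (np.repeat(np.arange(n), t), cols.ravel())),
        shape=(n, int(cols.max()) + 1),
    )
    return np.asarray((S @ S.T).todense())


def _oob_proximity(forest, leaves: np.ndarray, n: int, n_total: int) -> np.ndarray:
    """Proximity restricted to trees where both samples are out-of-bag."""
    counts = np.zeros((n, n))
    denom = np.zeros((n, n))
    for t, sampled in enumerate(forest.estimators_samples_):
        mask = np.ones(n, dtype=bool)
        mask[sampled[sampled < n]] = False
        pair = np.outer(mask, mask)
        denom += pair
        same = leaves[:, t][:, None] == leaves[:, t][None, :]
        counts += pair & same
    with np.errstate(invalid="ignore", divide="ignore"):
        prox = np.where(denom > 0, counts / denom, 0.0)
    np.fill_diagonal(prox, 1.0)
    return prox
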