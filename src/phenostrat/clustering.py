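"""Medoid clustering of forest dissimilarities and its permutation null.

Implements classic PAM (BUILD + SWAP, no sampling) on a precomputed
dissimilarity, silhouette-width model selection over a k grid, the
"Savannah" analysis — average silhouette width per k for the original data
against column-permuted replicates — plus the cluster/label agreement score
and classical (Torgerson) multidimensional scaling for visualization.

PAM is deterministic given the dissimilarity: ties in the BUILD greedy step,
in the SWAP choice and in nearest-medoid assignment are all broken toward
the lowest sample index, so a seed never changes the solution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .matrix import PhenotypeMatrix
from .proximity import DissimilarityMatrix, ForestConfig, fit_unsupervised_forest, synthetic_contrast

__all__ = [
    "ClusterSolution",
    "SavannahResult",
    "MDSResult",
    "pam",
    "silhouette_widths",
    "select_k",
    "savannah",
    "cluster_label_agreement",
    "classical_mds",
]


@dataclass
class ClusterSolution:
    k: int
    medoids: list  # sample ids, ascending by sample position
    assignment: pd.Series  # sample id -> cluster index
    silhouette: pd.Series | None  # per-sample width, None for k < 2
    avg_silhouette: float | None
    cost: float


def _build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        # adding h changes each sample's cost to min(nearest, d[:, h])
        new_costs = np.minimum(nearest[:, None], d).sum(axis=0)
        new_costs[medoids] = np.inf
        h = int(np.argmin(new_costs))
        medoids.append(h)
        nearest = np.minimum(nearest, d[:, h])
    return medoids


def _swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    n = d.shape[0]
    medoids = sorted(medoids)
    k = len(medoids)
    if k >= n:
        return medoids
    while True:
        dm = d[:, medoids]  # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        n1 = order[:, 0]
        dn1 = dm[np.arange(n), n1]
        dn2 = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        # base[m, i]: sample i's medoid distance if medoid slot m is removed
        base = np.tile(dn1, (k, 1))
        base[n1, np.arange(n)] = dn2
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        # candidate costs: (k slots) x (candidates)
        cand = np.minimum(base[:, None, :], d.T[None, non_medoids, :]).sum(axis=2)
        cur = dn1.sum()
        best = np.unravel_index(np.argmin(cand), cand.shape)
        if cand[best] < cur - 1e-12:
            m_slot, h_idx = best
            medoids[m_slot] = int(non_medoids[h_idx])
            medoids = sorted(medoids)
        else:
            return medoids


def pam(D: DissimilarityMatrix, k: int, seed: int = 0) -> ClusterSolution:
    """Classic PAM on a precomputed dissimilarity.

    The seed is accepted for interface symmetry but the algorithm is fully
    deterministic (lowest-index tie-breaks).
    """
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    d = D.d
    medoids = _swap(d, _build(d, k)) if k < n else list(range(n))
    medoids = sorted(medoids)
    assign_idx = np.argmin(d[:, medoids], axis=1)
    cost = float(d[np.arange(n), np.asarray(medoids)[assign_idx]].sum())
    assignment = pd.Series(assign_idx, index=D.sample_ids)
    sil = avg = None
    if k >= 2:
        per, avg = silhouette_widths(D, assignment)
        sil = per
    return ClusterSolution(
        k=k,
        medoids=[D.sample_ids[i] for i in medoids],
        assignment=assignment,
        silhouette=sil,
        avg_silhouette=avg,
        cost=cost,
    )


def silhouette_widths(D: DissimilarityMatrix, assignment) -> tuple[pd.Series, float]:
    """Per-sample silhouette widths s(i) = (b - a) / max(a, b).

    a(i) is the mean dissimilarity to the sample's own cluster (excluding
    itself), b(i) the smallest mean dissimilarity to any other cluster;
    members of singleton clusters get s(i) = 0 by convention.
    """
    labels = pd.Series(assignment, index=D.sample_ids).to_numpy()
    clusters, inv = np.unique(labels, return_inverse=True)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n, K = D.n, len(clusters)
    onehot = np.zeros((n, K))
    onehot[np.arange(n), inv] = 1.0
    sums = D.d @ onehot  # (n, K) total dissimilarity to each cluster
    sizes = onehot.sum(axis=0)
    own = sums[np.arange(n), inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = own / (sizes[inv] - 1)
        means_other = sums / sizes[None, :]
    means_other[np.arange(n), inv] = np.inf
    b = means_other.min(axis=1)
    s = np.where(sizes[inv] == 1, 0.0,
                 np.where(np.maximum(a, b) > 0, (b - a) / np.maximum(a, b), 0.0))
    per = pd.Series(s, index=D.sample_ids)
    return per, float(per.mean())


def select_k(D: DissimilarityMatrix, kmin: int = 2, kmax: int = 20,
             seed: int = 0) -> tuple[int, dict[int, ClusterSolution]]:
    """PAM for each k in [kmin, kmax]; k* maximizes average silhouette.

    Ties go to the smallest k (parsimony).
    """
    if kmax > D.n - 1:
        raise ValueError("kmax must be <= n - 1")
    if kmin < 2:
        raise ValueError("kmin must be >= 2")
    solutions = {k: pam(D, k, seed) for k in range(kmin, kmax + 1)}
    k_star = max(sorted(solutions), key=lambda k: (solutions[k].avg_silhouette, -k))
    return k_star, solutions


@dataclass
class SavannahResult:
    """Average silhouette widths per k: original data vs permuted replicates."""

    k_grid: list
    original_widths: np.ndarray  # (len(k_grid),)
    permuted_widths: np.ndarray  # (n_permutations, len(k_grid))
    n_permutations: int

    def to_long_tsv(self, path) -> None:
        """Long format (replicate, k, width); replicate 0 is the original."""
        rows = [(0, k, w) for k, w in zip(self.k_grid, self.original_widths)]
        for r in range(self.n_permutations):
            rows += [(r + 1, k, w) for k, w in zip(self.k_grid, self.permuted_widths[r])]
        pd.DataFrame(rows, columns=["replicate", "k", "width"]).to_csv(
            path, sep="\t", index=False)


def _widths_for(m: PhenotypeMatrix, cfg: ForestConfig, kmin: int, kmax: int) -> np.ndarray:
    D = fit_unsupervised_forest(m, cfg)
    _, sols = select_k(D, kmin, kmax)
    return np.array([sols[k].avg_silhouette for k in range(kmin, kmax + 1)])


def savannah(m: PhenotypeMatrix, cfg: ForestConfig, n_permutations: int = 100,
             kmin: int = 2, kmax: int = 20, seed: int = 0) -> SavannahResult:
    """Permutation null for cluster validity.

    The original data's average silhouette width per k is compared with the
    widths obtained after independently permuting every feature column
    (one fresh permuted dataset per replicate, reused across the k grid).
    Every replicate draws its permutation and its forest seed from the
    master seed by counter, so runs are reproducible.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    original = _widths_for(m, cfg, kmin, kmax)
    permuted = np.zeros((n_permutations, kmax - kmin + 1))
    for r in range(n_permutations):
        perm_seed = int(np.random.SeedSequence([seed, r + 1]).generate_state(1)[0] % 2**31)
        m_perm = synthetic_contrast(m, seed=perm_seed)
        cfg_r = replace(cfg, seed=perm_seed)
        permuted[r] = _widths_for(m_perm, cfg_r, kmin, kmax)
    return SavannahResult(list(range(kmin, kmax + 1)), original, permuted, n_permutations)


def cluster_label_agreement(assignment, labels) -> float:
    """Best fraction of samples matched under a one-to-one cluster->class map.

    The optimal mapping is found on the contingency table (rectangular
    assignment problem; unmatched clusters contribute nothing).
    """
    assignment = pd.Series(assignment)
    labels = pd.Series(labels)
    labels = labels.reindex(assignment.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:3]
        raise ValueError(f"labels missing for samples {missing}")
    table = pd.crosstab(assignment, labels).to_numpy()
    r, c = table.shape
    size = max(r, c)
    padded = np.zeros((size, size))
    padded[:r, :c] = table
    rows, cols = linear_sum_assignment(-padded)
    return float(padded[rows, cols].sum() / len(assignment))


@dataclass
class MDSResult:
    sample_ids: list
    coords: np.ndarray  # (n, dims_kept)
    eigenvalues: np.ndarray
    n_dropped: int  # requested dimensions dropped for non-positive eigenvalues

    def to_tsv(self, path) -> None:
        cols = [f"dim{i + 1}" for i in range(self.coords.shape[1])]
        pd.DataFrame(self.coords, index=self.sample_ids, columns=cols) \
            .rename_axis("sample_id").to_csv(path, sep="\t")


def classical_mds(D: DissimilarityMatrix, dims: int = 2) -> MDSResult:
    """Torgerson scaling: double-center -D^2/2, embed on top eigenpairs.

    Dimensions whose eigenvalue is not positive are dropped and counted.
    Each kept eigenvector's first nonzero entry is made positive, fixing the
    reflection ambiguity.
    """
    n = D.n
    if dims > n:
        raise ValueError("dims must be <= n")
    d2 = D.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:dims]
    vals_top, vecs_top = vals[order], vecs[:, order]
    keep = vals_top > 1e-10
    n_dropped = int(dims - keep.sum())
    vals_k, vecs_k = vals_top[keep], vecs_top[:, keep]
    for j in range(vecs_k.shape[1]):
        col = vecs_k[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            vecs_k[:, j] = -col
    coords = vecs_k * np.sqrt(vals_k)[None, :]
    if coords.size == 0:
        coords = np.zeros((n, dims))
        n_dropped = 0 if np.allclose(D.d, 0) else n_dropped
    return MDSResult(list(D.sample_ids), coords, vals_top, n_dropped)
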