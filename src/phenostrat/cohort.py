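"""Seeded generator of questionnaire-like cohorts with latent class structure.

Real constitution-type questionnaire data are not publicly deposited, so the
pipeline is exercised on synthetic cohorts that reproduce the study regime:
three "extreme" classes of individuals (defaults 66/35/46 = 147 samples),
~133 unordered categorical features of 2-4 levels, a class-informative subset
arranged in correlated blocks, mixture ("non-extreme") individuals drawn
feature-wise from two parent classes, and a small MCAR missingness rate.

Generative model
----------------
Each informative feature ``f`` has, per class ``c``, a *preferred level*
(levels are cycled by class index so that different classes prefer different
levels wherever the level count allows).  The class-conditional distribution
interpolates between uniform and a point mass on the preferred level:
``signal_strength = 0`` gives the uniform distribution (identical across
classes, i.e. no signal) and for ``signal_strength >= 1/L`` the preferred
level carries exactly ``signal_strength`` probability mass, the remainder
spread evenly over the other levels.  Non-informative features share a single
multinomial across classes.  Features are partitioned into contiguous blocks;
with probability ``block_coupling`` an informative feature's value is driven
by a per-sample, per-block latent uniform rather than an independent draw,
inducing within-block correlation (the "coupling" a permutation null should
detect).  Mixture samples choose, independently per feature, one of their two
parent classes with probability 1/2 and draw from its class-conditional
distribution, so mixtures sit midway between parents on every feature.

All randomness derives from the spec's seed through named substreams, so a
spec reproduces its cohorts byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import PhenotypeMatrix

__all__ = [
    "CohortSpec",
    "CohortModel",
    "default_spec",
    "generate_extreme",
    "generate_nonextreme",
    "inject_missing",
    "derive_second_cohort",
]

_LEVEL_NAMES = ("a", "b", "c", "d")

# substream tags so each draw family has its own independent stream
_STREAM_PARAMS, _STREAM_EXTREME, _STREAM_MIX, _STREAM_SECOND, _STREAM_MISSING = range(5)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the study regime: 147 extreme samples in three classes
    (66/35/46), 106 mixture samples, 133 features of which 80 are
    class-informative in 12 correlated blocks, strong per-feature signal
    (0.85), moderate block coupling (0.5) and 3% missingness.
    """

    n_per_class: tuple[int, ...] = (66, 35, 46)
    class_names: tuple[str, ...] = ("Vata", "Pitta", "Kapha")
    n_nonextreme: dict = field(
        default_factory=lambda: {
            ("Vata", "Pitta"): 40,
            ("Pitta", "Kapha"): 33,
            ("Vata", "Kapha"): 33,
        }
    )
    n_features: int = 133
    n_informative: int = 80
    levels_per_feature: tuple[int, ...] | None = None  # None -> drawn in {2,3,4}
    signal_strength: float = 0.85
    n_blocks: int = 12
    block_coupling: float = 0.5
    missing_rate: float = 0.03
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(self.class_names):
            raise ValueError("n_per_class: must have one count per class name")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class: counts must be >= 0")
        # normalize mixture-pair keys: "A+B" strings (from YAML/JSON) -> tuples
        pairs = {}
        for pair, count in self.n_nonextreme.items():
            key = tuple(pair.split("+")) if isinstance(pair, str) else tuple(pair)
            pairs[key] = count
        object.__setattr__(self, "n_nonextreme", pairs)
        if any(c < 0 for c in self.n_nonextreme.values()):
            raise ValueError("n_nonextreme: counts must be >= 0")
        for pair in self.n_nonextreme:
            if len(pair) != 2 or not set(pair) <= set(self.class_names):
                raise ValueError(f"n_nonextreme: unknown parent class in pair {pair!r}")
        if self.n_features < 1:
            raise ValueError("n_features: must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative: must be in [0, n_features]")
        if self.levels_per_feature is not None:
            if len(self.levels_per_feature) != self.n_features:
                raise ValueError("levels_per_feature: need one entry per feature")
            if any(not 2 <= L <= 4 for L in self.levels_per_feature):
                raise ValueError("levels_per_feature: levels must be in [2, 4]")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength: must be in [0, 1]")
        if self.n_blocks < 1 or self.n_blocks > self.n_features:
            raise ValueError("n_blocks: must be in [1, n_features]")
        if not 0.0 <= self.block_coupling <= 1.0:
            raise ValueError("block_coupling: must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate: must be in [0, 0.2]")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def feature_ids(self) -> list[str]:
        return [f"Q{i + 1:03d}" for i in range(self.n_features)]


def default_spec(**overrides) -> CohortSpec:
    """The default study-shaped spec, optionally with field overrides."""
    return CohortSpec(**overrides)


class CohortModel:
    """Frozen generative state derived deterministically from a spec.

    Holds the per-feature level sets, the per-(feature, class) preferred
    levels, the class-conditional CDFs and the block partition.  The same
    model instance must be used when extreme and mixture samples are meant
    to share their latent structure.
    """

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        rng = np.random.default_rng([_STREAM_PARAMS, spec.seed])
        p = spec.n_features
        if spec.levels_per_feature is None:
            self.n_levels = rng.integers(2, 5, size=p)
        else:
            self.n_levels = np.asarray(spec.levels_per_feature, dtype=int)
        # contiguous near-equal blocks over all features
        bounds = np.linspace(0, p, spec.n_blocks + 1).astype(int)
        self.block_of = np.zeros(p, dtype=int)
        for b in range(spec.n_blocks):
            self.block_of[bounds[b]:bounds[b + 1]] = b
        self.informative = np.arange(p) < spec.n_informative
        K = spec.n_classes
        # preferred level index of class j on feature f: cycle by class index
        self.preferred = np.zeros((p, K), dtype=int)
        for f in range(p):
            for j in range(K):
                self.preferred[f, j] = (f + j) % self.n_levels[f]
        # shared multinomial for noise features (moderately even Dirichlet)
        self.noise_probs = [rng.dirichlet(np.full(L, 5.0)) for L in self.n_levels]

    # -- distributions -----------------------------------------------------
    def class_probs(self, f: int, j: int) -> np.ndarray:
        """Class-conditional level probabilities of feature ``f`` in class ``j``.

        Level order is the feature's natural level order (index 0..L-1).
        """
        L = int(self.n_levels[f])
        if not self.informative[f]:
            return np.asarray(self.noise_probs[f])
        s = self.spec.signal_strength
        t = max(0.0, (s - 1.0 / L) / (1.0 - 1.0 / L))  # uniform<->point-mass mix
        probs = np.full(L, (1.0 - t) / L)
        probs[self.preferred[f, j]] += t
        return probs

    def level_names(self, f: int) -> list[str]:
        return list(_LEVEL_NAMES[: self.n_levels[f]])

    def _cdf_order(self, f: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """CDF and level permutation with the preferred level first.

        Putting the preferred level first in the inverse-CDF ordering makes
        block-coupled features concordant: a shared low latent uniform maps
        every coupled feature to its own preferred level.
        """
        L = int(self.n_levels[f])
        if self.informative[f]:
            pref = self.preferred[f, j]
            order = np.r_[pref, [l for l in range(L) if l != pref]]
        else:
            order = np.arange(L)
        probs = self.class_probs(f, j)[order]
        return np.cumsum(probs), order

    # -- sampling ----------------------------------------------------------
    def _sample_classes(self, class_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw level indices (n x p) for samples with the given class index."""
        spec = self.spec
        n, p = len(class_idx), spec.n_features
        u_block = rng.random((n, spec.n_blocks))
        coupled = rng.random((n, p)) < spec.block_coupling
        u_indep = rng.random((n, p))
        u = np.where(coupled & self.informative[None, :],
                     u_block[:, self.block_of], u_indep)
        out = np.zeros((n, p), dtype=int)
        for f in range(p):
            for j in np.unique(class_idx):
                rows = class_idx == j
                cdf, order = self._cdf_order(f, int(j))
                out[rows, f] = order[np.searchsorted(cdf, u[rows, f], side="right")
                                     .clip(max=len(cdf) - 1)]
        return out

    def _to_frame(self, codes: np.ndarray, sample_ids, labels) -> PhenotypeMatrix:
        cols = {}
        names = np.asarray(_LEVEL_NAMES, dtype=object)
        for f, fid in enumerate(self.spec.feature_ids):
            cols[fid] = names[codes[:, f]]
        df = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
        return PhenotypeMatrix(df, pd.Series(list(labels), index=df.index))

    def generate_extreme(self) -> PhenotypeMatrix:
        """Draw the extreme cohort (pure-class samples, no missing values)."""
        spec = self.spec
        rng = np.random.default_rng([_STREAM_EXTREME, spec.seed])
        class_idx = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
        codes = self._sample_classes(class_idx, rng)
        ids = [f"A{i + 1:04d}" for i in range(len(class_idx))]
        labels = [spec.class_names[j] for j in class_idx]
        return self._to_frame(codes, ids, labels)

    def generate_nonextreme(self) -> PhenotypeMatrix:
        """Draw mixture samples: per feature, one of the two parents at 1/2."""
        spec = self.spec
        rng = np.random.default_rng([_STREAM_MIX, spec.seed])
        rows, labels = [], []
        name_to_idx = {c: j for j, c in enumerate(spec.class_names)}
        p = spec.n_features
        for pair, count in spec.n_nonextreme.items():
            a, b = pair
            if a not in name_to_idx or b not in name_to_idx:
                raise ValueError(f"unknown parent class in pair {pair!r}")
            ja, jb = name_to_idx[a], name_to_idx[b]
            pick_a = rng.random((count, p)) < 0.5
            u = rng.random((count, p))
            codes = np.zeros((count, p), dtype=int)
            for f in range(p):
                for j, rows_mask in ((ja, pick_a[:, f]), (jb, ~pick_a[:, f])):
                    cdf, order = self._cdf_order(f, j)
                    idx = np.searchsorted(cdf, u[rows_mask, f], side="right")
                    codes[rows_mask, f] = order[idx.clip(max=len(cdf) - 1)]
            rows.append(codes)
            labels.extend([f"{a}+{b}"] * count)
        codes = np.vstack(rows) if rows else np.zeros((0, p), dtype=int)
        ids = [f"M{i + 1:04d}" for i in range(codes.shape[0])]
        return self._to_frame(codes, ids, labels)

    def generate_second_cohort(self, shared_features: int, n_per_class,
                               seed: int | None = None) -> PhenotypeMatrix:
        """An external-validation cohort from the same distributions.

        Restricted to the first ``shared_features`` features (informative
        features come first in the layout, then noise), with its own sample
        sizes and an independent random stream.
        """
        spec = self.spec
        if not 1 <= shared_features <= spec.n_features:
            raise ValueError("shared_features must be in [1, n_features]")
        if len(n_per_class) != spec.n_classes:
            raise ValueError("n_per_class: one count per class")
        rng = np.random.default_rng([_STREAM_SECOND, spec.seed if seed is None else seed])
        class_idx = np.repeat(np.arange(spec.n_classes), list(n_per_class))
        codes = self._sample_classes(class_idx, rng)
        ids = [f"B{i + 1:04d}" for i in range(len(class_idx))]
        labels = [spec.class_names[j] for j in class_idx]
        m = self._to_frame(codes, ids, labels)
        return m.select_features(spec.feature_ids[:shared_features])


# -- module-level convenience wrappers ------------------------------------

def generate_extreme(spec: CohortSpec) -> PhenotypeMatrix:
    return CohortModel(spec).generate_extreme()


def generate_nonextreme(spec: CohortSpec, model: CohortModel | None = None) -> PhenotypeMatrix:
    model = model if model is not None else CohortModel(spec)
    return model.generate_nonextreme()


def derive_second_cohort(spec: CohortSpec, shared_features: int, n_per_class,
                         seed: int | None = None) -> PhenotypeMatrix:
    return CohortModel(spec).generate_second_cohort(shared_features, n_per_class, seed)


def inject_missing(m: PhenotypeMatrix, rate: float, seed: int) -> PhenotypeMatrix:
    """Blank each cell independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = m.copy()
    if rate > 0.0:
        rng = np.random.default_rng([_STREAM_MISSING, seed])
        mask = rng.random(out.data.shape) < rate
        out.data = out.data.mask(mask)
    return out
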