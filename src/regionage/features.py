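"""Key-voxel selection by resampled age correlation.

The selector identifies, per region, the voxels whose values correlate
most stably with chronological age in the healthy training cohort. One
*round* draws half of the subjects, ranks voxels by correlation with age,
keeps the top half, and repeats this inner trial 100 times; the round's
key-voxel set is the intersection of the 100 per-trial top sets. The round
itself is repeated 100 times, and voxels appearing in more than 10 of the
100 round sets become the region's key features.

Under this scheme a pure-noise voxel survives a single round with
probability ~0.5^100, so the expected selection count of noise voxels is
essentially zero, while a genuinely age-informative voxel saturates at the
full round count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionParams", "FeatureMask", "voxel_age_corr",
           "key_voxels_single_round", "select_features"]

logger = logging.getLogger(__name__)

#: Minimum feature count retained by the empty-selection fallback.
FALLBACK_MIN_VOXELS = 10


@dataclass
class SelectionParams:
    """Resampling-procedure knobs.

    n_inner
        Half-sample trials per round (default 100).
    n_outer
        Rounds (default 100); selection counts are out of this.
    half_fraction
        Subsample fraction per trial; floor(half_fraction * n) subjects are
        drawn without replacement (default 0.5).
    top_fraction
        Fraction of voxels kept per trial, ceil(top_fraction * V), ranked
        by correlation magnitude with ties broken by lower voxel index
        (default 0.5).
    count_threshold
        A voxel is selected iff its round count strictly exceeds this
        (default 10, i.e. "> 10 of 100 rounds").
    signed_ranking
        Rank by signed r instead of |r|. Off by default: gray-matter and FA
        age correlations are predominantly negative and signed ranking
        would discard them.
    """

    n_inner: int = 100
    n_outer: int = 100
    half_fraction: float = 0.5
    top_fraction: float = 0.5
    count_threshold: int = 10
    signed_ranking: bool = False

    def __post_init__(self):
        if not 0 < self.half_fraction <= 1:
            raise ValueError("half_fraction must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_inner < 1 or self.n_outer < 1:
            raise ValueError("n_inner and n_outer must be positive")
        if not 0 <= self.count_threshold <= self.n_outer:
            raise ValueError("count_threshold must lie in [0, n_outer]")


@dataclass
class FeatureMask:
    """Outcome of the selection procedure for one region.

    ``selected_voxels`` follows the strict threshold rule
    (count > count_threshold). If that set is empty, ``feature_voxels``
    falls back to the highest-count voxels (at least 10) so downstream
    models always have at least one feature; ``fallback_used`` records
    this. Models consume ``feature_voxels``.
    """

    modality: str
    region_id: int
    selected_voxels: np.ndarray
    selection_counts: np.ndarray
    n_outer: int
    count_threshold: int
    fallback_used: bool = False
    n_region_voxels: int = 0

    def __post_init__(self):
        if self.n_region_voxels == 0:
            self.n_region_voxels = int(len(self.selection_counts))

    @property
    def feature_voxels(self) -> np.ndarray:
        if self.selected_voxels.size:
            return self.selected_voxels
        k = max(FALLBACK_MIN_VOXELS, self.count_threshold)
        k = min(k, self.n_region_voxels)
        order = np.argsort(-self.selection_counts, kind="stable")
        return np.sort(order[:k])


def voxel_age_corr(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Pearson r between each voxel (column) and chronological age.

    Zero-variance voxels get r = 0 by convention (logged). Requires at
    least 3 subjects and non-constant ages.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("values must be (n_subjects >= 3, n_voxels)")
    if y.shape != (x.shape[0],):
        raise ValueError("ages length must match number of subjects")
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("ages are constant; correlation undefined")
    xc = x - x.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    const = sx == 0
    if const.any():
        logger.debug("voxel_age_corr: %d zero-variance voxel(s) set to r=0", int(const.sum()))
    sx = np.where(const, 1.0, sx)
    r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[const] = 0.0
    return r


def _trial_subsets(rng: np.random.Generator, n_trials: int, n: int, m: int) -> np.ndarray:
    """Draw n_trials half-samples of size m without replacement.

    Contract (relied on by the replay oracle): one uniform (n_trials, n)
    matrix is drawn from ``rng`` and each trial's subset is the column
    indices of its m smallest entries.
    """
    u = rng.random((n_trials, n))
    return np.argsort(u, axis=1, kind="stable")[:, :m]


def _top_membership(values_c: np.ndarray, ages: np.ndarray, subsets: np.ndarray,
                    top_k: int, signed: bool) -> np.ndarray:
    """Boolean (n_trials, V): voxel in the trial's top-k by ranking statistic.

    Correlations for all trials are computed via subset-sum matrices (one
    matmul per moment), which keeps a full round at ~1 ms per region.
    """
    n_trials, m = subsets.shape
    n, V = values_c.shape
    sel = np.zeros((n_trials, n))
    rows = np.repeat(np.arange(n_trials), m)
    sel[rows, subsets.reshape(-1)] = 1.0

    y = ages
    sx = sel @ values_c                 # (n_trials, V) subset sums
    sxx = sel @ (values_c ** 2)
    sxy = sel @ (values_c * y[:, None])
    sy = sel @ y
    syy = sel @ (y ** 2)

    cov = sxy - sx * sy[:, None] / m
    varx = sxx - sx ** 2 / m
    vary = (syy - sy ** 2 / m)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.clip(varx, 0.0, None) * np.clip(vary, 0.0, None))
    r[~np.isfinite(r)] = 0.0

    stat = r if signed else np.abs(r)
    # stable sort on -stat: ties resolved by ascending voxel index
    order = np.argsort(-stat, axis=1, kind="stable")
    member = np.zeros((n_trials, V), dtype=bool)
    trial_rows = np.repeat(np.arange(n_trials), top_k)
    member[trial_rows, order[:, :top_k].reshape(-1)] = True
    return member


def key_voxels_single_round(values: np.ndarray, ages: np.ndarray,
                            params: SelectionParams, rng: np.random.Generator) -> np.ndarray:
    """One round: intersection of the per-trial top voxel sets.

    Each of ``params.n_inner`` trials draws floor(half_fraction * n)
    subjects without replacement, ranks voxels by correlation magnitude
    (ties by lower index) and keeps the top ceil(top_fraction * V). The
    returned sorted index array is the intersection across trials and may
    be empty.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 subjects for half-sample correlation")
    n, V = x.shape
    m = int(np.floor(params.half_fraction * n))
    if m < 3:
        raise ValueError("half-sample would have fewer than 3 subjects")
    top_k = int(np.ceil(params.top_fraction * V))
    subsets = _trial_subsets(rng, params.n_inner, n, m)
    member = _top_membership(x - x.mean(axis=0), y, subsets, top_k, params.signed_ranking)
    return np.flatnonzero(member.all(axis=0))


def select_features(values: np.ndarray, ages: np.ndarray, params: SelectionParams,
                    rng: np.random.Generator, *, modality: str = "GM",
                    region_id: int = 0) -> FeatureMask:
    """Full selection procedure for one region.

    Runs ``params.n_outer`` rounds on independent RNG sub-streams spawned
    from ``rng``; a voxel's selection count is the number of round sets
    containing it, and the key features are the voxels with count strictly
    above ``params.count_threshold``. An empty key set triggers the
    highest-count fallback (see FeatureMask) with a warning.
    """
    x = np.asarray(values, dtype=float)
    V = x.shape[1]
    counts = np.zeros(V, dtype=int)
    for child in rng.spawn(params.n_outer):
        counts[key_voxels_single_round(x, ages, params, child)] += 1
    selected = np.flatnonzero(counts > params.count_threshold)
    mask = FeatureMask(modality=modality, region_id=region_id,
                       selected_voxels=selected, selection_counts=counts,
                       n_outer=params.n_outer, count_threshold=params.count_threshold,
                       fallback_used=selected.size == 0, n_region_voxels=V)
    if mask.fallback_used:
        logger.warning("select_features: %s region %d selected no voxels above threshold; "
                       "falling back to %d highest-count voxels",
                       modality, region_id, mask.feature_voxels.size)
    return mask
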