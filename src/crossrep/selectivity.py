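"""Topographical selectivity maps and their comparison.

A selectivity map assigns each ROI voxel the condition with the largest
run-averaged beta (winner takes all). Maps are compared between groups with
a symmetric two-way correlation scheme — each subject's map against the
other group's average map, averaged in both directions — and significance is
assessed with a spatially constrained permutation null: the contiguous
same-label clusters of each map are held fixed and whole clusters are
randomly relabeled, preserving the map's spatial structure under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stats import (DEFAULT_N_PERM, PermutationResult, centered_ranks,
                    permutation_pvalue)
from .synthetic import PatternDataset

logger = logging.getLogger(__name__)

_CONN_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LabelMap:
    """Per-voxel winning condition over an ROI mask."""

    labels: np.ndarray            # (n_mask_voxels,) condition ids
    mask: np.ndarray              # flat voxel indices into the grid
    grid_shape: tuple
    granularity: int              # number of conditions (4 or 8)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.mask = np.asarray(self.mask)
        if self.labels.shape != self.mask.shape:
            raise ValueError("need exactly one label per mask voxel")
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= self.granularity):
            raise ValueError("labels outside the declared condition set")

    def volume(self, background: int = -1) -> np.ndarray:
        """Labels placed into the full grid (background elsewhere)."""
        vol = np.full(int(np.prod(self.grid_shape)), background, dtype=int)
        vol[self.mask] = self.labels
        return vol.reshape(self.grid_shape)


@dataclass
class ClusterDecomposition:
    """Partition of a map's mask into connected same-label clusters."""

    clusters: list                # list of index arrays into the *mask* axis
    labels: np.ndarray            # label of each cluster
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters])


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def winner_take_all(cond_betas: np.ndarray, mask, grid_shape,
                    granularity: int | None = None) -> LabelMap:
    """Label each voxel with the condition of its largest mean beta.

    ``cond_betas`` is (n_conditions, n_mask_voxels). Exact ties go to the
    lowest condition index (logged).
    """
    b = np.asarray(cond_betas, dtype=float)
    if np.any(~np.isfinite(b)):
        cond, vox = np.argwhere(~np.isfinite(b))[0]
        raise ValueError(f"non-finite beta at condition {cond}, mask voxel {vox}")
    labels = np.argmax(b, axis=0)
    n_ties = int(np.sum(np.sum(b == b.max(axis=0, keepdims=True), axis=0) > 1))
    if n_ties:
        logger.info("winner_take_all: %d voxel(s) tied; lowest condition index wins",
                    n_ties)
    return LabelMap(labels, np.asarray(mask), tuple(grid_shape),
                    granularity or b.shape[0])


def subject_map(dataset: PatternDataset, roi: str, granularity: int = 4) -> LabelMap:
    """Winner-take-all map of one subject's run-averaged betas."""
    b = dataset.condition_mean_betas(roi, granularity)
    return winner_take_all(b, dataset.roi_masks[roi], dataset.grid_shape, granularity)


def group_map(datasets: list, roi: str, granularity: int = 4) -> LabelMap:
    """Winner-take-all map of the across-subject mean betas."""
    if not datasets:
        raise ValueError("empty group")
    ref = datasets[0]
    mask = np.asarray(ref.roi_masks[roi])
    for d in datasets[1:]:
        if d.grid_shape != ref.grid_shape or not np.array_equal(
                np.asarray(d.roi_masks[roi]), mask):
            raise ValueError("subjects are not on a common grid/mask")
    mean_b = np.mean([d.condition_mean_betas(roi, granularity) for d in datasets],
                     axis=0)
    return winner_take_all(mean_b, mask, ref.grid_shape, granularity)


# ---------------------------------------------------------------------------
# clusters and the constrained null
# ---------------------------------------------------------------------------

def cluster_decomposition(label_map: LabelMap, connectivity: int = 6
                          ) -> ClusterDecomposition:
    """Connected same-label clusters of a map (6/18/26-connectivity)."""
    if connectivity not in _CONN_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    struct = _CONN_STRUCTS[connectivity]
    vol = label_map.volume()
    lookup = np.full(int(np.prod(label_map.grid_shape)), -1, dtype=int)
    lookup[label_map.mask] = np.arange(label_map.mask.size)
    clusters, labels = [], []
    for lab in np.unique(label_map.labels):
        comp, n = ndimage.label(vol == lab, structure=struct)
        for k in range(1, n + 1):
            flat = np.flatnonzero((comp == k).ravel())
            idx = lookup[flat]
            clusters.append(idx[idx >= 0])
            labels.append(int(lab))
    return ClusterDecomposition(clusters, np.array(labels), connectivity)


def n_cluster_assignments(decomp: ClusterDecomposition, n_conditions: int) -> int:
    """Size of the constrained-null space: n_conditions ** n_clusters."""
    return int(n_conditions) ** decomp.n_clusters


def _relabel(decomp: ClusterDecomposition, n_vox: int, n_conditions: int, rng
             ) -> np.ndarray:
    """One constrained-null draw: each cluster gets a uniform random label."""
    out = np.empty(n_vox, dtype=int)
    draw = rng.integers(0, n_conditions, size=decomp.n_clusters)
    for lab, idx in zip(draw, decomp.clusters):
        out[idx] = lab
    return out


def constrained_null(label_map: LabelMap, other_labels: np.ndarray,
                     n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                     connectivity: int = 6) -> PermutationResult:
    """Cluster-constrained null for the Spearman correlation of two maps.

    The observed statistic correlates ``label_map`` with ``other_labels``
    (integer-coded, same mask order); the null relabels whole clusters of
    ``label_map`` uniformly at random. Raises if the map has too few
    clusters to support ``n_perm`` distinct assignments.
    """
    decomp = cluster_decomposition(label_map, connectivity)
    n_cond = label_map.granularity
    if n_cluster_assignments(decomp, n_cond) < n_perm:
        raise InsufficientClustersError(
            f"map has {decomp.n_clusters} clusters: only "
            f"{n_cond ** decomp.n_clusters} assignments < n_perm={n_perm}"
        )
    rng = np.random.default_rng(seed)
    v = centered_ranks(np.asarray(other_labels, dtype=float))
    nv = np.linalg.norm(v)

    def corr(labels):
        u = centered_ranks(labels.astype(float))
        nu = np.linalg.norm(u)
        if nu == 0 or nv == 0:
            return 0.0
        return float(u @ v / (nu * nv))

    observed = corr(label_map.labels)
    null = np.array([corr(_relabel(decomp, label_map.labels.size, n_cond, rng))
                     for _ in range(n_perm)])
    p = permutation_pvalue(observed, null, tail="one")
    return PermutationResult(observed, null, p, "one", n_perm, seed,
                             extra={"n_clusters": decomp.n_clusters})


class InsufficientClustersError(ValueError):
    """A subject's map has too few clusters for the permutation budget."""


# ---------------------------------------------------------------------------
# group-level map correlation
# ---------------------------------------------------------------------------

def map_group_correlation(maps_a: tuple, maps_b: tuple,
                          n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                          connectivity: int = 6) -> PermutationResult:
    """Two-way averaged Spearman correlation between two groups of maps.

    Step 1: Spearman of each Group-A subject map with the Group-B average
    map, averaged over subjects; step 2: the mirror direction; step 3: the
    mean of the two. Maps are correlated as integer-coded label vectors with
    the study-wide condition coding.

    ``maps_a`` and ``maps_b`` are ``(subject_maps, group_average_map)``
    tuples, the average map built with :func:`group_map` from across-subject
    mean betas.

    The permutation null relabels the fixed spatial clusters of every map
    (subject maps and average maps) uniformly at random each iteration.
    Subjects whose map supports fewer than ``n_perm`` constrained
    assignments are excluded with a warning; an empty group after exclusion
    raises.
    """
    subj_a, mean_a = maps_a
    subj_b, mean_b = maps_b
    n_cond = mean_a.granularity

    def usable(maps):
        kept, dropped = [], 0
        for m in maps:
            d = cluster_decomposition(m, connectivity)
            if n_cluster_assignments(d, n_cond) < n_perm:
                dropped += 1
            else:
                kept.append((m, d))
        return kept, dropped

    kept_a, drop_a = usable(subj_a)
    kept_b, drop_b = usable(subj_b)
    if drop_a or drop_b:
        warnings.warn(
            f"excluded {drop_a}+{drop_b} subject map(s) with too few clusters "
            f"for {n_perm} constrained permutations", stacklevel=2)
    if not kept_a or not kept_b:
        raise ValueError("a group is empty after cluster-count exclusions")

    dec_mean_a = cluster_decomposition(mean_a, connectivity)
    dec_mean_b = cluster_decomposition(mean_b, connectivity)
    rng = np.random.default_rng(seed)

    def stat(labels_a_list, meanb_labels, labels_b_list, meana_labels):
        s1 = np.mean([_corr_pair(la, meanb_labels) for la in labels_a_list])
        s2 = np.mean([_corr_pair(lb, meana_labels) for lb in labels_b_list])
        return 0.5 * (s1 + s2)

    obs = stat([m.labels for m, _ in kept_a], mean_b.labels,
               [m.labels for m, _ in kept_b], mean_a.labels)

    nv_a = mean_a.labels.size
    nv_b = mean_b.labels.size
    null = np.empty(n_perm)
    for it in range(n_perm):
        la = [_relabel(d, nv_a, n_cond, rng) for _, d in kept_a]
        mb = _relabel(dec_mean_b, nv_b, n_cond, rng)
        lb = [_relabel(d, nv_b, n_cond, rng) for _, d in kept_b]
        ma = _relabel(dec_mean_a, nv_a, n_cond, rng)
        null[it] = stat(la, mb, lb, ma)
    p = permutation_pvalue(obs, null, tail="one")
    return PermutationResult(obs, null, p, "one", n_perm, seed,
                             extra={"excluded": drop_a + drop_b,
                                    "n_a": len(kept_a), "n_b": len(kept_b)})


def _corr_pair(labels_x, labels_y) -> float:
    u = centered_ranks(np.asarray(labels_x, dtype=float))
    v = centered_ranks(np.asarray(labels_y, dtype=float))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# Jaccard and voxel counts
# ---------------------------------------------------------------------------

@dataclass
class JaccardResult:
    score: float
    degenerate: bool = False


def jaccard(map_a: LabelMap, map_b: LabelMap, category: int) -> JaccardResult:
    """|A n B| / |A u B| over voxels preferring ``category`` in each map.

    Both sets empty is defined as 0 with a degenerate flag.
    """
    if not np.array_equal(map_a.mask, map_b.mask):
        raise ValueError("maps must share a common mask")
    a = map_a.labels == category
    b = map_b.labels == category
    union = np.sum(a | b)
    if union == 0:
        return JaccardResult(0.0, degenerate=True)
    return JaccardResult(float(np.sum(a & b) / union))


def within_group_jaccard(datasets: list, roi: str, granularity: int = 4,
                         leave_one_out: bool = False) -> np.ndarray:
    """Per-subject, per-category Jaccard against the group map.

    By default the group map includes the subject itself; ``leave_one_out``
    rebuilds the group map without the subject.
    """
    maps = [subject_map(d, roi, granularity) for d in datasets]
    out = np.empty((len(datasets), granularity))
    for i, m in enumerate(maps):
        if leave_one_out:
            others = [d for k, d in enumerate(datasets) if k != i]
            gm = group_map(others, roi, granularity)
        else:
            gm = group_map(datasets, roi, granularity)
        for c in range(granularity):
            out[i, c] = jaccard(m, gm, c).score
    return out


def selective_voxel_counts(label_map: LabelMap) -> np.ndarray:
    """Number of voxels preferring each condition; sums to the mask size."""
    return np.bincount(label_map.labels, minlength=label_map.granularity)
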