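"""Representational similarity analysis across groups, models and subjects.

All comparisons operate on vectorized DSMs: the upper triangle excluding
the diagonal, in the fixed lexicographic category-pair order (28 entries
for 8 categories). Group-to-group similarity uses the symmetric three-step
scheme — each subject of one group against the other group's average DSM,
averaged over subjects, mirrored, and the two direction means averaged —
with a condition-relabeling permutation null. Model comparisons use partial
Spearman correlation so each model is assessed with the other's shared
variance removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

from .design import DSM, permute_pair_vector_index, vectorize_dsm
from .stats import (DEFAULT_N_PERM, PermutationResult, centered_ranks,
                    permutation_pvalue)


def dsm_vectors(dsms: list) -> np.ndarray:
    """Stack vectorized DSMs into an (n_subjects, n_pairs) array."""
    return np.stack([vectorize_dsm(d.matrix) if isinstance(d, DSM)
                     else np.asarray(d, dtype=float) for d in dsms])


def _unit_ranks(x: np.ndarray) -> np.ndarray:
    """Centered midranks scaled to unit norm (rows if 2-D)."""
    u = centered_ranks(np.atleast_2d(x), axis=1)
    n = np.linalg.norm(u, axis=1, keepdims=True)
    n[n == 0] = np.nan
    return u / n


def two_way_group_stat(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Symmetric three-step statistic on two stacks of subject vectors."""
    ua = _unit_ranks(vec_a)
    ub = _unit_ranks(vec_b)
    mb = _unit_ranks(vec_b.mean(axis=0))[0]
    ma = _unit_ranks(vec_a.mean(axis=0))[0]
    s1 = float(np.mean(ua @ mb))
    s2 = float(np.mean(ub @ ma))
    return 0.5 * (s1 + s2)


def _condition_perm_indices(rng, n_categories: int, n: int) -> np.ndarray:
    """n draws of the pair-vector index realizing a random category perm."""
    out = np.empty((n, n_categories * (n_categories - 1) // 2), dtype=np.intp)
    for k in range(n):
        out[k] = permute_pair_vector_index(rng.permutation(n_categories),
                                           n_categories)
    return out


def group_dsm_correlation(dsms_a, dsms_b, n_categories: int = 8,
                          n_perm: int = DEFAULT_N_PERM,
                          seed: int | None = None) -> PermutationResult:
    """Three-step between-group DSM correlation with a condition-label null.

    Each null iteration draws an independent random category relabeling for
    every subject and recomputes the *whole* three-step statistic on the
    relabeled data — including the group averages, which are rebuilt from
    the permuted subject vectors. Rebuilding the averages (rather than
    permuting a precomputed average wholesale) preserves the dependence
    between the two direction terms through each subject's contribution to
    its own group's mean, which simulation shows is required for the p-value
    to be calibrated under a true null. p is one-tailed for positive
    association.
    """
    va = dsm_vectors(dsms_a)
    vb = dsm_vectors(dsms_b)
    if va.shape[1] != vb.shape[1]:
        raise ValueError("DSM vectors must have equal length and ordering")
    observed = two_way_group_stat(va, vb)

    ua = _unit_ranks(va)
    ub = _unit_ranks(vb)
    rng = np.random.default_rng(seed)
    na, nb = ua.shape[0], ub.shape[0]
    null = np.empty(n_perm)
    for it in range(n_perm):
        pa = _condition_perm_indices(rng, n_categories, na)
        pb = _condition_perm_indices(rng, n_categories, nb)
        ua_p = np.take_along_axis(ua, pa, axis=1)
        ub_p = np.take_along_axis(ub, pb, axis=1)
        ma_p = _unit_ranks(np.take_along_axis(va, pa, axis=1).mean(axis=0))[0]
        mb_p = _unit_ranks(np.take_along_axis(vb, pb, axis=1).mean(axis=0))[0]
        s1 = float(np.mean(ua_p @ mb_p))
        s2 = float(np.mean(ub_p @ ma_p))
        null[it] = 0.5 * (s1 + s2)
    p = permutation_pvalue(observed, null, tail="one")
    return PermutationResult(observed, null, p, "one", n_perm, seed)


def pair_difference_test(fixed_dsms, dsms_1, dsms_2, n_categories: int = 8,
                         n_perm: int = DEFAULT_N_PERM,
                         seed: int | None = None) -> PermutationResult:
    """Difference of two group-pair correlations sharing one group.

    Observed statistic: r(fixed, group1) - r(fixed, group2) under the
    three-step scheme. The null keeps the shared group fixed and reshuffles
    which subjects belong to group1 vs group2; two-tailed p.
    """
    vf = dsm_vectors(fixed_dsms)
    v1 = dsm_vectors(dsms_1)
    v2 = dsm_vectors(dsms_2)
    observed = two_way_group_stat(vf, v1) - two_way_group_stat(vf, v2)
    pool = np.vstack([v1, v2])
    n1 = v1.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for it in range(n_perm):
        idx = rng.permutation(pool.shape[0])
        g1, g2 = pool[idx[:n1]], pool[idx[n1:]]
        null[it] = two_way_group_stat(vf, g1) - two_way_group_stat(vf, g2)
    p = permutation_pvalue(observed, null, tail="two")
    return PermutationResult(observed, null, p, "two", n_perm, seed)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def partial_spearman(x, y, controlling) -> float:
    """Partial Spearman rho of x and y with ``controlling`` regressed out.

    All three vectors are rank-transformed; the partial correlation is the
    Pearson correlation of the rank residuals after projecting out the
    control ranks (and the intercept).
    """
    zx = centered_ranks(np.asarray(x, dtype=float))
    zy = centered_ranks(np.asarray(y, dtype=float))
    zn = centered_ranks(np.asarray(controlling, dtype=float))
    for name, v in (("x", zx), ("y", zy), ("controlling", zn)):
        if np.linalg.norm(v) == 0:
            raise ValueError(f"constant {name} vector: partial rank "
                             "correlation is undefined")
    qn = zn / np.linalg.norm(zn)
    rx = zx - (zx @ qn) * qn
    ry = zy - (zy @ qn) * qn
    # a variable fully explained by the control has no residual variance:
    # no association is left to measure (e.g. target identical to nuisance)
    if (np.linalg.norm(rx) <= 1e-9 * np.linalg.norm(zx)
            or np.linalg.norm(ry) <= 1e-9 * np.linalg.norm(zy)):
        return 0.0
    return float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))


def partial_model_correlation(brain_vec, target_vec, nuisance_vec,
                              n_categories: int = 8,
                              n_perm: int = DEFAULT_N_PERM,
                              seed: int | None = None,
                              tail: str = "one") -> PermutationResult:
    """Partial Spearman of a brain DSM with a model DSM, controlling another.

    The null relabels the conditions of the brain vector (category
    permutations) and recomputes the partial correlation; one-tailed against
    the positive tail by default — a negative observed correlation therefore
    yields p >= 0.5, never "significant negativity".
    """
    brain_vec = np.asarray(brain_vec, dtype=float)
    observed = partial_spearman(brain_vec, target_vec, nuisance_vec)

    zb = centered_ranks(brain_vec)
    zt = centered_ranks(np.asarray(target_vec, dtype=float))
    zn = centered_ranks(np.asarray(nuisance_vec, dtype=float))
    qn = zn / np.linalg.norm(zn)
    wt = zt - (zt @ qn) * qn
    wt = wt / np.linalg.norm(wt)

    rng = np.random.default_rng(seed)
    idx = _condition_perm_indices(rng, n_categories, n_perm)
    B = zb[idx]                                   # ranks permute with entries
    B = B - B.mean(axis=1, keepdims=True)
    B = B - (B @ qn)[:, None] * qn
    norms = np.linalg.norm(B, axis=1)
    norms[norms == 0] = np.nan
    null = (B @ wt) / norms
    p = permutation_pvalue(observed, null[np.isfinite(null)], tail=tail)
    return PermutationResult(observed, null, p, tail, n_perm, seed)


# ---------------------------------------------------------------------------
# inter-subject correlation
# ---------------------------------------------------------------------------

@dataclass
class InterSubjectResult:
    matrix: np.ndarray             # n_subjects x n_subjects Spearman
    group_labels: np.ndarray
    group_names: list
    within: dict                   # group -> block mean (upper half, no diag)
    between: dict                  # (group_i, group_j) -> block mean
    ranked: list                   # [(name, value)] sorted descending
    p_values: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _block_means(mat, labels, names):
    within, between = {}, {}
    for gi, g in enumerate(names):
        idx = np.flatnonzero(labels == gi)
        if idx.size < 2:
            within[g] = float("nan")
            continue
        block = mat[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        within[g] = float(block[iu].mean())
    for gi in range(len(names)):
        for gj in range(gi + 1, len(names)):
            bi = np.flatnonzero(labels == gi)
            bj = np.flatnonzero(labels == gj)
            between[(names[gi], names[gj])] = float(mat[np.ix_(bi, bj)].mean())
    return within, between


def intersubject_matrix(dsms, group_labels, group_names=None,
                        n_perm: int = DEFAULT_N_PERM,
                        seed: int | None = None) -> InterSubjectResult:
    """Subject-by-subject Spearman matrix of DSM vectors with block summaries.

    Within-group block means use the upper half of each diagonal block
    (diagonal excluded); between-group means use the full off-diagonal
    block. Each block mean gets a one-tailed p from a group-label
    permutation null. A singleton group's within-mean is NaN (flagged).
    """
    v = dsm_vectors(dsms)
    labels = np.asarray(group_labels)
    if group_names is None:
        group_names = [str(g) for g in np.unique(labels)]
        labels = np.searchsorted(np.unique(labels), labels)
    u = _unit_ranks(v)
    mat = u @ u.T
    np.fill_diagonal(mat, 1.0)
    within, between = _block_means(mat, labels, group_names)

    rng = np.random.default_rng(seed)
    keys = list(within) + list(between)
    null = {k: np.empty(n_perm) for k in keys}
    for it in range(n_perm):
        perm = rng.permutation(labels)
        w, b = _block_means(mat, perm, group_names)
        for k in w:
            null[k][it] = w[k]
        for k in b:
            null[k][it] = b[k]
    pvals = {}
    for k in keys:
        obs = within.get(k) if k in within else between[k]
        nl = null[k]
        nl = nl[np.isfinite(nl)]
        pvals[k] = (float("nan") if not np.isfinite(obs) or nl.size == 0
                    else permutation_pvalue(obs, nl, tail="one"))

    entries = [(g, within[g]) for g in within] + \
              [(f"{a}-{b}", between[(a, b)]) for a, b in between]
    ranked = sorted(entries, key=lambda kv: (np.isnan(kv[1]), -kv[1]))
    singletons = [g for g in within if np.isnan(within[g])]
    return InterSubjectResult(mat, labels, list(group_names), within, between,
                              ranked, pvals, extra={"singletons": singletons,
                                                    "n_perm": n_perm})


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_clusters(dsm: DSM | np.ndarray, k: int,
                          linkage: str = "single") -> np.ndarray:
    """Cut an agglomerative tree of the DSM's distances into k clusters.

    The DSM is used directly as inter-category distances (condensed upper
    triangle); returns a 0-based cluster id per category. Cuts of the same
    tree are nested as k grows.
    """
    mat = dsm.matrix if isinstance(dsm, DSM) else np.asarray(dsm, dtype=float)
    n = mat.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    z = hierarchy.linkage(vectorize_dsm(mat), method=linkage)
    return hierarchy.fcluster(z, t=k, criterion="maxclust") - 1


def clustering_dendrogram(dsm: DSM | np.ndarray, linkage: str = "single"):
    """The full linkage matrix (for inspection / ultrametric checks)."""
    mat = dsm.matrix if isinstance(dsm, DSM) else np.asarray(dsm, dtype=float)
    return hierarchy.linkage(vectorize_dsm(mat), method=linkage)
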