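"""Representational connectivity: seed-to-parcel DSM correlation profiles.

Each subject's neural DSM is extracted in a set of seed ROIs and in parcels
covering the rest of the brain; the Spearman correlation of every seed DSM
with every target DSM forms a (seeds x targets) connectivity profile.
Profiles are z-normalized (Fisher r-to-z, then standardized within seed
across targets — both steps toggleable) and compared between groups with
the same symmetric three-step scheme used for DSMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decoding import ClassifierConfig, neural_dsm
from .design import DSM, vectorize_dsm
from .rsa import _unit_ranks, two_way_group_stat
from .stats import (DEFAULT_N_PERM, PermutationResult, fisher_z,
                    permutation_pvalue, spearman)
from .synthetic import PatternDataset


def parcel_dsms(dataset: PatternDataset, parcels: list,
                config: ClassifierConfig | None = None) -> dict:
    """One decoding-based neural DSM per named parcel."""
    out = {}
    for name in parcels:
        if name not in dataset.roi_masks:
            raise ValueError(f"unknown parcel {name!r}")
        if np.asarray(dataset.roi_masks[name]).size == 0:
            raise ValueError(f"empty parcel {name!r}")
        out[name] = neural_dsm(dataset, name, config)
    return out


@dataclass
class ConnectivityProfile:
    """Seeds x targets matrix of (normalized) seed-target DSM correlations."""

    matrix: np.ndarray
    seeds: list
    targets: list
    normalized: bool = True
    degenerate: list = field(default_factory=list)
    subject_id: str | None = None
    group_id: str | None = None

    def vector(self) -> np.ndarray:
        """Flattened profile in fixed (seed, target) order."""
        return self.matrix.ravel()


def connectivity_profile(seed_dsms: dict, target_dsms: dict,
                         fisher: bool = True, standardize: bool = True,
                         subject_id=None, group_id=None) -> ConnectivityProfile:
    """Spearman correlations of each seed DSM with each target DSM.

    Raw correlations are Fisher r-to-z transformed and then z-scored within
    each seed across targets (the default "z-normalization"; either step can
    be disabled). A constant DSM vector yields a degenerate (zero) entry,
    flagged rather than silently dropped.
    """
    seeds = list(seed_dsms)
    targets = list(target_dsms)
    m = np.zeros((len(seeds), len(targets)))
    degenerate = []
    for i, s in enumerate(seeds):
        sv = vectorize_dsm(seed_dsms[s].matrix if isinstance(seed_dsms[s], DSM)
                           else np.asarray(seed_dsms[s]))
        for j, t in enumerate(targets):
            tv = vectorize_dsm(target_dsms[t].matrix
                               if isinstance(target_dsms[t], DSM)
                               else np.asarray(target_dsms[t]))
            r = spearman(sv, tv)
            if not np.isfinite(r):
                degenerate.append((s, t))
                r = 0.0
            m[i, j] = r
    if degenerate:
        warnings.warn(f"degenerate (constant-DSM) entries: {degenerate}",
                      stacklevel=2)
    if fisher:
        m = fisher_z(np.clip(m, -0.999999, 0.999999))
    if standardize:
        sd = m.std(axis=1, keepdims=True)
        mean = m.mean(axis=1, keepdims=True)
        # a seed whose correlations are all (numerically) equal carries no
        # profile information: its z-scores are defined as 0
        tol = 1e-10 * (np.abs(m).max(axis=1, keepdims=True) + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(sd > tol, (m - mean) / sd, 0.0)
    return ConnectivityProfile(m, seeds, targets,
                               normalized=fisher or standardize,
                               degenerate=degenerate,
                               subject_id=subject_id, group_id=group_id)


def subject_profile(dataset: PatternDataset, seeds: list, targets: list,
                    config: ClassifierConfig | None = None,
                    fisher: bool = True, standardize: bool = True
                    ) -> ConnectivityProfile:
    """Convenience: decode all seed and target parcels, then profile them."""
    sd = parcel_dsms(dataset, seeds, config)
    td = parcel_dsms(dataset, targets, config)
    return connectivity_profile(sd, td, fisher=fisher, standardize=standardize,
                                subject_id=dataset.subject_id,
                                group_id=dataset.group_id)


def _profile_vectors(profiles: list) -> np.ndarray:
    ref = (profiles[0].seeds, profiles[0].targets)
    for p in profiles[1:]:
        if (p.seeds, p.targets) != ref:
            raise ValueError("profiles have mismatched seed/target sets")
    return np.stack([p.vector() for p in profiles])


def profile_group_correlation(profiles_a: list, profiles_b: list,
                              n_perm: int = DEFAULT_N_PERM,
                              seed: int | None = None) -> PermutationResult:
    """Three-step correlation of connectivity profiles between two groups.

    The permutation null shuffles the (seed, target) entry labels of every
    subject profile independently and recomputes the whole statistic,
    rebuilding the group-average profiles from the permuted subject vectors
    (required for a calibrated p under a true null); one-tailed p.
    """
    va = _profile_vectors(profiles_a)
    vb = _profile_vectors(profiles_b)
    if va.shape[1] != vb.shape[1]:
        raise ValueError("mismatched parcellations")
    observed = two_way_group_stat(va, vb)
    rng = np.random.default_rng(seed)
    m = va.shape[1]
    # ranks permute with entries, so permuting precomputed unit ranks is
    # exactly the Spearman of the permuted vectors
    ua = _unit_ranks(va)
    ub = _unit_ranks(vb)
    null = np.empty(n_perm)
    for it in range(n_perm):
        pa = rng.permuted(np.broadcast_to(np.arange(m), ua.shape), axis=1)
        pb = rng.permuted(np.broadcast_to(np.arange(m), ub.shape), axis=1)
        ma_p = _unit_ranks(np.take_along_axis(va, pa, axis=1).mean(axis=0))[0]
        mb_p = _unit_ranks(np.take_along_axis(vb, pb, axis=1).mean(axis=0))[0]
        s1 = np.mean(np.take_along_axis(ua, pa, axis=1) @ mb_p)
        s2 = np.mean(np.take_along_axis(ub, pb, axis=1) @ ma_p)
        null[it] = 0.5 * (s1 + s2)
    p = permutation_pvalue(observed, null, tail="one")
    return PermutationResult(observed, null, p, "one", n_perm, seed)


def profile_pair_difference(fixed_profiles: list, profiles_1: list,
                            profiles_2: list, n_perm: int = DEFAULT_N_PERM,
                            seed: int | None = None) -> PermutationResult:
    """Shared-group-fixed shuffle test on profile correlations (two-tailed)."""
    from .rsa import pair_difference_test

    vf = _profile_vectors(fixed_profiles)
    v1 = _profile_vectors(profiles_1)
    v2 = _profile_vectors(profiles_2)
    # reuse the DSM pair-difference machinery on raw vectors
    return pair_difference_test(list(vf), list(v1), list(v2),
                                n_perm=n_perm, seed=seed)
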