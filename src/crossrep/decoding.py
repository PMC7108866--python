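"""Cross-validated pairwise category classification and the neural DSM.

Each unordered category pair is decoded with a linear support-vector
classifier (LIBSVM, C=1, raw betas as features) under leave-one-run-out
cross-validation: train on the exemplars of all runs but one, test on the
held-out run. The 28 pairwise accuracies of an 8-category design, arranged
as a symmetric matrix with zero diagonal, form the subject's neural
dissimilarity matrix: hard-to-discriminate pairs are representationally
similar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .design import DSM, category_pairs, vectorize_dsm
from .stats import TTestResult, fdr_bh, one_sample_t
from .synthetic import PatternDataset

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    """Linear SVM configuration (all knobs exposed, defaults declared)."""

    C: float = 1.0
    demean_runs: bool = False   # optional per-run feature demeaning

    def make(self):
        return SVC(kernel="linear", C=self.C)


def _pair_patterns(dataset: PatternDataset, roi: str, cat_a: int, cat_b: int):
    """Per-run train/test arrays for one binary problem.

    Returns X (n_exemplars, n_vox), y (labels), runs (run index per row).
    """
    labels = np.asarray(dataset.stimulus_labels)
    sel = np.flatnonzero((labels == cat_a) | (labels == cat_b))
    if sel.size == 0:
        raise ValueError(f"no stimuli for categories {cat_a}/{cat_b}")
    b = dataset.roi_betas(roi)[sel]              # (n_sel, n_runs, n_vox)
    n_sel, n_runs, n_vox = b.shape
    X = b.transpose(1, 0, 2).reshape(n_runs * n_sel, n_vox)
    y = np.tile(labels[sel], n_runs)
    runs = np.repeat(np.arange(n_runs), n_sel)
    return X, y, runs


def binary_decode(dataset: PatternDataset, roi: str, cat_a: int, cat_b: int,
                  config: ClassifierConfig | None = None) -> float:
    """Leave-one-run-out accuracy of the cat_a vs cat_b linear SVM.

    Every run must contain exemplars of both categories; accuracy is the
    mean over folds of the fraction of held-out exemplars classified
    correctly. Deterministic given the data and configuration.
    """
    config = config or ClassifierConfig()
    X, y, runs = _pair_patterns(dataset, roi, cat_a, cat_b)
    n_runs = dataset.n_runs
    if n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    for r in range(n_runs):
        present = set(y[runs == r])
        if present != {cat_a, cat_b}:
            raise ValueError(f"run {r} is missing a class for pair "
                             f"({cat_a}, {cat_b})")
    if config.demean_runs:
        X = X.copy()
        for r in range(n_runs):
            X[runs == r] -= X[runs == r].mean(axis=0, keepdims=True)
    fold_acc = np.empty(n_runs)
    for r in range(n_runs):
        train, test = runs != r, runs == r
        clf = config.make()
        clf.fit(X[train], y[train])
        fold_acc[r] = np.mean(clf.predict(X[test]) == y[test])
    return float(fold_acc.mean())


def neural_dsm(dataset: PatternDataset, roi: str,
               config: ClassifierConfig | None = None) -> DSM:
    """All pairwise decoding accuracies as a symmetric DSM (zero diagonal)."""
    design = dataset.design
    n = design.n_categories
    present = set(np.asarray(dataset.stimulus_labels).tolist())
    if present != set(range(n)):
        raise ValueError("all categories must be present to build the DSM")
    m = np.zeros((n, n))
    for i, j in category_pairs(n):
        try:
            acc = binary_decode(dataset, roi, i, j, config)
        except ValueError as err:
            raise ValueError(f"pair ({i}, {j}): {err}") from err
        m[i, j] = m[j, i] = acc
    cfg = config or ClassifierConfig()
    return DSM(m, design.category_names, kind="neural",
               meta={"roi": roi, "subject": dataset.subject_id,
                     "group": dataset.group_id, "n_folds": dataset.n_runs,
                     "classifier": {"kernel": "linear", "C": cfg.C,
                                    "demean_runs": cfg.demean_runs}})


def mean_accuracy(dsm: DSM) -> float:
    """Mean of the unique pairwise accuracies of one subject's neural DSM."""
    v = vectorize_dsm(dsm.matrix)
    if v.size != dsm.n * (dsm.n - 1) // 2:
        raise ValueError("incomplete DSM")
    return float(v.mean())


@dataclass
class ChanceTestResult:
    subject_means: np.ndarray
    ttest: TTestResult
    p_fdr: float | None = None
    extra: dict = field(default_factory=dict)


def group_chance_test(dsms: list, chance: float = 0.5, tail: str = "two",
                      family_pvals=None) -> ChanceTestResult:
    """Group-level one-sample t-test of mean accuracies against chance.

    If ``family_pvals`` (p-values of the other contrasts in the declared FDR
    family) is given, the FDR-adjusted p for this contrast is reported too.
    """
    means = np.array([mean_accuracy(d) for d in dsms])
    tt = one_sample_t(means, mu0=chance, tail=tail)
    p_fdr = None
    if family_pvals is not None and not tt.degenerate:
        adj = fdr_bh(np.concatenate([[tt.p], np.asarray(family_pvals, float)]))
        p_fdr = float(adj[0])
    return ChanceTestResult(means, tt, p_fdr)
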