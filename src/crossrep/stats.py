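"""Shared inference machinery: permutation engines, FDR, Fisher transform,
thin parametric tests, and fast rank-correlation helpers.

All permutation p-values use the add-one estimator
``p = (1 + #{null >= observed}) / (n_perm + 1)`` so a permutation p-value is
never exactly zero and always at least ``1 / (n_perm + 1)``. Two-tailed
p-values double the smaller tail and are capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 10_000


# ---------------------------------------------------------------------------
# rank helpers (vectorized Spearman used throughout the permutation engines)
# ---------------------------------------------------------------------------

def centered_ranks(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Midranks along ``axis``, centered to zero mean (ties averaged)."""
    r = sps.rankdata(np.asarray(x, dtype=float), axis=axis)
    return r - r.mean(axis=axis, keepdims=True)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho of two 1-D vectors (midranks; NaN if either is constant)."""
    u = centered_ranks(np.asarray(x))
    v = centered_ranks(np.asarray(y))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(u @ v / (nu * nv))


def spearman_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``X`` with the vector ``y``."""
    U = centered_ranks(np.atleast_2d(X), axis=1)
    v = centered_ranks(np.asarray(y))
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (U @ v) / (nu * nv)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p: float
    tail: str
    n_perm: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def permutation_pvalue(observed: float, null_values: np.ndarray, tail: str = "one") -> float:
    """Add-one permutation p-value from a null sample.

    ``tail="one"`` tests the upper tail (observed in the top alpha fraction);
    ``tail="two"`` doubles the smaller tail, capped at 1.
    """
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    if n < 1:
        raise ValueError("need at least one permutation")
    p_hi = (1 + np.sum(null_values >= observed)) / (n + 1)
    if tail == "one":
        return float(p_hi)
    if tail == "two":
        p_lo = (1 + np.sum(null_values <= observed)) / (n + 1)
        return float(min(1.0, 2 * min(p_hi, p_lo)))
    raise ValueError(f"unknown tail {tail!r}")


def permutation_test(statistic_fn, permuter, n_perm: int = DEFAULT_N_PERM,
                     tail: str = "one", seed: int | None = None) -> PermutationResult:
    """Generic permutation test.

    ``statistic_fn()`` returns the observed statistic; ``permuter(rng)``
    returns one draw from the exchangeable null. The null distribution is
    reproducible from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn())
    null = np.array([float(permuter(rng)) for _ in range(n_perm)])
    p = permutation_pvalue(observed, null, tail=tail)
    return PermutationResult(observed, null, p, tail, n_perm, seed)


# ---------------------------------------------------------------------------
# standard corrections / transforms / tests
# ---------------------------------------------------------------------------

def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-z transform, ``z = atanh(r)``; requires ``|r| < 1``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z) -> np.ndarray | float:
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    degenerate: bool = False


def one_sample_t(values, mu0: float = 0.0, tail: str = "two") -> TTestResult:
    """One-sample t-test of ``values`` against ``mu0``.

    A zero-variance sample is flagged degenerate (t undefined) rather than
    raising, since it legitimately occurs for constant accuracy vectors.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two observations")
    if np.allclose(v.std(ddof=1), 0.0):
        return TTestResult(float("nan"), v.size - 1, float("nan"), float(v.mean()),
                           degenerate=True)
    alternative = {"two": "two-sided", "one": "greater"}[tail]
    res = sps.ttest_1samp(v, popmean=mu0, alternative=alternative)
    return TTestResult(float(res.statistic), v.size - 1, float(res.pvalue), float(v.mean()))


def independent_t(a, b, tail: str = "two") -> tuple[float, float]:
    """Thin two-sample t-test wrapper (Levene-checked variance pooling)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    equal_var = sps.levene(a, b).pvalue > 0.05
    alternative = {"two": "two-sided", "one": "greater"}[tail]
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def repeated_measures_anova(data, subject: str, within: list[str], dv: str):
    """Thin wrapper over statsmodels AnovaRM (declared plumbing)."""
    from statsmodels.stats.anova import AnovaRM

    return AnovaRM(data, depvar=dv, subject=subject, within=within).fit()
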