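"""Representational model DSMs built from stimulus properties and ratings.

Three model geometries are supported:

* **pitch** — fundamental frequency per category estimated by windowed
  normalized autocorrelation (pitch floor 60 Hz by default); the DSM entry
  for a category pair is the absolute pitch difference in Hz.
* **hmaxC1** — the complex-cell (C1) layer of a hierarchical model of early
  vision: Gabor simple cells (4 orientations x 16 scales) followed by local
  max pooling over space and adjacent scales; the DSM entry is
  1 - Pearson correlation of the concatenated C1 vectors.
* **behavioral** — pairwise similarity ratings (1-7) inverted to
  dissimilarities (7 - rating) and averaged over the stimulus pairs spanning
  each category pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .design import DSM, StudyDesign

# ---------------------------------------------------------------------------
# pitch estimation (autocorrelation method)
# ---------------------------------------------------------------------------

#: result marker for aperiodic signals — distinct from an error
UNVOICED = None

DEFAULT_VOICING_THRESHOLD = 0.45


@dataclass
class PitchTrack:
    """Per-window pitch candidates of one signal."""

    window_pitches: np.ndarray    # Hz, NaN where unvoiced
    mean_pitch: float | None      # None if every window is unvoiced


def _window_pitch(frame: np.ndarray, sample_rate: float, lag_min: int,
                  lag_max: int, threshold: float) -> float:
    """Strongest periodic lag of one frame via normalized autocorrelation.

    Candidate lags are local maxima of the normalized autocorrelation in
    [lag_min, lag_max]; among candidates within 5% of the global maximum
    the shortest lag wins (suppresses octave-down errors for harmonic-rich
    signals), refined by parabolic interpolation. Returns NaN (unvoiced)
    when no candidate clears ``threshold``.
    """
    x = frame - frame.mean()
    r0 = float(x @ x)
    if r0 <= 0:
        return np.nan
    full = spsig.correlate(x, x, mode="full")
    ac = full[x.size - 1:] / r0                    # normalized, ac[0] == 1
    # unbiased estimate: divide out the rectangular-window taper, otherwise
    # the (1 - lag/N) envelope biases peak lags short (pitch estimates high)
    n = x.size
    lags = np.arange(ac.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = ac * n / np.maximum(n - lags, 1)
    hi = min(lag_max, x.size - 2)
    if hi <= lag_min:
        return np.nan
    seg = ac[lag_min:hi + 1]
    interior = np.flatnonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
    if interior.size == 0:
        return np.nan
    vals = seg[interior]
    best = vals.max()
    if best < threshold:
        return np.nan
    keep = interior[vals >= 0.95 * best]
    lag = int(lag_min + keep.min())
    # parabolic refinement around the integer lag
    if 1 <= lag < ac.size - 1:
        a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = a - 2 * b + c
        if denom < 0:
            lag = lag + 0.5 * (a - c) / denom
    return sample_rate / lag


def estimate_pitch(samples: np.ndarray, sample_rate: float,
                   pitch_floor: float = 60.0, pitch_ceiling: float = 2000.0,
                   voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
                   return_track: bool = False):
    """Mean pitch (Hz) of a signal by windowed normalized autocorrelation.

    The analysis window is two periods of the pitch floor (the floor sets
    the window size), hopped by half a window; each window contributes the
    frequency of its strongest periodic lag, and the voiced-window mean is
    returned. An aperiodic signal (no window reaching the voicing
    threshold) returns ``None`` ("unvoiced"), distinct from an error.
    """
    x = np.asarray(samples, dtype=float)
    if pitch_floor <= 0 or pitch_ceiling <= pitch_floor:
        raise ValueError("need 0 < pitch_floor < pitch_ceiling")
    win = int(round(2.0 * sample_rate / pitch_floor))
    if x.size < win:
        raise ValueError(
            f"signal of {x.size} samples is shorter than two periods of the "
            f"pitch floor ({win} samples)")
    lag_min = max(2, int(np.floor(sample_rate / pitch_ceiling)))
    lag_max = int(np.ceil(sample_rate / pitch_floor))
    hop = max(1, win // 2)
    pitches = []
    for start in range(0, x.size - win + 1, hop):
        pitches.append(_window_pitch(x[start:start + win], sample_rate,
                                     lag_min, lag_max, voicing_threshold))
    pitches = np.array(pitches)
    voiced = pitches[np.isfinite(pitches)]
    mean = float(voiced.mean()) if voiced.size else None
    if return_track:
        return PitchTrack(pitches, mean)
    return mean


def pitch_dsm(category_pitches: dict, design: StudyDesign | None = None) -> DSM:
    """DSM of absolute pitch differences between category mean pitches."""
    design = design or StudyDesign()
    missing = [c for c in design.category_names if c not in category_pitches]
    if missing:
        raise ValueError(f"missing pitch for categories: {missing}")
    p = np.array([float(category_pitches[c]) for c in design.category_names])
    m = np.abs(p[:, None] - p[None, :])
    return DSM(m, design.category_names, kind="pitch",
               meta={"category_pitches": {c: float(category_pitches[c])
                                          for c in design.category_names}})


# ---------------------------------------------------------------------------
# HMAX C1 features
# ---------------------------------------------------------------------------

DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


@dataclass
class C1Config:
    """Canonical Gabor filter-bank / pooling parameterization.

    Filter sizes run 7..37 px in steps of 2 (16 scales); sigma and
    wavelength grow with size; C1 pools spatially over scale-dependent
    neighborhoods (8..22 px, 50% overlap) and over adjacent scale pairs,
    giving 8 scale bands per orientation. ``n_scales=8`` is a reduced mode
    (sizes 7..21, 4 bands) for fast tests.
    """

    n_orientations: int = 4
    n_scales: int = 16
    gamma: float = 0.3

    @property
    def filter_sizes(self) -> np.ndarray:
        return 7 + 2 * np.arange(self.n_scales)

    @property
    def orientations(self) -> np.ndarray:
        return np.arange(self.n_orientations) * 180.0 / self.n_orientations

    @property
    def n_bands(self) -> int:
        return self.n_scales // 2

    def pool_size(self, band: int) -> int:
        return 8 + 2 * band


def _gabor(size: int, theta_deg: float, gamma: float) -> np.ndarray:
    """Zero-mean, unit-norm Gabor filter of one size and orientation."""
    sigma = 0.0036 * size ** 2 + 0.35 * size + 0.18
    lam = sigma / 0.8
    theta = np.deg2rad(theta_deg)
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    g = np.exp(-(xr ** 2 + (gamma * yr) ** 2) / (2 * sigma ** 2)) \
        * np.cos(2 * np.pi * xr / lam)
    circle = (x ** 2 + y ** 2) <= half ** 2
    g = g * circle
    g -= g[circle].mean() * circle        # zero mean inside the support
    n = np.linalg.norm(g)
    return g / n if n > 0 else g


def _block_max(a: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Max over sliding square windows with the given stride."""
    from scipy.ndimage import maximum_filter

    m = maximum_filter(a, size=size, mode="constant", cval=-np.inf)
    off = size // 2
    rows = np.arange(off, a.shape[0], stride)
    cols = np.arange(off, a.shape[1], stride)
    rows = rows[rows < a.shape[0]]
    cols = cols[cols < a.shape[1]]
    return m[np.ix_(rows, cols)]


def hmax_c1(image: np.ndarray, config: C1Config | None = None) -> np.ndarray:
    """Concatenated C1 unit responses of a grayscale image.

    S1: magnitude of the correlation with zero-mean unit-norm Gabors at each
    orientation and scale. C1: elementwise max over adjacent scale pairs,
    then max pooling over scale-dependent spatial neighborhoods with 50%
    overlap, within orientation. Layout: (band, orientation, grid position),
    all entries >= 0. Deterministic.
    """
    config = config or C1Config()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    biggest = int(config.filter_sizes[-1])
    if min(img.shape) < biggest:
        raise ValueError(
            f"image {img.shape} is smaller than the largest S1 filter "
            f"({biggest} px, scale {config.n_scales})")
    s1 = {}
    for si, size in enumerate(config.filter_sizes):
        half = int(size) // 2
        for oi, theta in enumerate(config.orientations):
            g = _gabor(int(size), float(theta), config.gamma)
            resp = spsig.fftconvolve(img, g[::-1, ::-1], mode="same")
            resp = np.abs(resp)
            # discard partially supported responses at the border so a
            # constant image maps to exactly zero S1 everywhere
            if half:
                resp[:half, :] = 0.0
                resp[-half:, :] = 0.0
                resp[:, :half] = 0.0
                resp[:, -half:] = 0.0
            s1[(si, oi)] = resp
    parts = []
    for band in range(config.n_bands):
        ps = config.pool_size(band)
        stride = max(1, ps // 2)
        for oi in range(config.n_orientations):
            both = np.maximum(s1[(2 * band, oi)], s1[(2 * band + 1, oi)])
            parts.append(_block_max(both, ps, stride).ravel())
    return np.concatenate(parts)


def feature_dsm(category_vectors: dict, design: StudyDesign | None = None,
                kind: str = "hmaxC1") -> DSM:
    """DSM of 1 - Pearson correlation between category feature vectors.

    Category vectors are typically the mean C1 vector over that category's
    images. A zero-variance vector makes the correlation distance undefined
    and raises a degenerate-input error.
    """
    design = design or StudyDesign()
    missing = [c for c in design.category_names if c not in category_vectors]
    if missing:
        raise ValueError(f"missing feature vector for categories: {missing}")
    vecs = [np.asarray(category_vectors[c], dtype=float)
            for c in design.category_names]
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise ValueError("feature vectors must all have the same length")
    X = np.stack(vecs)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [design.category_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance (degenerate) feature vectors: {bad}")
    c = np.corrcoef(X)
    m = 1.0 - c
    np.fill_diagonal(m, 0.0)
    m = 0.5 * (m + m.T)
    return DSM(m, design.category_names, kind=kind,
               meta={"n_features": int(X.shape[1])})


# ---------------------------------------------------------------------------
# behavioral DSMs
# ---------------------------------------------------------------------------

def behavioral_dsm(ratings: pd.DataFrame, design: StudyDesign | None = None
                   ) -> tuple[dict, DSM]:
    """Per-rater and group-mean category DSMs from pairwise ratings.

    Each stimulus pair's dissimilarity is ``7 - rating``; the category-level
    entry is the mean over all stimulus pairs spanning that category pair
    (within-category pairs only inform the excluded diagonal). The group
    DSM is the mean of the per-rater DSMs. Raters with missing pairs raise
    an error listing them.
    """
    design = design or StudyDesign()
    cats = design.stimulus_categories
    n_cat = design.n_categories
    n_stim = design.n_stimuli
    required = {(i, j) for i in range(n_stim) for j in range(i + 1, n_stim)}
    per_rater: dict[int, DSM] = {}
    for rater, grp in ratings.groupby("rater"):
        pairs = {(min(int(a), int(b)), max(int(a), int(b)))
                 for a, b in zip(grp["stim_i"], grp["stim_j"])}
        missing = sorted(required - pairs)
        if missing:
            raise ValueError(
                f"rater {rater} is missing {len(missing)} pair(s), e.g. "
                f"{missing[:5]}")
        sums = np.zeros((n_cat, n_cat))
        counts = np.zeros((n_cat, n_cat))
        for a, b, r in zip(grp["stim_i"], grp["stim_j"], grp["rating"]):
            ca, cb = cats[int(a)], cats[int(b)]
            if ca == cb:
                continue
            d = 7.0 - float(r)
            sums[ca, cb] += d
            sums[cb, ca] += d
            counts[ca, cb] += 1
            counts[cb, ca] += 1
        with np.errstate(invalid="ignore"):
            m = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        np.fill_diagonal(m, 0.0)
        per_rater[int(rater)] = DSM(m, design.category_names, kind="behavioral",
                                    meta={"rater": int(rater)})
    if not per_rater:
        raise ValueError("no raters in the rating table")
    group = np.mean([d.matrix for d in per_rater.values()], axis=0)
    group_dsm = DSM(group, design.category_names, kind="behavioral",
                    meta={"n_raters": len(per_rater)})
    return per_rater, group_dsm
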