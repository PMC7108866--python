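"""Synthetic multi-group pattern datasets with planted, recoverable truth.

The generator emulates the data a cross-modal category fMRI study produces
after GLM estimation: per subject, one beta pattern per stimulus per run over
a 3-D voxel grid, with named ROI masks. Ground truth is planted at two
levels so every downstream stage has an oracle:

* a **representational geometry** — an 8x8 dissimilarity matrix realized as
  category prototype patterns whose pairwise distances increase strictly
  with the planted dissimilarities;
* a **topography** — spatially contiguous clusters of voxels selective for
  each superordinate category, realized as an additive selectivity bump on
  the prototypes. The stored ``true_label_maps`` are the winner-take-all
  labels of the *noiseless* prototypes, so label-map recovery is exact in the
  zero-noise limit by construction.

Single-trial patterns are ``effect_size * prototype + N(0, noise_sd)`` i.i.d.
per (stimulus, run, voxel); every generator is a pure function of its
parameters and seed, with per-subject streams derived from the master seed
by a fixed entropy scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import StudyDesign

DEFAULT_GRID = (10, 10, 10)


# ---------------------------------------------------------------------------
# planted geometry
# ---------------------------------------------------------------------------

def default_true_dsm(design: StudyDesign | None = None) -> np.ndarray:
    """Requested 8x8 category geometry with a 4-superordinate block structure.

    Built from an explicit 7-D point configuration (hence embeddable by
    construction): superordinate centers sit in a common 3-D subspace at
    mutual distances ~0.95-1.27, and each superordinate's two categories are
    split along a dimension of their own, so within-superordinate distances
    (0.55-0.75) are exact and all 28 pairwise distances are distinct.
    """
    design = design or StudyDesign()
    if design.n_categories != 8 or design.n_superordinate != 4:
        raise ValueError("default geometry is defined for the 8/4 design")
    centers = np.array(
        [
            [0.00, 0.00, 0.00],   # human
            [0.95, 0.00, 0.00],   # animal
            [0.55, 1.00, 0.00],   # manipulable
            [0.35, 0.50, 1.00],   # big objects / places
        ]
    )
    within = np.array([0.55, 0.62, 0.68, 0.75])   # per-superordinate splits
    # small deterministic per-category displacements in the center space so
    # the four category pairs spanning a superordinate pair get distinct
    # distances (no accidental ties in the planted ranks)
    jitter = np.array(
        [
            [0.04, 0.01, -0.02], [-0.03, 0.04, 0.02],
            [0.02, -0.04, 0.03], [-0.04, -0.01, -0.03],
            [0.01, 0.03, 0.04], [0.03, -0.02, -0.04],
            [-0.02, 0.02, 0.01], [-0.01, -0.03, 0.02],
        ]
    )
    pts = np.zeros((8, 7))
    for c in range(8):
        s = design.category_to_superordinate[c]
        sign = 1.0 if c % 2 == 0 else -1.0
        pts[c, :3] = centers[s] + jitter[c]
        pts[c, 3 + s] = sign * within[s] / 2.0
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(dsm: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a dissimilarity matrix.

    Raises if the matrix is not (numerically) Euclidean-embeddable, i.e. the
    doubly centered Gram matrix has a meaningfully negative eigenvalue.
    """
    d = np.asarray(dsm, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - 1.0 / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    scale = max(w.max(), 1.0)
    if w.min() < -1e-6 * scale:
        raise ValueError(
            "dissimilarity matrix is not embeddable as Euclidean distances "
            f"(most negative Gram eigenvalue {w.min():.3g}); supply a "
            "Euclidean-realizable geometry"
        )
    keep = w > tol * scale
    return v[:, keep] * np.sqrt(w[keep])


# ---------------------------------------------------------------------------
# planted truth containers
# ---------------------------------------------------------------------------

@dataclass
class ROITruth:
    """Ground truth for one ROI: voxel set, geometry and selectivity layout.

    ``requested_dsm`` is the geometry the prototypes were drawn from;
    ``dsm`` is the *realized* pairwise prototype distance matrix (requested
    geometry plus the topographic selectivity component), which is the
    quantity recovery analyses are checked against.
    """

    name: str
    voxels: np.ndarray                 # flat indices into the grid
    requested_dsm: np.ndarray          # blueprint geometry (n_cat x n_cat)
    cluster_super: np.ndarray          # per-voxel superordinate id
    bump: np.ndarray                   # per-superordinate bump amplitude
    amplitude: float                   # overall signal scale of this ROI
    geometry_scale: float = 1.0
    dsm: np.ndarray = None             # realized prototype distances
    prototypes: np.ndarray = None      # (n_cat, n_vox), filled at construction
    basis: np.ndarray = None           # (n_vox, d) orthonormal geometry basis

    @property
    def n_voxels(self) -> int:
        return self.voxels.size


@dataclass
class GroupSpec:
    """One subject group: size, per-ROI signal multipliers, optional relabeling.

    ``category_permutation`` relabels the planted prototypes for this group
    (row permutation), giving the group a distinct representational geometry
    and topography while preserving SNR — used to plant between-group
    differences.
    """

    name: str
    n_subjects: int
    roi_effects: dict = field(default_factory=dict)
    category_permutation: tuple | None = None

    def effect_for(self, roi_name: str) -> float:
        if roi_name in self.roi_effects:
            return float(self.roi_effects[roi_name])
        if roi_name.startswith("parcel") and "parcels" in self.roi_effects:
            return float(self.roi_effects["parcels"])
        return 1.0


@dataclass
class PlantedTruth:
    """Everything the generator planted, kept for oracle comparisons."""

    design: StudyDesign
    grid_shape: tuple
    rois: dict
    true_dsm: np.ndarray
    true_label_maps: dict              # roi -> {4: labels, 8: labels}
    effect_size: float
    noise_sd: float
    seed: int

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class PatternDataset:
    """Per-subject beta patterns indexed (stimulus, run, voxel-in-grid)."""

    betas: np.ndarray
    stimulus_labels: np.ndarray        # category id per stimulus
    grid_shape: tuple
    roi_masks: dict                    # name -> flat voxel indices
    subject_id: str
    group_id: str
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")
        n_grid = int(np.prod(self.grid_shape))
        if self.betas.shape[2] != n_grid:
            raise ValueError("betas voxel axis must match the grid size")
        if self.betas.shape[0] != len(self.stimulus_labels):
            raise ValueError("every stimulus needs a label")
        for name, vox in self.roi_masks.items():
            vox = np.asarray(vox)
            if vox.size and (vox.min() < 0 or vox.max() >= n_grid):
                raise ValueError(f"mask {name!r} has voxel indices beyond the grid")

    @property
    def n_stimuli(self) -> int:
        return self.betas.shape[0]

    @property
    def n_runs(self) -> int:
        return self.betas.shape[1]

    def roi_betas(self, roi: str) -> np.ndarray:
        """Betas restricted to one ROI: (n_stim, n_runs, n_roi_voxels)."""
        if roi not in self.roi_masks:
            raise KeyError(f"unknown ROI {roi!r}")
        return self.betas[:, :, self.roi_masks[roi]]

    def condition_mean_betas(self, roi: str, granularity: int = 4) -> np.ndarray:
        """Run- and stimulus-averaged beta per condition: (n_cond, n_vox)."""
        x = self.roi_betas(roi).mean(axis=1)  # (n_stim, n_vox)
        if granularity == self.design.n_categories:
            cond = np.asarray(self.stimulus_labels)
            n_cond = self.design.n_categories
        elif granularity == self.design.n_superordinate:
            c2s = np.asarray(self.design.category_to_superordinate)
            cond = c2s[np.asarray(self.stimulus_labels)]
            n_cond = self.design.n_superordinate
        else:
            raise ValueError(f"granularity must be 4 or 8, got {granularity}")
        out = np.empty((n_cond, x.shape[1]))
        for c in range(n_cond):
            out[c] = x[cond == c].mean(axis=0)
        return out


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _block_indices(grid_shape, x, y, z) -> np.ndarray:
    """Flat indices of the box given by slice triples (C-order)."""
    ii, jj, kk = np.meshgrid(np.arange(*x), np.arange(*y), np.arange(*z), indexing="ij")
    return np.ravel_multi_index((ii.ravel(), jj.ravel(), kk.ravel()), grid_shape)


def _roi_prototypes(requested_dsm, cluster_super, cat_to_super, bump,
                    geometry_scale, amplitude, rng):
    """Category prototypes over an ROI's voxels.

    The classical-MDS geometry of ``requested_dsm`` is embedded along
    orthonormal voxel-space directions chosen orthogonal to the selectivity
    cluster indicator functions, then a per-superordinate selectivity bump
    is added on each superordinate's clusters. Because geometry and bump
    live in orthogonal subspaces, the realized pairwise distances decompose
    as ``sqrt(geometry_scale^2 d_ij^2 + bump term)``; the realized distance
    matrix (returned alongside) is stored as the planted truth.
    """
    n_vox = cluster_super.size
    y = geometry_scale * classical_mds(requested_dsm)
    d = y.shape[1]
    w = rng.standard_normal((d, n_vox))
    for c in np.unique(cluster_super):
        sel = cluster_super == c
        w[:, sel] -= w[:, sel].mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(w.T)           # (n_vox, d), columns orthonormal
    proto = y @ q.T
    c2s = np.asarray(cat_to_super)
    amps = np.asarray(bump, dtype=float)
    if amps.ndim == 0:
        amps = np.full(int(c2s.max()) + 1, float(amps))
    if np.any(amps):
        proto = proto + amps[c2s][:, None] * (c2s[:, None] == cluster_super[None, :])
        # guarantee a minimum superordinate winner margin at every cluster
        # voxel: where the geometry component erodes the bump below
        # MIN_WTA_MARGIN, raise that voxel's bump just enough. The realized
        # distance matrix and label maps are computed afterwards, so the
        # planted truth stays self-consistent.
        n_super = amps.size
        sp = np.stack([proto[c2s == s].mean(axis=0) for s in range(n_super)])
        own = sp[cluster_super, np.arange(proto.shape[1])]
        rival = np.where(np.arange(n_super)[:, None] == cluster_super[None, :],
                         -np.inf, sp).max(axis=0)
        deficit = np.maximum(0.0, MIN_WTA_MARGIN - (own - rival))
        proto = proto + deficit[None, :] * (c2s[:, None] == cluster_super[None, :])
    proto = amplitude * proto
    realized = np.linalg.norm(proto[:, None, :] - proto[None, :, :], axis=-1)
    np.fill_diagonal(realized, 0.0)
    return proto, q, realized


#: per-superordinate selectivity bump amplitudes: deliberately spread so the
#: bump component itself carries rankable between-superordinate structure
DEFAULT_BUMP = (0.25, 0.35, 0.45, 0.55)

#: minimum noiseless superordinate winner-take-all margin (in prototype
#: units, before the effect-size scale) enforced at every cluster voxel
MIN_WTA_MARGIN = 0.15


def _clustered_layout(grid_shape, x0: int):
    """8 selectivity clusters of 2x2x1 voxels in a 4x4x2 region at x offset.

    Two non-adjacent clusters per superordinate (different xy positions in
    the two z layers), so every cluster is a separate connected component
    under 6-connectivity and the constrained permutation has 8 relabelable
    units per map.
    """
    layer0 = {(0, 0): 0, (0, 2): 1, (2, 0): 2, (2, 2): 3}
    layer1 = {(0, 0): 2, (0, 2): 3, (2, 0): 0, (2, 2): 1}
    vox, clusters = [], []
    for z, layer in ((0, layer0), (1, layer1)):
        for (bx, by), s in layer.items():
            idx = _block_indices(grid_shape, (x0 + bx, x0 + bx + 2),
                                 (by, by + 2), (z, z + 1))
            vox.append(idx)
            clusters.append(np.full(idx.size, s))
    return np.concatenate(vox), np.concatenate(clusters)


def make_planted_truth(
    design: StudyDesign | None = None,
    grid_shape=DEFAULT_GRID,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    bump=DEFAULT_BUMP,
    geometry_scale: float = 0.8,
    true_dsm: np.ndarray | None = None,
    n_parcels: int = 10,
    parcel_size: int = 25,
    parcel_amplitudes=None,
    evc_amplitude: float = 1.0,
    seed: int = 0,
) -> PlantedTruth:
    """Build the default planted layout on a 3-D grid.

    Two structured ROIs sit in the front slab of the grid: ``VOTC`` (the
    target region: 8 selectivity clusters of 4 voxels, two per superordinate
    category with per-superordinate bump amplitudes) and ``EVC`` (a control
    region with a category-relabeled geometry standing in for low-level
    structure). The remaining voxels host ``n_parcels`` whole-brain parcels
    for the connectivity stage; by default parcels alternate between
    carrying the planted geometry (at amplitude 0.8, no topographic bump)
    and pure noise.

    ``true_dsm`` (and each ``ROITruth.dsm``) stores the *realized* noiseless
    prototype distance matrix, so recovery oracles are self-consistent.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))
    requested = (default_true_dsm(design) if true_dsm is None
                 else np.asarray(true_dsm, float))
    c2s = np.asarray(design.category_to_superordinate)
    n_grid = int(np.prod(grid_shape))

    rois: dict[str, ROITruth] = {}

    votc_vox, votc_clusters = _clustered_layout(grid_shape, x0=0)
    rois["VOTC"] = ROITruth("VOTC", votc_vox, requested, votc_clusters,
                            np.asarray(bump, float), 1.0, geometry_scale)

    evc_vox, evc_clusters = _clustered_layout(grid_shape, x0=5)
    evc_perm = np.array([4, 6, 1, 7, 2, 0, 5, 3])      # fixed relabeling
    evc_requested = requested[np.ix_(evc_perm, evc_perm)]
    rois["EVC"] = ROITruth("EVC", evc_vox, evc_requested, evc_clusters,
                           np.asarray(bump, float), evc_amplitude,
                           geometry_scale)

    used = set(votc_vox) | set(evc_vox)
    free = np.array([v for v in range(n_grid) if v not in used])
    if n_parcels * parcel_size > free.size:
        raise ValueError(
            f"{n_parcels} parcels of {parcel_size} voxels do not fit in the "
            f"{free.size} voxels left on the grid"
        )
    if parcel_amplitudes is None:
        parcel_amplitudes = [0.8 if i % 2 == 0 else 0.0 for i in range(n_parcels)]
    elif len(parcel_amplitudes) != n_parcels:
        raise ValueError(f"need one amplitude per parcel: got "
                         f"{len(parcel_amplitudes)} for {n_parcels} parcels")
    for i in range(n_parcels):
        vox = free[i * parcel_size:(i + 1) * parcel_size]
        # parcels carry geometry without a topographic bump; a trivial
        # single-cluster layout keeps the embedding helper applicable
        rois[f"parcel_{i:02d}"] = ROITruth(
            f"parcel_{i:02d}", vox, requested, np.zeros(vox.size, dtype=int),
            np.zeros(design.n_superordinate), float(parcel_amplitudes[i]),
            geometry_scale,
        )

    label_maps: dict[str, dict[int, np.ndarray]] = {}
    for name, roi in rois.items():
        roi.prototypes, roi.basis, roi.dsm = _roi_prototypes(
            roi.requested_dsm, roi.cluster_super, c2s, roi.bump,
            roi.geometry_scale, roi.amplitude, rng
        )
        labels8 = np.argmax(roi.prototypes, axis=0)
        super_proto = np.stack(
            [roi.prototypes[c2s == s].mean(axis=0)
             for s in range(design.n_superordinate)]
        )
        labels4 = np.argmax(super_proto, axis=0)
        label_maps[name] = {design.n_categories: labels8,
                            design.n_superordinate: labels4}

    return PlantedTruth(
        design=design,
        grid_shape=tuple(grid_shape),
        rois=rois,
        true_dsm=rois["VOTC"].dsm,
        true_label_maps=label_maps,
        effect_size=float(effect_size),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def default_groups(design: StudyDesign | None = None) -> list[GroupSpec]:
    """The three study groups with SNR multipliers mirroring the reference
    study's qualitative ordering (visual > blind-auditory > sighted-auditory,
    and no auditory signal in the sighted control's EVC)."""
    design = design or StudyDesign()
    sizes = design.group_sizes
    return [
        GroupSpec("SCv", sizes.get("SCv", 16),
                  {"VOTC": 1.0, "EVC": 0.8, "parcels": 1.0}),
        GroupSpec("EBa", sizes.get("EBa", 16),
                  {"VOTC": 0.6, "EVC": 0.4, "parcels": 0.6}),
        GroupSpec("SCa", sizes.get("SCa", 17),
                  {"VOTC": 0.35, "EVC": 0.0, "parcels": 0.35}),
    ]


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _subject_rng(master_seed: int, group_name: str, subject_idx: int):
    """Per-subject stream derived from the master seed by a fixed scheme."""
    gkey = int.from_bytes(group_name.encode()[:4].ljust(4, b"\0"), "little")
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, gkey, int(subject_idx)])
    )


def generate_subject(design: StudyDesign, truth: PlantedTruth, group: GroupSpec,
                     subject_idx: int, master_seed: int | None = None) -> PatternDataset:
    seed = truth.seed if master_seed is None else master_seed
    rng = _subject_rng(seed, group.name, subject_idx)
    n_grid = int(np.prod(truth.grid_shape))
    betas = rng.normal(0.0, truth.noise_sd,
                       size=(design.n_stimuli, design.n_runs, n_grid))
    stim_cat = design.stimulus_categories
    perm = (np.asarray(group.category_permutation)
            if group.category_permutation is not None else None)
    for name, roi in truth.rois.items():
        mult = group.effect_for(name) * truth.effect_size
        if mult == 0.0:
            continue
        proto = roi.prototypes if perm is None else roi.prototypes[perm]
        betas[:, :, roi.voxels] += mult * proto[stim_cat][:, None, :]
    return PatternDataset(
        betas=betas,
        stimulus_labels=stim_cat.copy(),
        grid_shape=truth.grid_shape,
        roi_masks={name: roi.voxels.copy() for name, roi in truth.rois.items()},
        subject_id=f"{group.name}_{subject_idx:02d}",
        group_id=group.name,
        design=design,
    )


def generate_group_dataset(design: StudyDesign, truth: PlantedTruth,
                           group: GroupSpec, master_seed: int | None = None
                           ) -> list[PatternDataset]:
    """All subjects of one group; deterministic given (design, truth, seed)."""
    return [generate_subject(design, truth, group, i, master_seed)
            for i in range(group.n_subjects)]


def generate_study(design: StudyDesign, truth: PlantedTruth,
                   groups: list[GroupSpec] | None = None,
                   master_seed: int | None = None) -> dict:
    """group name -> list of PatternDataset for the whole study."""
    groups = groups if groups is not None else default_groups(design)
    return {g.name: generate_group_dataset(design, truth, g, master_seed)
            for g in groups}


# ---------------------------------------------------------------------------
# behavioral ratings
# ---------------------------------------------------------------------------

def generate_behavioral_ratings(true_dsm: np.ndarray, n_raters: int,
                                noise_sd: float = 0.7, seed: int | None = None,
                                design: StudyDesign | None = None,
                                integer: bool = True) -> pd.DataFrame:
    """Pairwise similarity ratings (1-7) for all unordered stimulus pairs.

    Each rater judges every pair once; the rating is an affine map of the
    planted similarity plus Gaussian noise, rounded and clipped to the 1-7
    scale (``integer=False`` skips rounding, giving a continuous rating whose
    ordering matches the planted geometry exactly at zero noise).
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    design = design or StudyDesign()
    dsm = np.asarray(true_dsm, dtype=float)
    rng = np.random.default_rng(seed)
    cats = design.stimulus_categories
    dmax = dsm.max() if dsm.max() > 0 else 1.0
    rows = []
    n = design.n_stimuli
    for rater in range(n_raters):
        for i in range(n):
            for j in range(i + 1, n):
                d = dsm[cats[i], cats[j]]
                sim = 1.0 + 6.0 * (1.0 - d / dmax)
                val = sim + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if integer:
                    val = int(np.clip(np.rint(val), 1, 7))
                else:
                    val = float(np.clip(val, 1.0, 7.0))
                rows.append((rater, i, j, val))
    return pd.DataFrame(rows, columns=["rater", "stim_i", "stim_j", "rating"])


# ---------------------------------------------------------------------------
# audio / image stimulus synthesis
# ---------------------------------------------------------------------------

@dataclass
class Tone:
    samples: np.ndarray
    sample_rate: int
    f0: float
    waveform: str
    target_rms: float


def generate_tone(f0: float, duration: float = 2.0, sample_rate: int = 44100,
                  waveform: str = "sine", target_rms: float = 0.1,
                  n_harmonics: int = 8) -> Tone:
    """RMS-normalized mono tone with known fundamental frequency.

    ``sawtooth`` is synthesized band-limited (harmonics 1/h up to 0.45 x
    sample rate); ``harmonic-complex`` stacks ``n_harmonics`` equal-amplitude
    harmonics. The synthesis f0 is kept as metadata for oracle tests.
    """
    if not 0 < f0 < sample_rate / 2:
        raise ValueError(f"f0 must lie in (0, Nyquist={sample_rate / 2} Hz)")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if waveform == "sine":
        x = np.sin(2 * np.pi * f0 * t)
    elif waveform == "sawtooth":
        hmax = max(1, int(0.45 * sample_rate / f0))
        x = sum(np.sin(2 * np.pi * h * f0 * t) / h for h in range(1, hmax + 1))
    elif waveform == "harmonic-complex":
        hmax = max(1, min(n_harmonics, int(0.45 * sample_rate / f0)))
        x = sum(np.sin(2 * np.pi * h * f0 * t) for h in range(1, hmax + 1))
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    rms = np.sqrt(np.mean(x ** 2))
    x = x * (target_rms / rms)
    return Tone(x, sample_rate, float(f0), waveform, target_rms)


def generate_texture_image(orientation: float, spatial_freq: float,
                           size: int = 128, seed: int | None = None,
                           noise_amp: float = 0.1) -> np.ndarray:
    """Grayscale texture with a dominant orientation and spatial frequency.

    An oriented sinusoidal grating (``spatial_freq`` in cycles per image,
    ``orientation`` in degrees of the stripe direction) with seeded random
    phase, plus low-pass filtered noise; values in [0, 1].
    """
    if size < 7:
        raise ValueError("image must be at least 7 px (smallest S1 filter)")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(orientation)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    # wave vector perpendicular to the stripe orientation
    u = xx * np.sin(theta) + yy * np.cos(theta)
    phase = rng.uniform(0, 2 * np.pi)
    img = 0.5 + 0.4 * np.sin(2 * np.pi * spatial_freq * u / size + phase)
    if noise_amp > 0:
        img = img + noise_amp * ndimage.gaussian_filter(
            rng.standard_normal((size, size)), sigma=1.5)
    return np.clip(img, 0.0, 1.0)


def write_wav(path, tone: Tone) -> None:
    """16-bit PCM mono WAV."""
    from scipy.io import wavfile

    x = np.clip(tone.samples, -1.0, 1.0)
    wavfile.write(path, tone.sample_rate, (x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return data, int(rate)
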