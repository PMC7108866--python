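"""Readers/writers, run configuration, and the end-to-end pipeline.

Datasets round-trip either as a single TSV long table (subject, stimulus,
run, voxel, beta) with a JSON sidecar carrying the design, grid and masks,
or as NIfTI volumes (one 4-D beta image plus integer mask volumes).
Analyses operate in 0-based voxel space; the NIfTI affine is carried
through on read/write but not used for analysis.

Every output embeds a provenance block (config hash, seed, package
version) so a result can be traced to the exact configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import DSM, StudyDesign, vectorize_dsm
from .synthetic import (PatternDataset, default_groups,
                        generate_behavioral_ratings, generate_study,
                        make_planted_truth)


# ---------------------------------------------------------------------------
# dataset TSV round trip
# ---------------------------------------------------------------------------

def write_dataset_tsv(dataset: PatternDataset, path) -> None:
    path = Path(path)
    n_stim, n_runs, n_vox = dataset.betas.shape
    stim, run, vox = np.meshgrid(np.arange(n_stim), np.arange(n_runs),
                                 np.arange(n_vox), indexing="ij")
    df = pd.DataFrame({
        "subject": dataset.subject_id,
        "stimulus": stim.ravel(),
        "run": run.ravel(),
        "voxel": vox.ravel(),
        "beta": dataset.betas.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "subject_id": dataset.subject_id,
        "group_id": dataset.group_id,
        "grid_shape": list(dataset.grid_shape),
        "stimulus_labels": np.asarray(dataset.stimulus_labels).tolist(),
        "roi_masks": {k: np.asarray(v).tolist()
                      for k, v in dataset.roi_masks.items()},
        "design": dataset.design.to_dict(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_dataset_tsv(path) -> PatternDataset:
    path = Path(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    design = StudyDesign.from_dict(side["design"])
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    n_stim = design.n_stimuli
    n_runs = design.n_runs
    n_vox = int(np.prod(side["grid_shape"]))
    expected = n_stim * n_runs * n_vox
    if len(df) != expected:
        present = {(s, r) for s, r in
                   df[["stimulus", "run"]].drop_duplicates().itertuples(index=False)}
        missing = [(s, r) for s in range(n_stim) for r in range(n_runs)
                   if (s, r) not in present]
        raise ValueError(
            f"dataset table has {len(df)} rows, expected {expected}; "
            f"missing (stimulus, run) records: {missing[:10]}")
    betas = np.empty((n_stim, n_runs, n_vox))
    betas[df["stimulus"].to_numpy(), df["run"].to_numpy(),
          df["voxel"].to_numpy()] = df["beta"].to_numpy()
    return PatternDataset(
        betas=betas,
        stimulus_labels=np.asarray(side["stimulus_labels"]),
        grid_shape=tuple(side["grid_shape"]),
        roi_masks={k: np.asarray(v) for k, v in side["roi_masks"].items()},
        subject_id=side["subject_id"],
        group_id=side["group_id"],
        design=design,
    )


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def write_dataset_nifti(dataset: PatternDataset, directory) -> None:
    """One 4-D beta volume (stim*run along the 4th axis) + mask volumes."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_stim, n_runs, _ = dataset.betas.shape
    vol4 = dataset.betas.reshape(n_stim * n_runs, *dataset.grid_shape)
    vol4 = np.moveaxis(vol4, 0, -1)
    nib.save(nib.Nifti1Image(vol4.astype(np.float64), np.eye(4)),
             directory / "betas.nii")
    for name, vox in dataset.roi_masks.items():
        m = np.zeros(int(np.prod(dataset.grid_shape)), dtype=np.int16)
        m[np.asarray(vox)] = 1
        nib.save(nib.Nifti1Image(m.reshape(dataset.grid_shape), np.eye(4)),
                 directory / f"mask_{name}.nii")
    sidecar = {
        "subject_id": dataset.subject_id,
        "group_id": dataset.group_id,
        "grid_shape": list(dataset.grid_shape),
        "stimulus_labels": np.asarray(dataset.stimulus_labels).tolist(),
        "roi_names": list(dataset.roi_masks),
        "design": dataset.design.to_dict(),
    }
    (directory / "dataset.json").write_text(json.dumps(sidecar))


def read_dataset_nifti(directory) -> PatternDataset:
    import nibabel as nib

    directory = Path(directory)
    side = json.loads((directory / "dataset.json").read_text())
    design = StudyDesign.from_dict(side["design"])
    grid = tuple(side["grid_shape"])
    vol4 = np.asarray(nib.load(directory / "betas.nii").dataobj)
    if vol4.shape[:3] != grid:
        raise ValueError(f"beta volume grid {vol4.shape[:3]} does not match "
                         f"sidecar grid {grid}")
    betas = np.moveaxis(vol4, -1, 0).reshape(
        design.n_stimuli, design.n_runs, int(np.prod(grid)))
    masks = {}
    for name in side["roi_names"]:
        m = np.asarray(nib.load(directory / f"mask_{name}.nii").dataobj)
        masks[name] = np.flatnonzero(m.ravel())
    return PatternDataset(betas=betas,
                          stimulus_labels=np.asarray(side["stimulus_labels"]),
                          grid_shape=grid, roi_masks=masks,
                          subject_id=side["subject_id"],
                          group_id=side["group_id"], design=design)


def write_label_map(label_map, path, label_names=None) -> None:
    """Integer NIfTI volume (background -1) + JSON label dictionary."""
    import nibabel as nib

    path = Path(path)
    nib.save(nib.Nifti1Image(label_map.volume().astype(np.int16), np.eye(4)),
             path)
    side = {"mask": label_map.mask.tolist(),
            "granularity": label_map.granularity,
            "labels": {str(i): n for i, n in enumerate(label_names)}
            if label_names else None}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side))


# ---------------------------------------------------------------------------
# run configuration & provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "crossrep_out"
    n_perm: int = 500
    effect_size: float = 3.0
    noise_sd: float = 1.0
    group_sizes: dict = field(default_factory=lambda: {"SCv": 6, "EBa": 6, "SCa": 6})
    grid_shape: tuple = (10, 10, 10)
    granularity: int = 4
    svm_c: float = 1.0
    linkage: str = "single"
    n_parcels: int = 6
    parcel_size: int = 15
    connectivity_fisher: bool = True
    connectivity_standardize: bool = True
    n_raters: int = 8
    rating_noise_sd: float = 0.7
    include_connectivity: bool = True
    verbosity: int = 1

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def provenance(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed,
            "package_version": __version__}


def write_results_table(rows: list, path, config: RunConfig) -> None:
    """Standard results TSV with a provenance header comment."""
    path = Path(path)
    df = pd.DataFrame(rows, columns=["analysis", "contrast", "statistic",
                                     "p_raw", "p_fdr", "n_perm", "seed", "tail"])
    with open(path, "w") as fh:
        fh.write(f"# crossrep {__version__} config={config.config_hash()} "
                 f"seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """simulate -> selectivity -> decode -> rsa -> connectivity.

    Returns the summary dict and writes ``summary.json`` (sorted keys, so
    identical configs give byte-identical output), the results tables, and
    the group DSMs under ``config.out_dir``.
    """
    from . import connectivity as conn
    from . import decoding, models, rsa, selectivity
    from .stats import fdr_bh

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = StudyDesign(group_sizes=dict(config.group_sizes))
    truth = make_planted_truth(design, grid_shape=config.grid_shape,
                               effect_size=config.effect_size,
                               noise_sd=config.noise_sd,
                               n_parcels=config.n_parcels,
                               parcel_size=config.parcel_size,
                               seed=config.seed)
    groups = default_groups(design)
    study = generate_study(design, truth, groups, master_seed=config.seed)
    names = [g.name for g in groups]
    summary: dict = {"provenance": provenance(config)}
    rows = []

    # --- selectivity ------------------------------------------------------
    gmaps = {g: selectivity.group_map(study[g], "VOTC", config.granularity)
             for g in names}
    smaps = {g: [selectivity.subject_map(d, "VOTC", config.granularity)
                 for d in study[g]] for g in names}
    sel = {}
    for a, b in [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]:
        res = selectivity.map_group_correlation(
            (smaps[a], gmaps[a]), (smaps[b], gmaps[b]),
            n_perm=config.n_perm, seed=config.seed)
        sel[f"{a}-{b}"] = {"r": res.observed, "p": res.p}
        rows.append(("selectivity_map_corr", f"{a}-{b}", res.observed,
                     res.p, None, config.n_perm, config.seed, "one"))
    summary["selectivity_map_correlation"] = sel
    summary["selective_voxel_counts"] = {
        g: selectivity.selective_voxel_counts(gmaps[g]).tolist() for g in names}

    # --- decoding ---------------------------------------------------------
    clf = decoding.ClassifierConfig(C=config.svm_c)
    dsms = {g: [decoding.neural_dsm(d, "VOTC", clf) for d in study[g]]
            for g in names}
    chance = {}
    pvals = []
    for g in names:
        t = decoding.group_chance_test(dsms[g])
        chance[g] = {"mean_accuracy": float(t.subject_means.mean()),
                     "t": t.ttest.t, "p": t.ttest.p}
        pvals.append(t.ttest.p)
    adj = fdr_bh([p for p in pvals if np.isfinite(p)]) if pvals else []
    for g, p_adj in zip(names, adj):
        chance[g]["p_fdr"] = float(p_adj)
        rows.append(("decoding_vs_chance", g, chance[g]["mean_accuracy"],
                     chance[g]["p"], float(p_adj), None, config.seed, "two"))
    summary["decoding"] = chance

    # --- rsa --------------------------------------------------------------
    rsa_sum = {}
    for a, b in [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]:
        res = rsa.group_dsm_correlation(dsms[a], dsms[b],
                                        n_categories=design.n_categories,
                                        n_perm=config.n_perm, seed=config.seed)
        rsa_sum[f"{a}-{b}"] = {"r": res.observed, "p": res.p}
        rows.append(("rsa_group_dsm_corr", f"{a}-{b}", res.observed, res.p,
                     None, config.n_perm, config.seed, "one"))
    summary["rsa_group_correlation"] = rsa_sum

    all_dsms = [d for g in names for d in dsms[g]]
    labels = np.concatenate([[i] * len(dsms[g]) for i, g in enumerate(names)])
    isc = rsa.intersubject_matrix(all_dsms, labels, group_names=names,
                                  n_perm=config.n_perm, seed=config.seed)
    summary["intersubject"] = {
        "within": {k: v for k, v in isc.within.items()},
        "between": {f"{a}-{b}": v for (a, b), v in isc.between.items()},
    }

    mean_dsm = DSM(np.mean([d.matrix for d in dsms[names[0]]], axis=0),
                   design.category_names, kind="neural",
                   meta={"group": names[0], "roi": "VOTC"})
    mean_dsm.to_tsv(out / f"dsm_VOTC_{names[0]}.tsv")
    summary["clusters_k2"] = rsa.hierarchical_clusters(
        mean_dsm, 2, linkage=config.linkage).tolist()

    # recovery of the planted geometry (oracle available in synthetic runs)
    from .stats import spearman as _sp
    rec = {}
    for g in names:
        mean_vec = np.mean([vectorize_dsm(d.matrix) for d in dsms[g]], axis=0)
        rec[g] = float(_sp(mean_vec, vectorize_dsm(truth.true_dsm)))
    summary["true_dsm_recovery_spearman"] = rec

    # --- models -----------------------------------------------------------
    ratings = generate_behavioral_ratings(truth.true_dsm, config.n_raters,
                                          config.rating_noise_sd,
                                          seed=config.seed, design=design)
    _, behav = models.behavioral_dsm(ratings, design)
    rng = np.random.default_rng(config.seed + 7)
    pitches = {c: float(f) for c, f in zip(
        design.category_names, rng.uniform(120.0, 900.0, design.n_categories))}
    pitch = models.pitch_dsm(pitches, design)
    partial = {}
    for g in names:
        mean_vec = np.mean([vectorize_dsm(d.matrix) for d in dsms[g]], axis=0)
        res = rsa.partial_model_correlation(
            mean_vec, vectorize_dsm(behav.matrix), vectorize_dsm(pitch.matrix),
            n_categories=design.n_categories, n_perm=config.n_perm,
            seed=config.seed)
        partial[g] = {"r": res.observed, "p": res.p}
        rows.append(("rsa_partial_behavioral", g, res.observed, res.p, None,
                     config.n_perm, config.seed, "one"))
    summary["partial_behavioral_correlation"] = partial

    # --- connectivity -----------------------------------------------------
    if config.include_connectivity and config.n_parcels >= 4:
        parcel_names = sorted(n for n in truth.rois if n.startswith("parcel"))
        seeds, targets = parcel_names[:2], parcel_names[2:]
        profs = {g: [conn.subject_profile(d, seeds, targets, clf,
                                          fisher=config.connectivity_fisher,
                                          standardize=config.connectivity_standardize)
                     for d in study[g]] for g in names}
        csum = {}
        for a, b in [(names[i], names[j]) for i in range(len(names))
                     for j in range(i + 1, len(names))]:
            res = conn.profile_group_correlation(profs[a], profs[b],
                                                 n_perm=config.n_perm,
                                                 seed=config.seed)
            csum[f"{a}-{b}"] = {"r": res.observed, "p": res.p}
            rows.append(("connectivity_profile_corr", f"{a}-{b}", res.observed,
                         res.p, None, config.n_perm, config.seed, "one"))
        summary["connectivity"] = csum

    write_results_table(rows, out / "results.tsv", config)
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, default=float))
    return summary
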