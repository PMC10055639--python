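"""Synthetic two-sex, multi-scan-per-rat BOLD cohorts with known ground truth.

The generator plants the statistical structure the downstream analysis
assumes, at two levels of realism:

* a fast *latent* path (:func:`simulate_edge_z`,
  :func:`simulate_cohort_matrices`) that draws per-scan Fisher-z
  connectivity directly from the population model — sex-specific mean,
  rat-level random intercept, and edge sampling noise — for statistical
  calibration and power studies; and
* a full *voxel* path (:func:`generate_dataset`) that synthesizes 4-D BOLD
  volumes on a small grid: region latent signals with a planted
  block-correlation structure (AR(1) in time), voxelwise white noise,
  spatially structured nuisance components living mostly in WM/CSF, and
  motion-parameter files with smooth drift plus supra-threshold spikes.

Planted sex effects are specified on the Fisher-z scale (the scale the
pipeline's inference operates on) and converted to correlations via tanh;
a nearest-positive-definite repair (eigenvalue clipping) follows, because
additive z increments can break positive definiteness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BoldRun, MotionTrace
from .stats import fisher_z, inverse_fisher_z

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_atlas",
    "generate_dataset",
    "simulate_edge_z",
    "simulate_cohort_matrices",
    "write_dataset",
]

# Motion model constants: random-walk steps sized so the expected FD
# (~0.024 mm) sits well below the 0.2 mm scrub threshold, matching the
# very low motion of well-acclimated awake rats.
DRIFT_TRANS_STEP_MM = 0.005
DRIFT_ROT_STEP_RAD = 0.001


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the emulated acquisition: 600 one-second volumes per
    scan, a 64-region bilateral parcellation organized into 10 systems on a
    32 x 32 x 8 grid of 0.5 mm voxels, and two scans per rat.
    """

    n_rats_per_sex: int = 7
    scans_per_rat: int = 2
    n_volumes: int = 600
    tr_seconds: float = 1.0
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: float = 0.5
    n_regions: int = 64
    n_systems: int = 10
    baseline_correlation: float = 0.35
    effect_edges_male: list[tuple[int, int]] | None = None
    effect_edges_female: list[tuple[int, int]] | None = None
    effect_size_z: float = 0.3
    rat_sd_z: float = 0.1
    edge_noise_sd_z: float = 0.045  # ~ 1/sqrt(T-3) at T ~ 500 retained volumes
    motion_spike_prob: float = 0.01
    motion_spike_scale_mm: float = 0.5
    n_noise_components: int = 3
    ar_coefficient: float = 0.3
    signal_amplitude: float = 1.0
    voxel_noise_sd: float = 1.0
    nuisance_brain_amplitude: float = 0.3
    nuisance_outside_amplitude: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_regions % 2 != 0:
            raise ValueError("n_regions must be even (bilateral pairing)")
        if self.n_systems > self.n_regions // 2:
            raise ValueError("more systems than region pairs")
        if not (-1.0 < self.baseline_correlation < 1.0):
            raise ValueError("baseline_correlation must lie in (-1, 1)")
        if self.effect_size_z < 0:
            raise ValueError("effect_size_z must be nonnegative")
        if not (0.0 <= self.motion_spike_prob <= 1.0):
            raise ValueError("motion_spike_prob must be a probability")
        if self.effect_edges_male is None:
            self.effect_edges_male = self._default_effect_edges(which="male")
        if self.effect_edges_female is None:
            self.effect_edges_female = self._default_effect_edges(which="female")
        male = {tuple(sorted(e)) for e in self.effect_edges_male}
        female = {tuple(sorted(e)) for e in self.effect_edges_female}
        if male & female:
            raise ValueError("male and female effect edge sets must be disjoint")
        for i, j in male | female:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions) or i == j:
                raise ValueError(f"invalid effect edge ({i}, {j})")

    def _default_effect_edges(self, which: str) -> list[tuple[int, int]]:
        """Default planted effects mimic the reported dimorphism pattern:
        male-stronger edges run between the first and fourth systems
        (cortico-striatal-like, between-cluster), female-stronger edges sit
        within the last system (hypothalamus-like, within-cluster)."""
        clusters = self.cluster_assignment()
        if which == "male":
            if self.n_systems < 2:
                return []  # no between-cluster edges exist
            a = np.flatnonzero(clusters == 0)
            b = np.flatnonzero(clusters == min(3, self.n_systems - 1))
            return [(int(a[k % len(a)]), int(b[k // len(a) % len(b)])) for k in range(8)]
        regs = np.flatnonzero(clusters == self.n_systems - 1)
        edges = [
            (int(regs[i]), int(regs[j]))
            for i in range(len(regs))
            for j in range(i + 1, len(regs))
        ]
        return edges[:6]

    def cluster_assignment(self) -> np.ndarray:
        """System/cluster label per region; homotopic pairs share a system."""
        n_pairs = self.n_regions // 2
        pair_sys = np.array_split(np.arange(n_pairs), self.n_systems)
        lab = np.empty(self.n_regions, dtype=int)
        for s, pairs in enumerate(pair_sys):
            for p in pairs:
                lab[2 * p] = s
                lab[2 * p + 1] = s
        return lab


@dataclass
class GroundTruth:
    """Planted structure of one synthetic cohort."""

    rat_sex: dict  # rat id -> 'M' | 'F'
    scan_estrus: dict  # scan id -> 'estrus' | 'non-estrus' (female scans)
    effect_map_z: np.ndarray  # (n_regions, n_regions), male minus female on z
    cluster_assignment: np.ndarray
    noise_component_timecourses: dict  # scan id -> (t, n_noise) array
    spike_volumes: dict  # scan id -> sorted volume indices

    def to_json(self) -> str:
        return json.dumps(
            {
                "rat_sex": self.rat_sex,
                "scan_estrus": self.scan_estrus,
                "effect_map_z": self.effect_map_z.tolist(),
                "cluster_assignment": self.cluster_assignment.tolist(),
                "spike_volumes": {k: list(map(int, v)) for k, v in self.spike_volumes.items()},
            },
            indent=1,
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    atlas: np.ndarray
    lookup: pd.DataFrame
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    runs: list[BoldRun]
    manifest: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Atlas


def generate_atlas(config: SyntheticConfig):
    """Synthetic parcellation on the voxel grid.

    Returns ``(atlas, lookup, masks)``: an integer label volume whose
    nonzero labels 1..n_regions tile a central "brain" box as mirrored
    left/right pairs, a lookup table (label, name, hemisphere, system), and
    a dict with disjoint brain/WM/CSF masks.  WM and CSF occupy thin slabs
    outside the parcels and carry pure nuisance signal in generated data.
    """
    nx, ny, nz = config.grid_shape
    n_pairs = config.n_regions // 2
    # Brain box with 2-voxel margins in x/y and 1 in z; WM/CSF slabs at the
    # y extremes inside the head.
    x0, x1 = 2, nx - 2
    yb0, yb1 = 4, ny - 4
    z0, z1 = 1, nz - 1
    half = (x1 - x0) // 2
    left_vox = [
        (x, y, z)
        for x in range(x0, x0 + half)
        for y in range(yb0, yb1)
        for z in range(z0, z1)
    ]
    if len(left_vox) < 8 * n_pairs:
        raise ValueError(
            f"grid {config.grid_shape} too small for {config.n_regions} regions "
            "at >= 8 voxels each"
        )
    atlas = np.zeros(config.grid_shape, dtype=np.int32)
    chunks = np.array_split(np.arange(len(left_vox)), n_pairs)
    for p, idx in enumerate(chunks):
        label_l = 2 * p + 1
        label_r = 2 * p + 2
        for k in idx:
            x, y, z = left_vox[k]
            atlas[x, y, z] = label_l
            atlas[nx - 1 - x, y, z] = label_r  # mirror across the midline
    brain_mask = atlas > 0
    wm_mask = np.zeros_like(brain_mask)
    csf_mask = np.zeros_like(brain_mask)
    wm_mask[x0:x1, yb0 - 2 : yb0, z0:z1] = True
    csf_mask[x0:x1, yb1 : yb1 + 2, z0:z1] = True
    wm_mask &= ~brain_mask
    csf_mask &= ~brain_mask

    clusters = config.cluster_assignment()
    lookup = pd.DataFrame(
        {
            "label": np.arange(1, config.n_regions + 1),
            "name": [
                f"region_{i // 2:02d}_{'L' if i % 2 == 0 else 'R'}"
                for i in range(config.n_regions)
            ],
            "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(config.n_regions)],
            "system": [f"system_{clusters[i]:02d}" for i in range(config.n_regions)],
        }
    )
    return atlas, lookup, {"brain": brain_mask, "wm": wm_mask, "csf": csf_mask}


def split_atlas(atlas: np.ndarray, lookup: pd.DataFrame):
    """Double-resolution variant: split each region into two sub-parcels
    along the anterior-posterior axis (same code path downstream, 2x the
    region count)."""
    out = np.zeros_like(atlas)
    rows = []
    for _, row in lookup.iterrows():
        vox = np.argwhere(atlas == row["label"])
        if vox.shape[0] < 2:
            raise ValueError(f"region {row['label']} too small to split")
        order = np.lexsort((vox[:, 2], vox[:, 0], vox[:, 1]))
        halves = np.array_split(order, 2)
        for h, part in enumerate(halves):
            new_label = 2 * (row["label"] - 1) + h + 1
            for k in part:
                out[tuple(vox[k])] = new_label
            rows.append(
                {
                    "label": new_label,
                    "name": f"{row['name']}_{'a' if h == 0 else 'p'}",
                    "hemisphere": row["hemisphere"],
                    "system": row["system"],
                }
            )
    return out, pd.DataFrame(rows).sort_values("label").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Population model on the Fisher-z scale


def nearest_pd_correlation(R: np.ndarray, eig_floor: float = 1e-4) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= eig_floor:
        return R
    w = np.clip(w, eig_floor, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def population_z(config: SyntheticConfig, sex: str) -> np.ndarray:
    """Population-mean Fisher-z matrix for one sex: block baseline within
    planted clusters plus the sex-specific edge increments."""
    n = config.n_regions
    clusters = config.cluster_assignment()
    same = clusters[:, None] == clusters[None, :]
    base = np.where(same, fisher_z(config.baseline_correlation), 0.0)
    np.fill_diagonal(base, 0.0)
    z = base.copy()
    edges = config.effect_edges_male if sex == "M" else config.effect_edges_female
    for i, j in edges:
        z[i, j] += config.effect_size_z
        z[j, i] += config.effect_size_z
    return z


def effect_map_z(config: SyntheticConfig) -> np.ndarray:
    """Male-minus-female planted effect on the Fisher-z scale."""
    return population_z(config, "M") - population_z(config, "F")


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    m = rng.normal(0.0, sd, size=(n, n))
    m = np.triu(m, k=1)
    return m + m.T


# ---------------------------------------------------------------------------
# Fast latent-level generators


def simulate_edge_z(
    n_rats_per_sex: int,
    scans_per_rat: int,
    n_edges: int,
    effect_z=0.0,
    rat_sd_z: float = 0.1,
    edge_noise_sd_z: float = 0.045,
    seed: int = 0,
):
    """Draw per-scan Fisher-z values for a bank of independent edges.

    ``effect_z`` (scalar or length-``n_edges`` vector) is added to the male
    group's mean.  Returns ``(Y, sex, rat)`` with ``Y`` of shape
    (n_scans, n_edges).  This is the model the edgewise mixed model
    assumes, so it serves calibration and power studies directly.
    """
    rng = np.random.default_rng(seed)
    effect = np.broadcast_to(np.asarray(effect_z, dtype=float), (n_edges,))
    sex, rat, rows = [], [], []
    for s, sx in enumerate(("F", "M")):
        for r in range(n_rats_per_sex):
            rat_id = f"{sx}{r:02d}"
            offs = rng.normal(0.0, rat_sd_z, size=n_edges)
            mu = offs + (effect if sx == "M" else 0.0)
            for _ in range(scans_per_rat):
                rows.append(mu + rng.normal(0.0, edge_noise_sd_z, size=n_edges))
                sex.append(sx)
                rat.append(rat_id)
    return np.asarray(rows), np.asarray(sex), np.asarray(rat)


def simulate_cohort_matrices(config: SyntheticConfig, seed: int | None = None):
    """Per-scan Fisher-z connectivity matrices drawn at the latent level.

    Each scan's matrix is the sex's population z plus a rat-level symmetric
    random offset (sd ``rat_sd_z``) plus symmetric edge noise
    (sd ``edge_noise_sd_z``).  Returns ``(matrices, sex, rat, estrus)``
    aligned lists; ``matrices`` are plain (n, n) arrays with zero diagonal.
    """
    from .connectivity import ConnectivityMatrix

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_regions
    zpop = {s: population_z(config, s) for s in ("M", "F")}
    mats, sexes, rats, estrus = [], [], [], []
    for sx in ("F", "M"):
        for r in range(config.n_rats_per_sex):
            rat_id = f"{sx}{r:02d}"
            offs = _symmetric_noise(rng, n, config.rat_sd_z)
            for s in range(config.scans_per_rat):
                z = zpop[sx] + offs + _symmetric_noise(rng, n, config.edge_noise_sd_z)
                np.fill_diagonal(z, 0.0)
                lab = None
                if sx == "F":
                    lab = "estrus" if rng.random() < 0.5 else "non-estrus"
                mats.append(
                    ConnectivityMatrix(
                        z=z,
                        region_ids=np.arange(1, n + 1),
                        systems=config.cluster_assignment(),
                        meta={"rat": rat_id, "sex": sx, "scan": s, "estrus": lab},
                    )
                )
                sexes.append(sx)
                rats.append(rat_id)
                estrus.append(lab)
    return mats, np.asarray(sexes), np.asarray(rats), np.asarray(estrus, dtype=object)


# ---------------------------------------------------------------------------
# Full voxel-level generator


def _ar1_series(rng, R: np.ndarray, n_volumes: int, phi: float) -> np.ndarray:
    """Latent region series with stationary covariance R and AR(1) time
    structure: x_t = phi x_{t-1} + sqrt(1-phi^2) L eps_t."""
    L = np.linalg.cholesky(R)
    n = R.shape[0]
    x = np.empty((n_volumes, n))
    innov = rng.standard_normal((n_volumes, n)) @ L.T
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n_volumes):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def _motion_trace(rng, n_volumes: int, spike_prob: float, spike_scale: float):
    """Random-walk drift plus step-change spikes; returns (params, spikes)."""
    steps = np.concatenate(
        [
            rng.normal(0.0, DRIFT_TRANS_STEP_MM, size=(n_volumes, 3)),
            rng.normal(0.0, DRIFT_ROT_STEP_RAD, size=(n_volumes, 3)),
        ],
        axis=1,
    )
    steps[0] = 0.0
    spikes = np.flatnonzero(rng.random(n_volumes) < spike_prob)
    spikes = spikes[spikes > 0]
    sign = 1.0
    for v in spikes:
        steps[v, 0] += sign * spike_scale  # persistent step: FD spikes once
        sign = -sign
    return np.cumsum(steps, axis=0), np.sort(spikes)


def _smooth_map(rng, masks, sigma_vox=2.0):
    from scipy import ndimage

    vol = rng.standard_normal(masks["brain"].shape)
    vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
    vol /= np.abs(vol).max() + 1e-30
    return vol


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full cohort: atlas, per-scan BOLD runs with motion and
    nuisance structure, a manifest, and the ground truth.

    All randomness flows from ``config.seed``; identical configs produce
    bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    atlas, lookup, masks = generate_atlas(config)
    clusters = config.cluster_assignment()
    zpop = {s: population_z(config, s) for s in ("M", "F")}
    for s in ("M", "F"):
        r = inverse_fisher_z(zpop[s])
        np.fill_diagonal(r, 1.0)
        # near-singular planted correlations make the covariance target
        # numerically degenerate; treat them as outside the valid range
        if np.any(np.abs(r[~np.eye(len(r), dtype=bool)]) >= 0.995):
            raise ValueError(
                "planted effects push correlations outside the usable range "
                "(|r| >= 0.995); reduce baseline_correlation or effect_size_z"
            )

    runs: list[BoldRun] = []
    manifest_rows = []
    rat_sex, scan_estrus, noise_tcs, spike_map = {}, {}, {}, {}
    region_vox = [np.argwhere(atlas == lab) for lab in lookup["label"]]
    outside = masks["wm"] | masks["csf"]
    phi = config.ar_coefficient

    for sx in ("F", "M"):
        for ridx in range(config.n_rats_per_sex):
            rat_id = f"{sx}{ridx:02d}"
            rat_sex[rat_id] = sx
            offs = _symmetric_noise(rng, config.n_regions, config.rat_sd_z)
            for scan in range(config.scans_per_rat):
                scan_id = f"{rat_id}_s{scan:02d}"
                z = zpop[sx] + offs
                np.fill_diagonal(z, 0.0)
                R = inverse_fisher_z(z)
                np.fill_diagonal(R, 1.0)
                R = nearest_pd_correlation(R)
                latent = _ar1_series(rng, R, config.n_volumes, phi)

                data = np.zeros(config.grid_shape + (config.n_volumes,), dtype=np.float32)
                tissue = masks["brain"] | outside
                n_tissue = int(tissue.sum())
                flat = rng.normal(
                    0.0, config.voxel_noise_sd, size=(n_tissue, config.n_volumes)
                ).astype(np.float32)
                # Region signal, added on the flattened tissue view.
                tissue_idx = np.flatnonzero(tissue.ravel())
                pos_in_flat = np.full(tissue.size, -1, dtype=np.int64)
                pos_in_flat[tissue_idx] = np.arange(n_tissue)
                for r_i, vox in enumerate(region_vox):
                    lin = np.ravel_multi_index(vox.T, config.grid_shape)
                    sig = (config.signal_amplitude * latent[:, r_i]).astype(np.float32)
                    flat[pos_in_flat[lin]] += sig

                n_tc = np.empty((config.n_volumes, config.n_noise_components))
                amp = np.where(
                    outside,
                    config.nuisance_outside_amplitude,
                    np.where(masks["brain"], config.nuisance_brain_amplitude, 0.0),
                )
                for c in range(config.n_noise_components):
                    tc = _ar1_series(rng, np.eye(1), config.n_volumes, 0.5)[:, 0]
                    n_tc[:, c] = tc
                    wmap = _smooth_map(rng, masks)
                    w = (wmap * amp).ravel()[tissue_idx].astype(np.float32)
                    flat += np.outer(w, tc.astype(np.float32))
                data[tissue] = flat
                noise_tcs[scan_id] = n_tc

                params, spikes = _motion_trace(
                    rng,
                    config.n_volumes,
                    config.motion_spike_prob,
                    config.motion_spike_scale_mm,
                )
                spike_map[scan_id] = spikes

                estrus = None
                if sx == "F":
                    estrus = "estrus" if rng.random() < 0.5 else "non-estrus"
                    scan_estrus[scan_id] = estrus

                runs.append(
                    BoldRun(
                        data=data,
                        brain_mask=masks["brain"],
                        wm_mask=masks["wm"],
                        csf_mask=masks["csf"],
                        motion=MotionTrace(params=params),
                        tr_seconds=config.tr_seconds,
                        meta={
                            "scan_id": scan_id,
                            "rat": rat_id,
                            "sex": sx,
                            "session": 0,
                            "scan": scan,
                            "estrus": estrus,
                        },
                    )
                )
                manifest_rows.append(
                    {
                        "rat_id": rat_id,
                        "sex": sx,
                        "session": 0,
                        "scan_id": scan_id,
                        "estrus": estrus if estrus is not None else "",
                    }
                )

    truth = GroundTruth(
        rat_sex=rat_sex,
        scan_estrus=scan_estrus,
        effect_map_z=effect_map_z(config),
        cluster_assignment=clusters,
        noise_component_timecourses=noise_tcs,
        spike_volumes=spike_map,
    )
    return SyntheticDataset(
        config=config,
        atlas=atlas,
        lookup=lookup,
        brain_mask=masks["brain"],
        wm_mask=masks["wm"],
        csf_mask=masks["csf"],
        runs=runs,
        manifest=pd.DataFrame(manifest_rows),
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write the cohort to disk in the formats the pipeline consumes.

    Layout: NIfTI BOLD per scan, NIfTI atlas and tissue masks, 6-column
    whitespace-delimited motion files (translations mm, rotations rad),
    per-scan nuisance-timecourse TSVs (the ground-truth counterpart of
    manually labeled noise components), a scan manifest TSV, the region
    lookup TSV, and the ground truth as JSON.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.diag([ds.config.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(ds.atlas.astype(np.int16), aff), outdir / "atlas.nii.gz")
    for name, m in (
        ("brain", ds.brain_mask),
        ("wm", ds.wm_mask),
        ("csf", ds.csf_mask),
    ):
        nib.save(
            nib.Nifti1Image(m.astype(np.uint8), aff), outdir / f"mask_{name}.nii.gz"
        )
    ds.lookup.to_csv(outdir / "lookup.tsv", sep="\t", index=False)

    rows = []
    for run, mrow in zip(ds.runs, ds.manifest.to_dict("records")):
        sid = run.meta["scan_id"]
        bold = outdir / f"{sid}_bold.nii.gz"
        motion = outdir / f"{sid}_motion.txt"
        nib.save(nib.Nifti1Image(run.data, aff), bold)
        np.savetxt(motion, run.motion.params, fmt="%.6f")
        np.savetxt(
            outdir / f"{sid}_nuisance_tcs.tsv",
            ds.truth.noise_component_timecourses[sid],
            fmt="%.6f",
            delimiter="\t",
        )
        rows.append(
            {
                **mrow,
                "scan_path": bold.name,
                "motion_path": motion.name,
                "ic_labels_path": "",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    (outdir / "ground_truth.json").write_text(ds.truth.to_json())
    return outdir
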