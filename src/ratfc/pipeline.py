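"""End-to-end orchestration: preprocess -> connectivity -> classify -> network.

A single master seed feeds every stochastic stage through named substreams
(stable hashes of ``"{master}:{stage}:{scan}"``), so rerunning any stage in
isolation reproduces its output without coupling stages to one another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSettings, classify_all_regions
from .connectivity import (
    connectivity_matrix,
    edgewise_mixed_model,
    extract_roi_timeseries,
    group_mean_matrix,
    matrix_similarity,
    subgroup_contrast,
    system_summary,
)
from .io import Manifest, read_lookup, read_motion_file, read_nifti, save_matrix_tsv
from .network import DEFAULT_DENSITIES, compare_topology, graph_metrics, ward_cluster
from .preprocess import BoldRun, preprocess_run

log = logging.getLogger("ratfc")

__all__ = ["PipelineConfig", "run_pipeline", "substream_seed"]


def substream_seed(master: int, *names) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    key = ":".join([str(master), *map(str, names)]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (
        2**31
    )


@dataclass
class PipelineConfig:
    """All tunables of the four analysis stages.

    Defaults are the reference protocol: FD threshold 0.2 mm with a 5 mm
    head radius, first 10 volumes discarded, 15% maximum removal, 50 ICA
    components, 1 mm FWHM smoothing, 0.01-0.1 Hz bandpass, 10-fold CV
    repeated 5 times with 1000 permutations, graph densities 0.10-0.30 in
    steps of 0.05, and a 7-cluster dendrogram cut.
    """

    fd_threshold_mm: float = 0.2
    head_radius_mm: float = 5.0
    n_discard: int = 10
    max_removed_fraction: float = 0.15
    n_ica_components: int | None = 50
    fwhm_mm: float = 1.0
    voxel_size_mm: float = 0.5
    band_hz: tuple[float, float] = (0.01, 0.1)
    alpha: float = 0.05
    n_folds: int = 10
    n_repeats: int = 5
    n_permutations: int = 1000
    group_by_rat: bool = False
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    n_null_graphs: int = 20
    n_clusters: int = 7
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["densities"] = list(self.densities)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        if "densities" in d:
            d["densities"] = tuple(d["densities"])
        return cls(**d)


def _load_run(manifest: Manifest, row, masks, config: PipelineConfig) -> BoldRun:
    from .preprocess import MotionTrace

    data = read_nifti(manifest.path(row, "scan_path")).astype(np.float64)
    trace = read_motion_file(manifest.path(row, "motion_path"))
    trace = MotionTrace(params=trace.params, head_radius_mm=config.head_radius_mm)
    return BoldRun(
        data=data,
        brain_mask=masks["brain"],
        wm_mask=masks["wm"],
        csf_mask=masks["csf"],
        motion=trace,
        tr_seconds=1.0,
        meta={
            "scan_id": row["scan_id"],
            "rat": row["rat_id"],
            "sex": row["sex"],
            "estrus": row.get("estrus", "") or None,
        },
    )


def run_pipeline(
    manifest: Manifest,
    atlas: np.ndarray,
    lookup: pd.DataFrame,
    masks: dict,
    config: PipelineConfig,
    outdir: str | Path,
) -> Path:
    """Run every stage for every scan and persist all result tables.

    Scan-level failures (rejected by scrubbing, unreadable files) are
    recorded in the QC log and the pipeline continues; losing every scan of
    one sex is a cohort-level failure and aborts.
    """
    outdir = Path(outdir)
    (outdir / "qc").mkdir(parents=True, exist_ok=True)
    (outdir / "matrices").mkdir(exist_ok=True)

    region_ids = lookup["label"].to_numpy()
    names = list(lookup["name"])
    systems = lookup["system"].to_numpy()

    matrices, sex_labels, rat_labels, estrus_labels = [], [], [], []
    qc_rows = []
    for _, row in manifest.scans.iterrows():
        sid = row["scan_id"]
        try:
            run = _load_run(manifest, row, masks, config)
            seed = substream_seed(config.seed, "preprocess", sid)
            cleaned, scrub_mask = preprocess_run(
                run,
                fd_threshold_mm=config.fd_threshold_mm,
                n_discard=config.n_discard,
                max_removed_fraction=config.max_removed_fraction,
                n_ica_components=config.n_ica_components,
                ic_labels_file=(
                    str(manifest.path(row, "ic_labels_path"))
                    if row.get("ic_labels_path", "")
                    else None
                ),
                fwhm_mm=config.fwhm_mm,
                voxel_size_mm=config.voxel_size_mm,
                band_hz=config.band_hz,
                seed=seed,
            )
        except Exception as exc:  # scan-level isolation
            log.warning("scan %s failed: %s", sid, exc)
            qc_rows.append({"scan_id": sid, "status": "failed", "reason": str(exc)})
            continue
        qc_rows.append(
            {
                "scan_id": sid,
                "status": "ok",
                "fd_mean": float(np.mean(run.motion.fd)) if run.motion.fd is not None else None,
                "fd_max": float(np.max(run.motion.fd)) if run.motion.fd is not None else None,
                "removed_fraction": scrub_mask.removed_fraction,
                "n_kept": scrub_mask.n_kept,
            }
        )
        ts = extract_roi_timeseries(cleaned.data, atlas, region_ids)
        m = connectivity_matrix(
            ts,
            region_ids=region_ids,
            region_names=names,
            systems=systems,
            meta=cleaned.meta,
        )
        save_matrix_tsv(outdir / "matrices" / f"{sid}.tsv", m.z, names)
        matrices.append(m)
        sex_labels.append(row["sex"])
        rat_labels.append(row["rat_id"])
        estrus_labels.append(row.get("estrus", "") or None)

    pd.DataFrame(qc_rows).to_csv(outdir / "qc" / "scans.tsv", sep="\t", index=False)
    sex_labels = np.asarray(sex_labels)
    rat_labels = np.asarray(rat_labels)
    for s in ("M", "F"):
        if not np.any(sex_labels == s):
            raise RuntimeError(f"cohort-level failure: no surviving scans for sex {s}")

    # --- edgewise sex contrast + system summary
    contrast = edgewise_mixed_model(matrices, sex_labels, rat_labels, alpha=config.alpha)
    cf = contrast.to_frame()
    cf["region_i"] = np.asarray(names)[contrast.edge_i]
    cf["region_j"] = np.asarray(names)[contrast.edge_j]
    cf.to_csv(outdir / "contrast_sex.tsv", sep="\t", index=False)
    system_summary(contrast, systems).to_csv(
        outdir / "system_summary.tsv", sep="\t", index=False
    )

    male_mean = group_mean_matrix(matrices, sex_labels, "M")
    female_mean = group_mean_matrix(matrices, sex_labels, "F")
    save_matrix_tsv(outdir / "mean_matrix_M.tsv", male_mean, names)
    save_matrix_tsv(outdir / "mean_matrix_F.tsv", female_mean, names)
    similarity = matrix_similarity(male_mean, female_mean)

    # --- estrus subgroup contrast (female scans with a label)
    has_estrus = np.array([e in ("estrus", "non-estrus") for e in estrus_labels])
    est_done = False
    if has_estrus.sum() >= 4:
        sub_m = [m for m, h in zip(matrices, has_estrus) if h]
        sub_lab = np.asarray([e for e, h in zip(estrus_labels, has_estrus) if h])
        sub_rat = rat_labels[has_estrus]
        if np.unique(sub_lab).size == 2 and np.unique(sub_rat).size >= 4:
            try:
                est, trend = subgroup_contrast(sub_m, sub_lab, sub_rat, alpha=config.alpha)
                ef = est.to_frame()
                ef["trend_p_lt_0.001"] = trend
                ef.to_csv(outdir / "contrast_estrus.tsv", sep="\t", index=False)
                est_done = True
            except ValueError as exc:
                log.warning("estrus contrast skipped: %s", exc)

    # --- per-region classification
    cls_settings = ClassifierSettings(
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        n_permutations=config.n_permutations,
        group_by_rat=config.group_by_rat,
        seed=substream_seed(config.seed, "classify"),
    )
    cls = classify_all_regions(matrices, cls_settings, rat_ids=rat_labels)
    cls.to_csv(outdir / "classification.tsv", sep="\t", index=False)

    # --- clustering of the group-mean matrices
    cluster_rows = []
    for label, mean in (("M", male_mean), ("F", female_mean)):
        dend = ward_cluster(mean, k=config.n_clusters)
        for name, c in zip(names, dend.labels):
            cluster_rows.append({"sex": label, "region": name, "cluster": int(c)})
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    # --- graph topology
    metric_frames = []
    for m, sid in zip(matrices, [mm.meta["scan_id"] for mm in matrices]):
        metric_frames.append(
            graph_metrics(
                m.z,
                densities=config.densities,
                n_null=config.n_null_graphs,
                seed=substream_seed(config.seed, "network", sid),
                meta={"scan_id": sid},
            )
        )
    metrics = pd.concat(metric_frames, ignore_index=True)
    metrics.to_csv(outdir / "topology_metrics.tsv", sep="\t", index=False)
    glob, nodal = compare_topology(metrics, sex_labels, rat_labels, alpha=config.alpha)
    glob.to_csv(outdir / "topology_contrast.tsv", sep="\t", index=False)
    nodal["region"] = np.asarray(names)[nodal["node"]]
    nodal.to_csv(outdir / "degree_contrast.tsv", sep="\t", index=False)

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_scans_ok": int(len(matrices)),
        "n_scans_failed": int(sum(r["status"] == "failed" for r in qc_rows)),
        "rejected_scans": [r["scan_id"] for r in qc_rows if r["status"] == "failed"],
        "matrix_similarity_m_f": similarity,
        "n_significant_edges": int(contrast.significant.sum()),
        "estrus_contrast_run": est_done,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return outdir
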