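"""File formats: manifests, region lookup tables, motion files, matrices.

Everything tabular is tab-separated text with header rows; regions are
named by their lookup-table name in outputs, never by bare index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Manifest",
    "ManifestError",
    "validate_manifest",
    "read_lookup",
    "read_motion_file",
    "read_nifti",
    "save_matrix_tsv",
    "load_matrix_tsv",
]

MANIFEST_REQUIRED = ["rat_id", "sex", "session", "scan_path", "motion_path"]
MANIFEST_OPTIONAL = ["scan_id", "ic_labels_path", "estrus"]


class ManifestError(ValueError):
    """Structural manifest problem, with line numbers where possible."""


@dataclass
class Manifest:
    scans: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.scans)

    def path(self, row, column: str) -> Path:
        p = Path(row[column])
        return p if p.is_absolute() else self.root / p


def validate_manifest(path: str | Path) -> Manifest:
    """Load and fully validate a scan manifest TSV.

    Checks: required columns, each rat mapping to exactly one sex,
    duplicate scan paths, and existence of every referenced file.  All
    problems are collected and reported together with 1-based data line
    numbers (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    errors: list[str] = []
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    root = path.parent
    sex_by_rat: dict[str, str] = {}
    seen_paths: dict[str, int] = {}
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        rat, sex = row["rat_id"], row["sex"]
        if sex not in ("M", "F"):
            errors.append(f"line {line}: sex must be M or F, got {sex!r}")
        elif rat in sex_by_rat and sex_by_rat[rat] != sex:
            errors.append(f"line {line}: rat {rat!r} listed with two sexes")
        else:
            sex_by_rat.setdefault(rat, sex)
        for col in ("scan_path", "motion_path"):
            p = row[col]
            if not p:
                errors.append(f"line {line}: empty {col}")
                continue
            full = Path(p) if Path(p).is_absolute() else root / p
            if not full.exists():
                errors.append(f"line {line}: {col} does not exist: {p}")
        sp = row["scan_path"]
        if sp in seen_paths:
            errors.append(
                f"line {line}: duplicate scan path {sp!r} "
                f"(first at line {seen_paths[sp]})"
            )
        else:
            seen_paths[sp] = line
        if row.get("ic_labels_path", ""):
            p = row["ic_labels_path"]
            full = Path(p) if Path(p).is_absolute() else root / p
            if not full.exists():
                errors.append(f"line {line}: ic_labels_path does not exist: {p}")
    if errors:
        raise ManifestError("invalid manifest:\n  " + "\n  ".join(errors))
    if "scan_id" not in df.columns:
        df["scan_id"] = [Path(p).stem for p in df["scan_path"]]
    return Manifest(scans=df, root=root)


def read_lookup(path: str | Path) -> pd.DataFrame:
    """Region lookup TSV: label, name, hemisphere, system."""
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "name", "hemisphere", "system"):
        if col not in df.columns:
            raise ValueError(f"lookup table missing column {col!r}")
    df["label"] = df["label"].astype(int)
    return df.sort_values("label").reset_index(drop=True)


def read_motion_file(path: str | Path):
    """6-column whitespace-delimited motion parameters (mm, mm, mm,
    rad, rad, rad), one row per volume."""
    from .preprocess import MotionTrace

    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    return MotionTrace(params=arr)


def read_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj)


def save_matrix_tsv(path: str | Path, z: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(z, index=names, columns=names).to_csv(
        path, sep="\t", index_label="region", float_format="%.8g"
    )


def load_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)
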