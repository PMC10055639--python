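"""ROI connectivity matrices and edgewise group contrasts.

Per scan, the region-mean BOLD series are correlated (Pearson) and mapped
to the Fisher-z scale.  Group differences are then assessed edge by edge
with a linear mixed model — group (sex, or estrus subgroup) as the fixed
effect and the rat as a random intercept — with Benjamini–Hochberg FDR over
all unique region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, fisher_z, mixed_model_ttest

__all__ = [
    "ConnectivityMatrix",
    "EdgewiseContrast",
    "extract_roi_timeseries",
    "connectivity_matrix",
    "edgewise_mixed_model",
    "subgroup_contrast",
    "system_summary",
    "group_mean_matrix",
    "matrix_similarity",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity over atlas regions for one scan."""

    z: np.ndarray
    region_ids: np.ndarray
    region_names: list[str] | None = None
    systems: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        n = z.shape[0]
        if z.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(z[off])):
            raise ValueError("non-finite off-diagonal Fisher-z values")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.z = z
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.size != n:
            raise ValueError("region_ids length does not match matrix")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class EdgewiseContrast:
    """Per-edge mixed-model contrast over unique region pairs (i < j)."""

    edge_i: np.ndarray
    edge_j: np.ndarray
    estimate: np.ndarray  # Fisher-z scale, group2 - group1
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    q: np.ndarray
    group_levels: tuple  # (level1, level2) in sorted order
    alpha: float = 0.05
    region_ids: np.ndarray | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.q < self.alpha

    @property
    def direction(self) -> np.ndarray:
        """Which group level has the larger mean on each edge."""
        lv1, lv2 = self.group_levels
        return np.where(self.estimate > 0, lv2, lv1)

    def to_square(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-edge vector into a symmetric matrix (diag = 0)."""
        n = int(max(self.edge_i.max(), self.edge_j.max())) + 1
        m = np.zeros((n, n), dtype=float)
        m[self.edge_i, self.edge_j] = values
        m[self.edge_j, self.edge_i] = values
        return m

    def to_frame(self) -> pd.DataFrame:
        names = (
            self.region_ids
            if self.region_ids is not None
            else np.arange(int(max(self.edge_j.max(), self.edge_i.max())) + 1)
        )
        return pd.DataFrame(
            {
                "region_i": np.asarray(names)[self.edge_i],
                "region_j": np.asarray(names)[self.edge_j],
                "estimate": self.estimate,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "q": self.q,
                "direction": self.direction,
            }
        )


def extract_roi_timeseries(
    data: np.ndarray, atlas: np.ndarray, region_ids: np.ndarray
) -> np.ndarray:
    """Region-mean time series: row r = mean over voxels labeled r.

    ``data`` is the (x, y, z, t) cleaned signal and ``atlas`` an integer
    label volume on the same grid.  A region with no voxels raises an
    atlas-coverage error rather than yielding a silent NaN row.
    """
    if atlas.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match the BOLD grid")
    region_ids = np.asarray(region_ids)
    out = np.empty((region_ids.size, data.shape[3]), dtype=float)
    for k, rid in enumerate(region_ids):
        vox = atlas == rid
        n = int(vox.sum())
        if n == 0:
            raise ValueError(f"region {rid} has no voxels in the atlas")
        out[k] = data[vox].mean(axis=0)
    return out


def connectivity_matrix(
    ts: np.ndarray,
    region_ids: np.ndarray | None = None,
    meta: dict | None = None,
    systems: np.ndarray | None = None,
    region_names: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pearson-correlate region series and Fisher-z transform.

    Rejects constant rows (undefined correlation) and perfectly correlated
    pairs (|r| = 1, where arctanh diverges) instead of clipping.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a (n_regions, t>=3) time-series matrix")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region index {bad} has a constant time series")
    r = np.corrcoef(ts)
    off = ~np.eye(r.shape[0], dtype=bool)
    r_off = np.clip(r[off], -1.0, 1.0)  # guard FP overshoot only
    if np.any(np.abs(r_off) >= 1.0 - 1e-12):
        raise ValueError("perfectly correlated region pair (|r| = 1)")
    z = np.zeros_like(r)
    z[off] = fisher_z(r_off)
    if region_ids is None:
        region_ids = np.arange(r.shape[0])
    return ConnectivityMatrix(
        z=z,
        region_ids=region_ids,
        region_names=region_names,
        systems=systems,
        meta=meta or {},
    )


def _stack_edges(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, ...]:
    n = matrices[0].n_regions
    for m in matrices:
        if m.n_regions != n:
            raise ValueError("matrices disagree on the region set")
    iu, ju = np.triu_indices(n, k=1)
    Y = np.stack([m.z[iu, ju] for m in matrices])  # (n_scans, n_edges)
    return Y, iu, ju


def edgewise_mixed_model(
    matrices: list[ConnectivityMatrix],
    group: np.ndarray,
    subject: np.ndarray,
    alpha: float = 0.05,
) -> EdgewiseContrast:
    """Fit z ~ group + (1 | subject) per unique edge, FDR over edges.

    ``group`` and ``subject`` give one label per scan (in the order of
    ``matrices``); typically sex and rat id.  With a single scan per rat
    the per-edge test reduces to the classical two-sample t-test.
    """
    group = np.asarray(group)
    subject = np.asarray(subject)
    if len(matrices) != group.size or group.size != subject.size:
        raise ValueError("one group and subject label per matrix is required")
    Y, iu, ju = _stack_edges(matrices)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("exactly two group levels are required")
    n_edges = Y.shape[1]
    est = np.empty(n_edges)
    t = np.empty(n_edges)
    df = np.empty(n_edges)
    p = np.empty(n_edges)
    for e in range(n_edges):
        res = mixed_model_ttest(Y[:, e], group, subject)
        est[e], t[e], df[e], p[e] = res.estimate, res.t, res.df, res.p
    q = bh_fdr(p)
    return EdgewiseContrast(
        edge_i=iu,
        edge_j=ju,
        estimate=est,
        t=t,
        df=df,
        p=p,
        q=q,
        group_levels=(levels[0], levels[1]),
        alpha=alpha,
        region_ids=matrices[0].region_ids,
    )


def subgroup_contrast(
    matrices: list[ConnectivityMatrix],
    subgroup: np.ndarray,
    subject: np.ndarray,
    alpha: float = 0.05,
    uncorrected_alpha: float = 0.001,
) -> tuple[EdgewiseContrast, np.ndarray]:
    """Within-group contrast (e.g. estrus/proestrus vs non-estrus scans).

    Same machinery as the sex contrast; additionally returns the
    uncorrected significance mask at ``uncorrected_alpha``, since small
    subgroups often show trends that do not survive FDR correction.
    """
    subgroup = np.asarray(subgroup)
    levels, counts = np.unique(subgroup, return_counts=True)
    if levels.size != 2 or np.any(counts == 0):
        raise ValueError("need two nonempty subgroups")
    contrast = edgewise_mixed_model(matrices, subgroup, subject, alpha=alpha)
    return contrast, contrast.p < uncorrected_alpha


def system_summary(
    contrast: EdgewiseContrast, systems: np.ndarray
) -> pd.DataFrame:
    """Count significant edges within and between brain systems.

    One row per unordered system pair (including within-system rows):
    significant-edge counts split by direction, possible-edge count, and
    their ratio.
    """
    systems = np.asarray(systems)
    if contrast.region_ids is not None and systems.size != contrast.region_ids.size:
        raise ValueError("one system per region is required")
    if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in systems):
        raise ValueError("every region needs a system assignment")
    sys_i = systems[contrast.edge_i]
    sys_j = systems[contrast.edge_j]
    swap = sys_j < sys_i  # order each pair lexicographically
    lo = np.where(swap, sys_j, sys_i)
    hi = np.where(swap, sys_i, sys_j)
    sig = contrast.significant
    direc = contrast.direction
    lv1, lv2 = contrast.group_levels
    rows = []
    uniq = np.unique(systems)
    for a_idx, a in enumerate(uniq):
        for b in uniq[a_idx:]:
            in_pair = (lo == min(a, b)) & (hi == max(a, b))
            possible = int(in_pair.sum())
            n_sig = int((in_pair & sig).sum())
            rows.append(
                {
                    "system_a": a,
                    "system_b": b,
                    "n_significant": n_sig,
                    f"n_{lv1}_stronger": int((in_pair & sig & (direc == lv1)).sum()),
                    f"n_{lv2}_stronger": int((in_pair & sig & (direc == lv2)).sum()),
                    "n_possible": possible,
                    "ratio": n_sig / possible if possible else 0.0,
                }
            )
    return pd.DataFrame(rows)


def group_mean_matrix(
    matrices: list[ConnectivityMatrix], group: np.ndarray, level
) -> np.ndarray:
    """Mean Fisher-z matrix over the scans of one group."""
    group = np.asarray(group)
    sel = [m for m, g in zip(matrices, group) if g == level]
    if not sel:
        raise ValueError(f"no scans with group label {level!r}")
    return np.mean([m.z for m in sel], axis=0)


def matrix_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Entry-to-entry Pearson correlation of two matrices' unique edges."""
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return float(np.corrcoef(a[iu, ju], b[iu, ju])[0, 1])
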