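"""Scan-level preprocessing: motion scrubbing, ICA cleaning, nuisance and
soft regression, spatial smoothing, and temporal bandpass filtering.

The stages follow the order scrub -> nuisance regression -> soft regression
of noise-IC unique parts -> smoothing -> bandpass.  Censored volumes are
dropped and the retained volumes concatenated before any regression or
filtering; interpolation over censored gaps is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal
from sklearn.decomposition import FastICA

__all__ = [
    "MotionTrace",
    "ScrubMask",
    "BoldRun",
    "IcaDecomposition",
    "compute_fd",
    "scrub",
    "apply_scrub",
    "ica_decompose",
    "label_components",
    "nuisance_regress",
    "smooth_and_filter",
    "preprocess_run",
]

DEFAULT_HEAD_RADIUS_MM = 5.0  # rat head radius: cortex to head centre
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionTrace:
    """Rigid-body motion parameters for one scan.

    ``params`` has one row per volume and six columns: translations x, y, z
    in millimetres, then rotations alpha, beta, gamma in radians.  ``fd`` is
    the framewise displacement in millimetres (zero for the first volume)
    once :func:`compute_fd` has run.
    """

    params: np.ndarray
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    fd: np.ndarray | None = None

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be (n_volumes, 6)")
        if self.head_radius_mm <= 0:
            raise ValueError("head radius must be positive")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class ScrubMask:
    """Per-volume keep/drop decision with the reason for each drop."""

    keep: np.ndarray
    steady_state_drop: np.ndarray
    fd_drop: np.ndarray
    adjacent_drop: np.ndarray
    removed_fraction: float  # over post-steady-state volumes
    rejected: bool

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class BoldRun:
    """One scan: 4-D signal plus masks, motion, and scrub state.

    ``data`` is (x, y, z, t).  The brain, white-matter and CSF masks are
    mutually disjoint boolean volumes.  After :func:`apply_scrub` the time
    axis holds only retained volumes and ``motion.params`` is subset to
    match.
    """

    data: np.ndarray
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    motion: MotionTrace | None
    tr_seconds: float
    meta: dict = field(default_factory=dict)
    scrub_mask: ScrubMask | None = None
    scrubbed: bool = False

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        for name in ("brain_mask", "wm_mask", "csf_mask"):
            m = getattr(self, name)
            if m.shape != self.data.shape[:3]:
                raise ValueError(f"{name} does not match the volume grid")
        overlap = (
            self.brain_mask.astype(int)
            + self.wm_mask.astype(int)
            + self.csf_mask.astype(int)
        )
        if overlap.max() > 1:
            raise ValueError("brain/WM/CSF masks must be mutually disjoint")
        if (
            self.motion is not None
            and not self.scrubbed
            and self.motion.n_volumes != self.data.shape[3]
        ):
            raise ValueError("motion trace length does not match time axis")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def voxel_timeseries(self, mask: np.ndarray) -> np.ndarray:
        """Return (t, n_voxels) series for voxels inside ``mask``."""
        return self.data[mask].T


@dataclass
class IcaDecomposition:
    """Spatial ICA of in-brain voxels: maps are independent over space."""

    maps: np.ndarray  # (n_components, n_voxels_in_mask)
    timecourses: np.ndarray  # (t, n_components)
    mask: np.ndarray  # the voxel mask the maps refer to
    labels: np.ndarray | None = None  # 'signal' | 'noise' per component

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def noise_indices(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("components are unlabeled")
        return np.flatnonzero(self.labels == "noise")


def compute_fd(trace: MotionTrace) -> MotionTrace:
    """Framewise displacement per volume transition.

    FD_i = |dx_i| + |dy_i| + |dz_i| + r * (|da_i| + |db_i| + |dg_i|), with
    differences taken from the previous volume and the rotation angles
    converted to arc length by the head radius r.  FD of the first volume
    is zero by convention.
    """
    if trace.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    bad = ~np.isfinite(trace.params)
    if bad.any():
        vol = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"non-finite motion parameter at volume {vol}")
    d = np.abs(np.diff(trace.params, axis=0))
    fd = d[:, :3].sum(axis=1) + trace.head_radius_mm * d[:, 3:].sum(axis=1)
    trace.fd = np.concatenate([[0.0], fd])
    return trace


def scrub(
    trace: MotionTrace,
    fd_threshold_mm: float = 0.2,
    n_discard: int = 10,
    max_removed_fraction: float = 0.15,
) -> ScrubMask:
    """Build the volume-censoring mask from the FD trace.

    Drops the first ``n_discard`` steady-state volumes, every volume with
    FD above threshold, and the immediate temporal neighbours of each
    supra-threshold volume.  The removed fraction is computed over the
    post-steady-state volumes; exceeding ``max_removed_fraction`` flags the
    scan as rejected (a verdict, not an error).
    """
    if trace.fd is None:
        trace = compute_fd(trace)
    n = trace.n_volumes
    fd = trace.fd
    steady = np.zeros(n, dtype=bool)
    steady[: min(n_discard, n)] = True
    over = fd > fd_threshold_mm
    adjacent = np.zeros(n, dtype=bool)
    adjacent[:-1] |= over[1:]
    adjacent[1:] |= over[:-1]
    adjacent &= ~over
    keep = ~(steady | over | adjacent)
    post = n - int(steady.sum())
    removed_post = int(((over | adjacent) & ~steady).sum())
    frac = removed_post / post if post > 0 else 1.0
    return ScrubMask(
        keep=keep,
        steady_state_drop=steady,
        fd_drop=over & ~steady,
        adjacent_drop=adjacent & ~steady,
        removed_fraction=frac,
        rejected=frac > max_removed_fraction,
    )


def apply_scrub(run: BoldRun, mask: ScrubMask) -> BoldRun:
    """Concatenate retained volumes; motion parameters are subset to match."""
    if run.scrubbed:
        return run
    keep = mask.keep
    motion = run.motion
    if motion is not None:
        motion = MotionTrace(
            params=motion.params[keep],
            head_radius_mm=motion.head_radius_mm,
            fd=None if motion.fd is None else motion.fd[keep],
        )
    return replace(
        run,
        data=run.data[..., keep],
        motion=motion,
        scrub_mask=mask,
        scrubbed=True,
    )


def ica_decompose(
    run: BoldRun, n_components: int = 50, seed: int = 0
) -> IcaDecomposition:
    """Spatial ICA of the in-brain voxel series (fast fixed-point algorithm).

    Voxels are the samples and timepoints the features, so the recovered
    sources are spatial maps and the mixing matrix holds the component
    timecourses.  Deterministic given ``seed``.
    """
    mask = run.brain_mask
    if not mask.any():
        raise ValueError("brain mask is empty")
    t = run.n_volumes
    if t <= n_components:
        raise ValueError(
            f"need more retained volumes ({t}) than components ({n_components})"
        )
    X = run.data[mask]  # (n_voxels, t)
    ica = FastICA(
        n_components=n_components,
        random_state=np.random.RandomState(seed),
        whiten="unit-variance",
        max_iter=1000,
        tol=1e-5,
    )
    maps = ica.fit_transform(X).T  # (n_components, n_voxels)
    tcs = ica.mixing_  # (t, n_components)
    # Sign convention: positive-skew maps; fixed order by explained energy.
    for k in range(maps.shape[0]):
        if sstats_skew(maps[k]) < 0:
            maps[k] *= -1.0
            tcs[:, k] *= -1.0
    energy = (tcs**2).sum(axis=0) * (maps**2).sum(axis=1)
    order = np.argsort(-energy, kind="stable")
    return IcaDecomposition(maps=maps[order], timecourses=tcs[:, order], mask=mask)


def sstats_skew(x: np.ndarray) -> float:
    x = x - x.mean()
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean(x**3) / s**3)


def label_components(
    decomp: IcaDecomposition,
    labels_file: str | None = None,
    run: BoldRun | None = None,
    fd_corr_threshold: float = 0.3,
    outside_weight_threshold: float = 0.5,
) -> IcaDecomposition:
    """Assign signal/noise labels to ICA components.

    The supported path is an explicit label file (tab/whitespace-delimited:
    component index, ``signal`` or ``noise``).  Alternatively a heuristic
    flags a component as noise when its timecourse correlates with the FD
    trace above ``fd_corr_threshold`` in absolute value, or when the
    fraction of its squared spatial weight lying outside the brain mask
    (within WM/CSF) exceeds ``outside_weight_threshold``.
    """
    labels = np.array(["signal"] * decomp.n_components, dtype=object)
    if labels_file is not None:
        import csv

        with open(labels_file) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                parts = row if len(row) >= 2 else row[0].split()
                idx, lab = int(parts[0]), parts[1].strip().lower()
                if idx < 0 or idx >= decomp.n_components:
                    raise ValueError(
                        f"label file references absent component {idx}"
                    )
                if lab not in ("signal", "noise"):
                    raise ValueError(f"unknown component label {lab!r}")
                labels[idx] = lab
    else:
        if run is None:
            raise ValueError("heuristic labeling needs the BoldRun")
        fd = run.motion.fd if run.motion is not None else None
        outside = run.wm_mask | run.csf_mask
        for k in range(decomp.n_components):
            noisy = False
            if fd is not None and np.std(fd) > 0:
                tc = decomp.timecourses[:, k]
                c = np.corrcoef(tc, fd)[0, 1]
                noisy |= abs(c) > fd_corr_threshold
            if outside.any():
                # Project the component map onto WM/CSF voxel series to
                # estimate how much of its energy lives outside the brain.
                tc = decomp.timecourses[:, k]
                tc_n = (tc - tc.mean()) / (tc.std() + 1e-30)
                out_ts = run.data[outside]  # (n_out_vox, t)
                out_ts = out_ts - out_ts.mean(axis=1, keepdims=True)
                denom = np.sqrt((out_ts**2).sum(axis=1)) * np.sqrt(len(tc_n))
                denom[denom == 0] = 1.0
                corr_out = (out_ts @ tc_n) / denom
                noisy |= float(np.mean(np.abs(corr_out))) > outside_weight_threshold
            if noisy:
                labels[k] = "noise"
    return IcaDecomposition(
        maps=decomp.maps,
        timecourses=decomp.timecourses,
        mask=decomp.mask,
        labels=labels,
    )


def _ols_residual(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residualize columns of Y against the column span of X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def nuisance_regress(run: BoldRun, decomp: IcaDecomposition | None = None) -> BoldRun:
    """Two-stage voxelwise cleaning on the retained volumes.

    Stage 1 removes, by ordinary least squares, an intercept, the WM and
    CSF mean timecourses, and the six motion parameters.  Stage 2 ("soft
    regression") removes only the *unique* parts of the noise-IC
    timecourses: each noise timecourse is orthogonalized against the span
    of all signal-IC timecourses, and the residualized regressors are then
    regressed out.  Variance shared between noise and signal components is
    therefore retained.
    """
    if not run.scrubbed:
        raise ValueError("apply the scrub mask before nuisance regression")
    t = run.n_volumes
    cols = [np.ones(t)]
    names = ["intercept"]
    if run.wm_mask.any():
        cols.append(run.data[run.wm_mask].mean(axis=0))
        names.append("wm_mean")
    if run.csf_mask.any():
        cols.append(run.data[run.csf_mask].mean(axis=0))
        names.append("csf_mean")
    if run.motion is not None:
        for j in range(6):
            cols.append(run.motion.params[:, j])
            names.append(f"motion_{j}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient nuisance design; collinear regressors among: "
            + ", ".join(names)
        )

    work = run.brain_mask | run.wm_mask | run.csf_mask
    Y = run.data[work].T  # (t, n_voxels)
    Y = _ols_residual(Y, X)

    if decomp is not None:
        if decomp.labels is None:
            raise ValueError("ICA components must be labeled before regression")
        noise_idx = decomp.noise_indices()
        if noise_idx.size:
            signal_idx = np.flatnonzero(decomp.labels == "signal")
            N = decomp.timecourses[:, noise_idx]
            if signal_idx.size:
                S = decomp.timecourses[:, signal_idx]
                unique = _ols_residual(N, np.column_stack([np.ones(t), S]))
            else:
                unique = N - N.mean(axis=0)
            # Drop numerically-zero unique parts (noise fully shared with
            # signal components removes nothing, by design).
            norms = np.linalg.norm(unique, axis=0)
            keep = norms > 1e-10 * max(1.0, np.linalg.norm(N))
            if keep.any():
                Y = _ols_residual(Y, unique[:, keep])

    data = run.data.copy()
    data[work] = Y.T
    return replace(run, data=data)


def smooth_and_filter(
    run: BoldRun,
    fwhm_mm: float = 1.0,
    voxel_size_mm: float = 0.5,
    band_hz: tuple[float, float] = (0.01, 0.1),
    filter_order: int = 4,
) -> BoldRun:
    """Gaussian spatial smoothing within the brain mask, then a zero-phase
    Butterworth bandpass along time.

    Smoothing is mask-renormalized (the kernel is re-weighted by the
    smoothed mask) so constant images remain constant inside the mask and
    no out-of-mask zeros bleed in.  The bandpass is an order-``filter_order``
    Butterworth applied forward and backward.
    """
    lo, hi = band_hz
    nyquist = 0.5 / run.tr_seconds
    if hi >= nyquist:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist {nyquist} Hz")
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")

    data = run.data.astype(float, copy=True)
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
        mask = run.brain_mask.astype(float)
        sm_mask = ndimage.gaussian_filter(mask, sigma=sigma_vox)
        inside = run.brain_mask
        for ti in range(data.shape[3]):
            vol = data[..., ti] * mask
            sm = ndimage.gaussian_filter(vol, sigma=sigma_vox)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = sm / sm_mask
            data[..., ti][inside] = out[inside]

    sos = signal.butter(
        filter_order, [lo, hi], btype="bandpass", fs=1.0 / run.tr_seconds,
        output="sos",
    )
    work = run.brain_mask | run.wm_mask | run.csf_mask
    series = data[work]
    data[work] = signal.sosfiltfilt(sos, series, axis=1)
    return replace(run, data=data)


def preprocess_run(
    run: BoldRun,
    fd_threshold_mm: float = 0.2,
    n_discard: int = 10,
    max_removed_fraction: float = 0.15,
    n_ica_components: int | None = 50,
    ic_labels_file: str | None = None,
    fwhm_mm: float = 1.0,
    voxel_size_mm: float = 0.5,
    band_hz: tuple[float, float] = (0.01, 0.1),
    seed: int = 0,
) -> tuple[BoldRun, ScrubMask]:
    """Full scan-level chain; returns the cleaned run and its scrub mask.

    Raises ``RuntimeError`` if the scan fails the removed-fraction rule.
    Set ``n_ica_components`` to ``None`` to skip ICA cleaning.
    """
    if run.motion is None:
        raise ValueError("motion parameters are required for scrubbing")
    mask = scrub(
        run.motion,
        fd_threshold_mm=fd_threshold_mm,
        n_discard=n_discard,
        max_removed_fraction=max_removed_fraction,
    )
    if mask.rejected:
        raise RuntimeError(
            f"scan rejected: {mask.removed_fraction:.1%} of volumes removed"
        )
    run = apply_scrub(run, mask)
    decomp = None
    if n_ica_components is not None:
        decomp = ica_decompose(run, n_components=n_ica_components, seed=seed)
        decomp = label_components(decomp, labels_file=ic_labels_file, run=run)
    run = nuisance_regress(run, decomp)
    run = smooth_and_filter(
        run, fwhm_mm=fwhm_mm, voxel_size_mm=voxel_size_mm, band_hz=band_hz
    )
    return run, mask
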