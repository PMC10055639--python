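"""Statistical primitives shared across the pipeline.

The group contrast used throughout (edgewise connectivity, global graph
metrics, nodal degree) is a linear mixed model with the group indicator as
the fixed effect and the animal as a random intercept, fitted by restricted
maximum likelihood (REML).  Because the model has a single random intercept
and a single grouping factor, the REML criterion can be profiled down to a
one-dimensional search over the variance ratio, which makes the thousands of
per-edge fits cheap.  Equivalence with a general-purpose mixed-model fitter
is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats as sstats

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "bh_fdr",
    "MixedTestResult",
    "mixed_model_ttest",
]


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing arctanh transform of correlation coefficients."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z transform undefined at |r| >= 1")
    return np.arctanh(r)


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    """Map Fisher z values back to correlations (tanh)."""
    return np.tanh(np.asarray(z, dtype=float))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Monotonicity is enforced by the cumulative minimum over the sorted
    sequence, so ``q >= p`` elementwise and q is nondecreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class MixedTestResult:
    """Fixed-effect contrast from the random-intercept model.

    Attributes
    ----------
    estimate : float
        Fixed-effect coefficient (second-group mean minus first-group mean).
    t, df, p : float
        Wald t statistic, its degrees of freedom, and the two-sided p-value.
    sigma_subject, sigma_resid : float
        REML estimates of the random-intercept and residual standard
        deviations.
    """

    __slots__ = ("estimate", "t", "df", "p", "sigma_subject", "sigma_resid")

    def __init__(self, estimate, t, df, p, sigma_subject, sigma_resid):
        self.estimate = float(estimate)
        self.t = float(t)
        self.df = float(df)
        self.p = float(p)
        self.sigma_subject = float(sigma_subject)
        self.sigma_resid = float(sigma_resid)

    def __repr__(self):  # pragma: no cover - debugging aid
        return (
            f"MixedTestResult(estimate={self.estimate:.4g}, t={self.t:.4g}, "
            f"df={self.df:.4g}, p={self.p:.4g})"
        )


def _neg2_reml(log_lam, y, X, starts, counts, n, p_dim):
    """Profiled -2 REML log-likelihood at variance ratio lam = sb^2/se^2."""
    lam = np.exp(log_lam)
    # V^-1 = I - (lam / (1 + lam*m_g)) J_g blockwise; apply via group sums.
    shrink = lam / (1.0 + lam * counts)  # per group
    XtViX, XtViy, ytViy = _gls_crossprods(y, X, starts, counts, shrink)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - XtViy @ beta
    sigma2 = rss / (n - p_dim)
    if not np.isfinite(sigma2) or sigma2 <= 0.0:
        # Perfect fit (zero residual): every lam is equivalent; report a
        # flat, finite objective so the optimizer terminates quietly.
        return 0.0
    logdetV = np.sum(np.log1p(lam * counts))
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    return (n - p_dim) * np.log(sigma2) + logdetV + logdetXtViX


def _gls_crossprods(y, X, starts, counts, shrink):
    """Cross-products X'V^-1 X, X'V^-1 y, y'V^-1 y for block-equicorrelated V."""
    # Group sums of X columns and of y (observations are ordered by group).
    cuts = np.concatenate([starts, [len(y)]])
    Xg = np.add.reduceat(X, starts, axis=0)
    yg = np.add.reduceat(y, starts)
    w = shrink  # length n_groups
    XtViX = X.T @ X - (Xg * w[:, None]).T @ Xg
    XtViy = X.T @ y - (Xg * w[:, None]).T @ yg
    ytViy = y @ y - np.sum(w * yg * yg)
    del cuts
    return XtViX, XtViy, ytViy


def mixed_model_ttest(
    y: np.ndarray,
    group: np.ndarray,
    subject: np.ndarray,
    lam_tol: float = 1e-6,
) -> MixedTestResult:
    """Two-group contrast with a per-subject random intercept (REML).

    Parameters
    ----------
    y : observations (e.g. one edge's Fisher-z value per scan).
    group : binary or two-level labels; the contrast is level2 - level1
        (levels in sorted order).
    subject : subject (rat) identifier per observation; each subject must
        belong to a single group.
    lam_tol : variance-ratio threshold below which the random effect is
        treated as absent and the test collapses to ordinary least squares.

    Degrees of freedom use the between-within rule: the group effect varies
    between subjects, so df = n_subjects - 2, which coincides with the
    Satterthwaite value in balanced designs.  With one observation per
    subject the result equals the classical pooled two-sample t-test.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    subject = np.asarray(subject)
    if y.ndim != 1 or y.shape != group.shape or y.shape != subject.shape:
        raise ValueError("y, group and subject must be 1-D and equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels.size}")
    g01 = (group == levels[1]).astype(float)

    # Subjects must nest within groups (a rat has one sex).
    subj_ids, subj_idx = np.unique(subject, return_inverse=True)
    for s in range(subj_ids.size):
        if np.unique(g01[subj_idx == s]).size > 1:
            raise ValueError(f"subject {subj_ids[s]!r} appears in both groups")
    n_subjects = subj_ids.size
    if n_subjects < 4:
        raise ValueError("need at least 2 subjects per group")

    if np.ptp(y) == 0.0:
        # Constant response: the group difference is exactly zero with no
        # residual variance, so the t-statistic is undefined.
        return MixedTestResult(
            estimate=0.0, t=np.nan, df=np.nan, p=np.nan,
            sigma_subject=0.0, sigma_resid=0.0,
        )

    # Order observations by subject so V^-1 acts blockwise.
    order = np.argsort(subj_idx, kind="stable")
    y_o = y[order]
    g_o = g01[order]
    so = subj_idx[order]
    starts = np.searchsorted(so, np.arange(n_subjects))
    counts = np.diff(np.concatenate([starts, [len(so)]])).astype(float)

    n = y_o.size
    X = np.column_stack([np.ones(n), g_o])
    p_dim = 2

    res = optimize.minimize_scalar(
        _neg2_reml,
        bounds=(np.log(1e-9), np.log(1e7)),
        args=(y_o, X, starts, counts, n, p_dim),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    # Collapse to OLS when the boundary solution says "no subject variance".
    at_zero = lam < lam_tol or _neg2_reml(
        np.log(1e-12), y_o, X, starts, counts, n, p_dim
    ) <= res.fun + 1e-9
    if at_zero:
        lam = 0.0
    shrink = lam / (1.0 + lam * counts)
    XtViX, XtViy, ytViy = _gls_crossprods(y_o, X, starts, counts, shrink)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - XtViy @ beta
    sigma2 = rss / (n - p_dim)
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(cov[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    df = (n - 2) if lam == 0.0 else (n_subjects - 2)
    p = 2.0 * sstats.t.sf(abs(t), df)
    return MixedTestResult(
        estimate=beta[1],
        t=t,
        df=df,
        p=p,
        sigma_subject=np.sqrt(lam * sigma2),
        sigma_resid=np.sqrt(sigma2),
    )
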