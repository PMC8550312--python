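"""Rank-APE breakpoint analysis and the labeling detection threshold.

The rank-vs-APE curve of a qSIP run is flat at low ranks (unlabeled taxa,
estimates scattered around zero) and rises once genuinely labeled taxa
begin: a single-breakpoint segmented linear model

    y = beta0 + beta1 * x + beta2 * (x - psi)_+

is fitted to the lowest ``rank_hi`` ranks (default 90).  The breakpoint
``psi`` is estimated by Muggeo-style iterative linearization with a
grid-search fallback; the existence of a slope change is tested with the
Davies bound for a nuisance parameter present only under the alternative.
The detection threshold is the upper 99.7% confidence limit of the
breakpoint (psi + 3 SE), converted to an APE cutoff by linear
interpolation of the sorted APE sequence; taxa above the cutoff are
flagged as having detectably incorporated the tracer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger("gqsip")

__all__ = [
    "BreakpointFit",
    "fit_segmented",
    "davies_test",
    "restrict_window",
    "ape_cutoff",
]

_BETA2_ZERO = 1e-10
_GAMMA_TOL = 1e-8
_MAX_ITER = 50
_GRID_STEP = 0.1


@dataclass
class BreakpointFit:
    """Result of a single-breakpoint segmented regression."""

    psi: float  # breakpoint location (rank units)
    psi_se: float  # standard error of psi
    beta0: float  # intercept
    beta1: float  # left-segment slope
    beta2: float  # slope change at psi
    rss: float  # residual sum of squares at the fit
    window: tuple[float, float]  # (rank_lo, rank_hi) fitted
    converged: bool
    no_breakpoint: bool  # |beta2| below numerical zero
    method: str  # "iterative" or "grid"
    n_iter: int
    davies_p: float = float("nan")
    m: float = float("nan")  # SE multiplier used for the threshold
    threshold_rank: float = float("nan")  # psi + m * psi_se
    ape_cutoff: float = float("nan")  # APE (percent) at threshold_rank


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with coefficient covariance (pinv handles collinearity)."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = len(y) - X.shape[1]
    sigma2 = rss / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, rss, cov


def _hinge_design(x: np.ndarray, psi: float) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])


def _rss_at(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    _, rss, _ = _ols(_hinge_design(x, psi), y)
    return rss


def _rss_profile(x: np.ndarray, y: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """RSS of the hinge fit at every candidate psi, vectorized.

    All normal-equation moments involving U = (x - psi)_+ are polynomials in
    psi given suffix sums of the sorted x, so the 3x3 systems for every
    candidate are assembled and solved in one shot.
    """
    n = float(len(x))
    sx, sx2 = x.sum(), (x * x).sum()
    sy, sxy, syy = y.sum(), (x * y).sum(), (y * y).sum()
    # suffix sums over points with x > psi
    cx = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
    cx2 = np.concatenate([np.cumsum((x * x)[::-1])[::-1], [0.0]])
    cy = np.concatenate([np.cumsum(y[::-1])[::-1], [0.0]])
    cxy = np.concatenate([np.cumsum((x * y)[::-1])[::-1], [0.0]])
    cn = np.concatenate([np.arange(len(x), 0, -1, dtype=float), [0.0]])
    k = np.searchsorted(x, psis, side="right")
    np_, sxp, sx2p, syp, sxyp = cn[k], cx[k], cx2[k], cy[k], cxy[k]

    su = sxp - psis * np_
    sxu = sx2p - psis * sxp
    su2 = sx2p - 2 * psis * sxp + psis**2 * np_
    suy = sxyp - psis * syp

    m = len(psis)
    A = np.empty((m, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = sx
    A[:, 0, 2] = A[:, 2, 0] = su
    A[:, 1, 1] = sx2
    A[:, 1, 2] = A[:, 2, 1] = sxu
    A[:, 2, 2] = su2
    b = np.empty((m, 3))
    b[:, 0] = sy
    b[:, 1] = sxy
    b[:, 2] = suy
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    rss = syy - np.einsum("ij,ij->i", coef, b)
    return np.maximum(rss, 0.0)


def _grid_search(x: np.ndarray, y: np.ndarray, step: float = _GRID_STEP) -> float:
    """Exhaustive RSS minimization over interior psi; ties -> smallest psi."""
    lo, hi = x[0] + step, x[-1] - step
    psis = np.arange(lo, hi + step / 2, step)
    rss = _rss_profile(x, y, psis)
    return float(psis[int(np.argmin(rss))])  # argmin takes first == smallest psi


def _working_fit(x: np.ndarray, y: np.ndarray, psi: float):
    """One linearization step at fixed psi: adds V = -1{x > psi}."""
    U = np.clip(x - psi, 0.0, None)
    V = -(x > psi).astype(float)
    X = np.column_stack([np.ones_like(x), x, U, V])
    coef, rss, cov = _ols(X, y)
    se_gamma = float(np.sqrt(max(cov[3, 3], 0.0)))
    return coef, rss, se_gamma


def _iterate(x: np.ndarray, y: np.ndarray, psi: float):
    """Damped Muggeo iteration from a starting psi.

    The raw update psi <- psi + gamma/beta2 can oscillate around the
    optimum when the RSS surface is kinked; the step is shrunk whenever
    |gamma| fails to contract.
    """
    damp, prev_gamma = 1.0, None
    for n_iter in range(1, _MAX_ITER + 1):
        coef, _, _ = _working_fit(x, y, psi)
        b2, gamma = float(coef[2]), float(coef[3])
        if abs(b2) < _BETA2_ZERO:  # flat slope change: no-breakpoint case
            return psi, True, n_iter
        if abs(gamma) < _GAMMA_TOL:
            return psi, True, n_iter
        if prev_gamma is not None and abs(gamma) >= 0.9 * abs(prev_gamma):
            damp *= 0.6
        step = damp * gamma / b2
        psi_new = psi + step
        if not np.isfinite(psi_new) or not (x[0] < psi_new < x[-1]):
            return psi, False, n_iter
        psi, prev_gamma = psi_new, gamma
    return psi, False, _MAX_ITER


def _validate_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 8:
        raise ValueError("segmented fit needs at least 8 points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    return x, y


def fit_segmented(x, y, psi0: float | None = None) -> BreakpointFit:
    """Fit y = b0 + b1*x + b2*(x - psi)_+ with a standard error on psi.

    Iterative linearization (Muggeo): at the current psi, regress on
    [1, x, (x-psi)_+, -1{x>psi}] and update psi <- psi + gamma_hat/b2_hat
    until |gamma_hat| < 1e-8 (50 iterations max).  If iterations leave the
    data range or fail to converge, fall back to exhaustive RSS grid search
    at 0.1-rank resolution (ties -> smallest psi, the most conservative
    threshold).  psi_se = SE(gamma_hat) / |b2_hat| at the solution.
    """
    x, y = _validate_xy(x, y)
    psi_start = float(np.median(x)) if psi0 is None else float(psi0)
    psi_start = min(max(psi_start, x[1]), x[-2])

    # iterative solution, cross-checked against the exhaustive grid: the
    # linearization can converge to a local RSS minimum, so the grid (plus a
    # polish iteration from the best grid point) guards the global optimum
    psi_it, conv_it, n_iter = _iterate(x, y, psi_start)
    psi_grid = _grid_search(x, y)
    psi_gp, conv_gp, extra = _iterate(x, y, psi_grid)
    if conv_gp and _rss_at(x, y, psi_gp) <= _rss_at(x, y, psi_grid) + 1e-12:
        psi_grid = psi_gp
    if conv_it and _rss_at(x, y, psi_it) <= _rss_at(x, y, psi_grid) * (1 + 1e-9) + 1e-12:
        psi, method = psi_it, "iterative"
    else:
        psi, method, n_iter = psi_grid, "grid", n_iter + extra
        log.info("fit_segmented: grid fallback psi=%.3f", psi)

    coef4, _, se_gamma = _working_fit(x, y, psi)
    coef3, rss, _ = _ols(_hinge_design(x, psi), y)
    beta0, beta1, beta2 = (float(c) for c in coef3)
    no_breakpoint = abs(beta2) < _BETA2_ZERO
    psi_se = float("nan") if no_breakpoint else se_gamma / abs(float(coef4[2]))

    n_left = int((x < psi).sum())
    n_right = int((x > psi).sum())
    if min(n_left, n_right) < 3 and not no_breakpoint:
        warnings.warn(
            f"fit_segmented: breakpoint near the boundary "
            f"({n_left} points left, {n_right} right of psi={psi:.2f})",
            stacklevel=2,
        )

    return BreakpointFit(
        psi=float(psi),
        psi_se=psi_se,
        beta0=beta0,
        beta1=beta1,
        beta2=beta2,
        rss=rss,
        window=(float(x[0]), float(x[-1])),
        converged=True,  # grid guard guarantees a solution
        no_breakpoint=no_breakpoint,
        method=method,
        n_iter=n_iter,
    )


def davies_test(x, y, K: int = 10, margin: float = 2.0) -> float:
    """Davies (1987) upper bound on the p-value for a slope change.

    Evaluates the Wald statistic s_k for beta2 at K equally spaced interior
    candidate breakpoints and bounds the null probability of the observed
    maximum M with p = Phi(-M) + V * exp(-M^2/2) / sqrt(8*pi), where V is
    the total variation sum |s_{k+1} - s_k|.  Conservative; capped at 1.
    """
    x, y = _validate_xy(x, y)
    if K < 5:
        raise ValueError("davies_test: K must be >= 5")
    if np.var(y) == 0.0:
        return 1.0
    cands = np.linspace(x[0] + margin, x[-1] - margin, K)
    stats = np.empty(K)
    for i, psi in enumerate(cands):
        coef, _, cov = _ols(_hinge_design(x, psi), y)
        se = np.sqrt(max(cov[2, 2], 0.0))
        if se == 0.0 or not np.isfinite(se):
            # perfect fit at this candidate: infinitely strong evidence
            stats[i] = np.inf if coef[2] != 0 else 0.0
        else:
            stats[i] = coef[2] / se
    M = float(np.max(stats))
    if not np.isfinite(M):
        return 0.0
    total_var = float(np.sum(np.abs(np.diff(stats[np.isfinite(stats)]))))
    p = norm.sf(M) + total_var * np.exp(-(M**2) / 2.0) / np.sqrt(8.0 * np.pi)
    return float(min(max(p, 0.0), 1.0))


def restrict_window(enrichment: pd.DataFrame, rank_hi: int = 90):
    """Ranks 1..min(n, rank_hi) and their APEs, for the breakpoint fit.

    The fit is restricted to the lowest-APE populations: including highly
    enriched ranks, where the rank-APE slope declines again, skews the
    breakpoint estimate toward zero APE.
    """
    if rank_hi < 1:
        raise ValueError("restrict_window: rank_hi must be >= 1")
    n = len(enrichment)
    if n < rank_hi:
        warnings.warn(
            f"restrict_window: only {n} taxa available (< rank_hi={rank_hi})",
            stacklevel=2,
        )
        rank_hi = n
    sub = enrichment.sort_values("rank").iloc[:rank_hi]
    return sub["rank"].to_numpy(dtype=float), sub["APE_percent"].to_numpy(dtype=float)


def ape_cutoff(
    enrichment: pd.DataFrame, fit: BreakpointFit, m: float = 3.0
) -> tuple[BreakpointFit, pd.DataFrame]:
    """Convert the breakpoint into an APE labeling cutoff and flag taxa.

    threshold_rank = psi + m * psi_se (m = 3 gives the upper 99.7%
    confidence limit of the breakpoint); the APE cutoff is the linear
    interpolation of the rank-sorted APE sequence at that fractional rank.
    Taxa with APE strictly above the cutoff are flagged labeled.
    """
    if fit.no_breakpoint:
        raise ValueError("ape_cutoff: fit flagged no-breakpoint")
    if not fit.converged:
        raise ValueError("ape_cutoff: fit did not converge")
    threshold_rank = fit.psi + m * (0.0 if m == 0 else fit.psi_se)
    out = enrichment.sort_values("rank", ignore_index=True)
    ranks = out["rank"].to_numpy(dtype=float)
    apes = out["APE_percent"].to_numpy(dtype=float)
    if threshold_rank > ranks[-1]:
        warnings.warn(
            f"ape_cutoff: threshold rank {threshold_rank:.2f} beyond max rank "
            f"{ranks[-1]:.0f}; no taxon is flagged labeled",
            stacklevel=2,
        )
    cutoff = float(np.interp(threshold_rank, ranks, apes))
    out["labeled"] = out["APE_percent"] > cutoff
    fit = replace(fit, m=float(m), threshold_rank=float(threshold_rank), ape_cutoff=cutoff)
    return fit, out
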