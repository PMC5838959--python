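"""TSS-relative motif-density enrichment with loess confidence bands.

Hit offsets from foreground promoter windows and a 10x random background
are binned on a common TSS-relative grid, smoothed by degree-2 local
regression with pointwise 95% t-intervals, and two enrichment windows are
called: a *robust* window where the foreground lower band clears the
background upper band, and a *permissive* window bounded by the nearest
sign changes of the fitted difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist


@dataclass
class PositionalDensityResult:
    grid: np.ndarray            # bin centers, bp relative to TSS
    fg_density: np.ndarray      # hits per window per bp
    bg_density: np.ndarray
    fg_fit: np.ndarray
    fg_lo: np.ndarray
    fg_hi: np.ndarray
    bg_fit: np.ndarray
    bg_lo: np.ndarray
    bg_hi: np.ndarray
    robust_window: tuple[float, float] | None
    permissive_window: tuple[float, float] | None
    permissive_at_edge: bool = False


def binned_density(
    offsets: np.ndarray,
    n_windows: int,
    bin_bp: int = 50,
    span: tuple[int, int] = (-5000, 2000),
) -> tuple[np.ndarray, np.ndarray]:
    """Bin hit offsets into per-window per-bp densities on ``span``.

    ``density[k] = (#hits in bin k) / (n_windows * bin_bp)``.  Returns
    (bin centers, density).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    lo, hi = span
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    counts, _ = np.histogram(np.asarray(offsets), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / (n_windows * bin_bp)


def loess_ci(
    grid: np.ndarray,
    density: np.ndarray,
    span_frac: float = 0.75,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Degree-2 local regression with tricube weights and pointwise
    t-intervals.

    At each grid point the nearest ``ceil(span_frac * n)`` points are fit
    by weighted least squares on a local quadratic; the interval is
    ``fit +/- t_{1-(1-level)/2, nu} * SE`` with ``nu = n_local - 3`` and SE
    from the local linear-smoother variance with the weighted residual
    variance estimate.
    """
    x = np.asarray(grid, dtype=float)
    y = np.asarray(density, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 grid points")
    k = int(np.ceil(span_frac * n))
    k = min(max(k, 4), n)
    alpha = 1.0 - level

    fit = np.empty(n)
    lo = np.empty(n)
    hi = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        order = np.argsort(d, kind="stable")
        local = order[:k]
        dmax = d[local].max()
        if dmax == 0:
            raise ValueError("singular local design: all x identical")
        w = (1 - (d[local] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        pos = w > 0
        local, w = local[pos], w[pos]
        xl = x[local] - x[i]
        X = np.column_stack([np.ones_like(xl), xl, xl * xl])
        WX = X * w[:, None]
        XtWX = X.T @ WX
        try:
            beta_mat = np.linalg.solve(XtWX, WX.T)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular local design") from exc
        l_vec = beta_mat[0]  # fit = l . y_local
        yl = y[local]
        fit[i] = float(l_vec @ yl)
        resid = yl - X @ (beta_mat @ yl)
        nu = len(local) - 3
        if nu <= 0:
            sigma2 = 0.0
        else:
            sigma2 = float((w * resid * resid).sum() / w.sum()) \
                * len(local) / nu
        se = np.sqrt(sigma2 * float((l_vec * l_vec).sum()))
        tq = t_dist.ppf(1 - alpha / 2, max(nu, 1))
        lo[i] = fit[i] - tq * se
        hi[i] = fit[i] + tq * se
    return fit, lo, hi


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive index pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def call_windows(
    grid: np.ndarray,
    fg_fit: np.ndarray, fg_lo: np.ndarray, fg_hi: np.ndarray,
    bg_fit: np.ndarray, bg_lo: np.ndarray, bg_hi: np.ndarray,
    min_run_bins: int = 2,
) -> tuple[tuple[float, float] | None, tuple[float, float] | None, bool]:
    """Call the robust and permissive enrichment windows.

    Robust: longest contiguous run (>= ``min_run_bins`` bins) where the
    foreground lower band exceeds the background upper band — enrichment
    direction only, depletion never qualifies.  Permissive: the contiguous
    interval containing the robust window, bounded on each side by the last
    grid point where ``fg_fit - bg_fit`` is still positive before a sign
    change (or the span edge).  Both are None when no robust run exists.
    Returns (robust, permissive, permissive_at_edge).
    """
    sep = fg_lo > bg_hi
    runs = [r for r in _runs(sep) if r[1] - r[0] + 1 >= min_run_bins]
    if not runs:
        return None, None, False
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    robust = (float(grid[start]), float(grid[end]))

    diff = fg_fit - bg_fit
    left = start
    while left > 0 and diff[left - 1] > 0:
        left -= 1
    right = end
    while right < len(grid) - 1 and diff[right + 1] > 0:
        right += 1
    at_edge = left == 0 or right == len(grid) - 1
    permissive = (float(grid[left]), float(grid[right]))
    return robust, permissive, at_edge


def positional_density(
    fg_offsets: np.ndarray,
    n_fg: int,
    bg_offsets: np.ndarray,
    n_bg: int,
    bin_bp: int = 50,
    span: tuple[int, int] = (-5000, 2000),
    span_frac: float = 0.75,
    level: float = 0.95,
    min_run_bins: int = 2,
) -> PositionalDensityResult:
    """Full positional-enrichment analysis on a common grid."""
    grid, fg_density = binned_density(fg_offsets, n_fg, bin_bp, span)
    _, bg_density = binned_density(bg_offsets, n_bg, bin_bp, span)
    fg_fit, fg_lo, fg_hi = loess_ci(grid, fg_density, span_frac, level)
    bg_fit, bg_lo, bg_hi = loess_ci(grid, bg_density, span_frac, level)
    robust, permissive, at_edge = call_windows(
        grid, fg_fit, fg_lo, fg_hi, bg_fit, bg_lo, bg_hi, min_run_bins
    )
    return PositionalDensityResult(
        grid, fg_density, bg_density, fg_fit, fg_lo, fg_hi,
        bg_fit, bg_lo, bg_hi, robust, permissive, at_edge,
    )


def sample_background_tss(
    pool_ids: list[str],
    fg_ids: list[str],
    fold: int = 10,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Uniform without-replacement sample of ``fold * len(fg_ids)`` TSS ids
    from the pool, excluding the foreground; deterministic under a seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fg = set(fg_ids)
    eligible = [p for p in pool_ids if p not in fg]
    n = fold * len(fg_ids)
    if len(eligible) < n:
        raise ValueError(
            f"background pool too small: need {n}, have {len(eligible)}"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]
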