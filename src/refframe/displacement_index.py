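"""Cross-covariance displacement index (DI) between tuning curves measured at
different static eye positions, with bootstrap confidence intervals and the
four-way reference-frame classification.

DI for a curve pair is the circular lag (searched in integer degrees over
[-180, 180] on 1-degree linearly interpolated curves) that maximizes the
covariance between the mean-subtracted curves, divided by the eye-position
displacement. The sign convention is such that a tuning shift equal to the
gaze displacement yields DI = +1 (eye-centered) and no shift yields DI = 0
(head-centered). Shifting is circular (wrap-around); this choice is recorded
in output metadata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import TuningCurve, tuning_significance

__all__ = [
    "DIResult",
    "FlatCurveError",
    "InsufficientTuningError",
    "interpolate_circular",
    "pairwise_di",
    "neuron_di",
    "bootstrap_ci",
    "classify_frame",
    "di_by_eccentricity",
]

SHIFT_METADATA = {"lag_search": "circular", "lag_range_deg": [-180, 180]}


class FlatCurveError(ValueError):
    """A tuning curve has zero variance; the DI lag is undefined."""


class InsufficientTuningError(ValueError):
    """Fewer than two significantly tuned curves; neuron excluded."""


def _interp_matrix(
    headings_deg: np.ndarray,
    resolution_deg: float = 1.0,
    period_deg: float = 360.0,
    origin_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse-in-spirit weight matrix W mapping sampled values to a dense
    circular grid: dense = W @ values. Linear interpolation with wrap-around
    at the stated period (360 for full curves, 180 for half-range curves)."""
    h = np.asarray(headings_deg, dtype=float) - origin_deg
    order = np.argsort(h)
    h = h[order]
    n = len(h)
    if n < 3:
        raise ValueError("need at least 3 distinct headings to interpolate")
    grid = np.arange(0.0, period_deg, resolution_deg)
    # extended knots covering the wrap
    knots = np.concatenate([h, [h[0] + period_deg]])
    g = grid.copy()
    g[g < h[0]] += period_deg
    seg = np.clip(np.searchsorted(knots, g, side="right") - 1, 0, n - 1)
    left = knots[seg]
    right = knots[seg + 1]
    frac = (g - left) / (right - left)
    W = np.zeros((len(grid), n))
    rows = np.arange(len(grid))
    W[rows, seg] = 1.0 - frac
    W[rows, (seg + 1) % n] = frac
    return W, order


def interpolate_circular(
    curve: TuningCurve, resolution_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of the mean curve on the circle.

    Returns (grid_deg, values); original sample points are reproduced exactly.
    """
    h = np.asarray(curve.headings_deg, dtype=float)
    if len(np.unique(h)) != len(h):
        raise ValueError("duplicate headings in tuning curve")
    W, order = _interp_matrix(h, resolution_deg)
    dense = W @ np.asarray(curve.mean_rate_hz, dtype=float)[order]
    return np.arange(0.0, 360.0, resolution_deg), dense


def _best_lag(dense_i: np.ndarray, dense_j: np.ndarray) -> int:
    """Integer lag k in [-180, 180] maximizing cov[R_i(theta), R_j(theta + k)].

    Ties (within numerical tolerance) break to the smallest |k|, then the
    negative lag — deterministic and conservative toward no shift.
    """
    a = dense_i - dense_i.mean()
    b = dense_j - dense_j.mean()
    if np.allclose(a, 0.0) or np.allclose(b, 0.0):
        raise FlatCurveError("flat tuning curve: DI lag undefined")
    # circular cross-correlation: c[k] = sum_theta a[theta] * b[theta + k]
    c = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=len(a))
    lags = np.arange(len(c))
    lags = np.where(lags > 180, lags - 360, lags)
    tol = 1e-9 * max(1.0, float(np.abs(c).max()))
    cand = np.flatnonzero(c >= c.max() - tol)
    best = min(cand, key=lambda i: (abs(int(lags[i])), int(lags[i]) > 0))
    return int(lags[best])


def pairwise_di(
    curve_i: TuningCurve,
    curve_j: TuningCurve,
    p_i: float | None = None,
    p_j: float | None = None,
) -> tuple[float, int]:
    """DI for one pair of tuning curves at eye positions ``p_i`` != ``p_j``.

    Returns (di, k_star) where k_star is the optimal lag in degrees. A curve
    shift equal to the gaze displacement gives di = +1.
    """
    p_i = curve_i.eye_pos_deg if p_i is None else p_i
    p_j = curve_j.eye_pos_deg if p_j is None else p_j
    if p_i == p_j:
        raise ValueError("eye positions must differ")
    _, di_dense = interpolate_circular(curve_i)
    _, dj_dense = interpolate_circular(curve_j)
    k_star = _best_lag(di_dense, dj_dense)
    return k_star / (p_j - p_i), k_star


@dataclass
class DIResult:
    """Displacement index for one neuron/modality."""

    di: float
    pair_dis: list[tuple[float, float, float]]  # (P_i, P_j, di_ij)
    n_pairs: int
    ci95: tuple[float, float] | None = None
    category: str | None = None
    boot_reps: int = 0
    seed: int | None = None
    metadata: dict = field(default_factory=lambda: dict(SHIFT_METADATA))


def _significant_pairs(
    curves: dict[float, TuningCurve], alpha: float
) -> list[tuple[float, float]]:
    sig = [e for e, c in sorted(curves.items()) if tuning_significance(c) < alpha]
    if len(sig) < 2:
        raise InsufficientTuningError(
            f"only {len(sig)} significantly tuned curve(s) (need >= 2)"
        )
    return list(itertools.combinations(sig, 2))


def neuron_di(
    curves: dict[float, TuningCurve],
    alpha: float = 0.05,
    pairs: list[tuple[float, float]] | None = None,
) -> DIResult:
    """Average DI over all pairs of significantly tuned curves.

    ``curves`` maps eye position (degrees) to its tuning curve. With all
    three curves significant, three pair DIs are averaged (unweighted).
    """
    if pairs is None:
        pairs = _significant_pairs(curves, alpha)
    pair_dis = []
    for p_i, p_j in pairs:
        di_ij, _ = pairwise_di(curves[p_i], curves[p_j], p_i, p_j)
        pair_dis.append((p_i, p_j, di_ij))
    di = float(np.mean([d for _, _, d in pair_dis]))
    return DIResult(di=di, pair_dis=pair_dis, n_pairs=len(pair_dis))


def bootstrap_ci(
    curves: dict[float, TuningCurve],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    pairs: list[tuple[float, float]] | None = None,
) -> tuple[tuple[float, float], np.ndarray, int]:
    """95% bootstrap CI of the neuron-level DI.

    Repetitions are resampled with replacement independently within each
    (eye position x heading) cell, tunings rebuilt, and the DI recomputed.
    Replicates whose resampled curves are flat are dropped (and counted);
    a warning is issued if more than 20% drop.

    Returns ((low, high), di_samples, n_dropped).
    """
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = _significant_pairs(curves, alpha)
    eyes = sorted({e for pair in pairs for e in pair})

    # vectorized resampling: per eye position, bootstrap per-heading means
    W = {}
    boot_means = {}
    for e in eyes:
        c = curves[e]
        W_e, order = _interp_matrix(c.headings_deg)
        W[e] = W_e
        means = np.empty((len(c.headings_deg), n_boot))
        for hi in order:
            vals = np.asarray(c.trials[hi], dtype=float)
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            means[hi] = vals[idx].mean(axis=1)
        boot_means[e] = means[order]  # rows sorted by heading

    dense = {e: W[e] @ boot_means[e] for e in eyes}  # (360, n_boot)
    centered = {e: d - d.mean(axis=0, keepdims=True) for e, d in dense.items()}
    flat = np.zeros(n_boot, dtype=bool)
    for e in eyes:
        flat |= np.all(np.abs(centered[e]) < 1e-12, axis=0)

    fft = {e: np.fft.rfft(centered[e], axis=0) for e in eyes}
    lags = np.arange(360)
    lags = np.where(lags > 180, lags - 360, lags)
    # candidate lags in tie-break priority: smallest |k|, negatives first
    order_idx = np.asarray(
        sorted(range(360), key=lambda i: (abs(int(lags[i])), int(lags[i]) > 0))
    )

    di_sum = np.zeros(n_boot)
    for p_i, p_j in pairs:
        c = np.fft.irfft(np.conj(fft[p_i]) * fft[p_j], n=360, axis=0)
        c_ord = c[order_idx]  # candidates in tie-break priority order
        tol = 1e-9 * np.maximum(1.0, np.abs(c).max(axis=0))
        is_max = c_ord >= (c.max(axis=0) - tol)
        first = np.argmax(is_max, axis=0)
        k_star = lags[order_idx[first]]
        di_sum += k_star / (p_j - p_i)
    di_samples = di_sum / len(pairs)
    di_samples = di_samples[~flat]
    n_dropped = int(flat.sum())
    if n_dropped > 0.2 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap replicates dropped (flat curves)",
            stacklevel=2,
        )
    if len(di_samples) == 0:
        raise FlatCurveError("all bootstrap replicates produced flat curves")
    lo, hi = np.percentile(di_samples, [2.5, 97.5])
    return (float(lo), float(hi)), di_samples, n_dropped



def classify_frame(di: float, ci95: tuple[float, float]) -> str:
    """Four-way reference-frame category from the bootstrap CI.

    head: CI includes 0 but not 1; eye: includes 1 but not 0; intermediate:
    CI strictly inside (0, 1); otherwise unclassified.
    """
    lo, hi = ci95
    if lo > hi:
        raise ValueError("CI low must not exceed high")
    has0 = lo <= 0.0 <= hi
    has1 = lo <= 1.0 <= hi
    if has0 and not has1:
        return "head"
    if has1 and not has0:
        return "eye"
    if lo > 0.0 and hi < 1.0:
        return "intermediate"
    return "unclassified"


def analyze_neuron(
    curves: dict[float, TuningCurve],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> DIResult:
    """Full DI analysis: point estimate, bootstrap CI, and category."""
    pairs = _significant_pairs(curves, alpha)
    result = neuron_di(curves, alpha=alpha, pairs=pairs)
    ci, samples, n_dropped = bootstrap_ci(
        curves, n_boot=n_boot, seed=seed, alpha=alpha, pairs=pairs
    )
    result.ci95 = ci
    result.boot_reps = len(samples)
    result.category = classify_frame(result.di, ci)
    result.metadata["boot_dropped"] = n_dropped
    return result


def di_by_eccentricity(
    curves: dict[float, TuningCurve], alpha: float = 0.05
) -> dict[float, float]:
    """DI per eccentricity magnitude using center-vs-eccentric curve pairs.

    ``curves`` maps eye positions drawn from {0, +-10, +-20, +-30} to tuning
    curves. For each eccentricity e the significant pairs among
    {(-e, 0), (0, +e)} are averaged; eccentricities with no valid pair are
    omitted.
    """
    if 0.0 not in curves:
        raise ValueError("central (0 deg) curve required")
    sig = {e for e, c in curves.items() if tuning_significance(c) < alpha}
    if 0.0 not in sig:
        raise InsufficientTuningError("central curve not significantly tuned")
    out: dict[float, float] = {}
    eccs = sorted({abs(e) for e in curves if e != 0.0})
    for ecc in eccs:
        dis = []
        for p in (-ecc, ecc):
            if p in sig:
                di_ij, _ = pairwise_di(curves[p], curves[0.0], p, 0.0)
                dis.append(di_ij)
        if dis:
            out[ecc] = float(np.mean(dis))
    return out
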