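"""Tuning-shift quantification under smooth pursuit via the 3-step
partial-shift procedure, converted to a pursuit displacement index (DI).

Steps: (1) linearly scale each pursuit curve's peak-to-trough modulation to
match the no-pursuit curve; (2) split each sampled curve into the [0, 180)
and [180, 360) half-ranges and linearly interpolate each half to 1-degree
resolution (periodic within the half, so circular shifting is well defined);
(3) within each half, circularly shift the no-pursuit half in 1-degree steps
to maximize its Pearson correlation with the pursuit half. Splitting before
interpolating keeps each half free of contamination from the other half's
samples across the boundary. The up-to-four signed half-shifts (2 pursuit
directions x 2 halves) are sign-aligned so that shifts consistent with
uncompensated resultant optic flow are positive, averaged, and divided by
the predicted full shift (default 30 degrees). DI = 0 thus means complete
eye-rotation compensation and DI = 1 a complete tuning shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import TuningCurve, tuning_significance
from .displacement_index import (
    FlatCurveError,
    _best_lag,
    _interp_matrix,
    interpolate_circular,
)

__all__ = [
    "PursuitDIResult",
    "scale_to_reference",
    "split_halves",
    "interpolate_half",
    "half_shift",
    "pursuit_di",
    "pursuit_di_xcov",
    "classify_pursuit",
]

DEFAULT_PREDICTED_SHIFT_DEG = 30.0

#: sign by which each (pursuit direction, half) shift is multiplied before
#: averaging, so an uncompensated neuron contributes +shift from every half.
#: Derived once from the generator's flank-shift convention (the two halves
#: move in opposite directions, mirrored between pursuit directions).
SIGN_ALIGNMENT = {
    ("leftward", "A"): +1,
    ("leftward", "B"): -1,
    ("rightward", "A"): -1,
    ("rightward", "B"): +1,
}


@dataclass
class PursuitDIResult:
    """Pursuit DI for one neuron."""

    di: float | None
    half_shifts_deg: dict[tuple[str, str], int]  # (direction, half) -> signed deg
    scale_factors: dict[str, float]
    n_valid_halves: int
    category: str | None = None
    ci95: tuple[float, float] | None = None
    metadata: dict = field(
        default_factory=lambda: {
            "predicted_shift_deg": DEFAULT_PREDICTED_SHIFT_DEG,
            "half_A": "[0, 180)",
            "half_B": "[180, 360)",
            "shift_search_deg": [-90, 90],
        }
    )


def scale_to_reference(
    pursuit_curve: TuningCurve, reference_curve: TuningCurve
) -> tuple[TuningCurve, float]:
    """Linearly rescale the pursuit curve about its mean so its peak-to-trough
    modulation equals the reference's. Returns (scaled curve, scale factor)."""
    ptt = pursuit_curve.amplitude
    if ptt == 0:
        raise FlatCurveError("zero peak-to-trough: scaling undefined")
    factor = reference_curve.amplitude / ptt
    m = pursuit_curve.mean_rate_hz.mean()
    scaled = TuningCurve(
        headings_deg=pursuit_curve.headings_deg.copy(),
        mean_rate_hz=m + (pursuit_curve.mean_rate_hz - m) * factor,
        sem_hz=pursuit_curve.sem_hz * factor,
        trials=[m + (t - m) * factor for t in pursuit_curve.trials],
        eye_pos_deg=pursuit_curve.eye_pos_deg,
        pursuit_dir=pursuit_curve.pursuit_dir,
    )
    return scaled, float(factor)


def split_halves(dense: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a dense 1-degree curve into half A [0, 180) and half B [180, 360)."""
    dense = np.asarray(dense, dtype=float)
    if len(dense) != 360:
        raise ValueError("expected a dense 360-sample curve")
    return dense[:180].copy(), dense[180:].copy()


def half_shift(reference_half: np.ndarray, pursuit_half: np.ndarray,
               max_shift: int = 90) -> int:
    """Integer shift (degrees) of the reference half-curve, circular within
    the half, maximizing Pearson correlation with the pursuit half.

    Positive shift means the pursuit half is displaced toward larger
    headings relative to the reference. Search range [-max_shift, max_shift];
    ties break to the smallest |shift|, negative first.
    """
    a = np.asarray(reference_half, dtype=float)
    b = np.asarray(pursuit_half, dtype=float)
    if a.shape != b.shape:
        raise ValueError("halves must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise FlatCurveError("flat half-curve: correlation undefined")
    shifts = range(-max_shift, max_shift + 1)
    best, best_r = 0, -np.inf
    for s in sorted(shifts, key=lambda s: (abs(s), s > 0)):
        r = np.corrcoef(np.roll(a, s), b)[0, 1]
        if r > best_r + 1e-12:
            best, best_r = s, r
    return best


def _half_trials(curve: TuningCurve, half: str) -> TuningCurve:
    """Sub-curve restricted to the headings of one half-range."""
    lo, hi = (0.0, 180.0) if half == "A" else (180.0, 360.0)
    mask = (curve.headings_deg >= lo) & (curve.headings_deg < hi)
    idx = np.flatnonzero(mask)
    return TuningCurve(
        headings_deg=curve.headings_deg[idx],
        mean_rate_hz=curve.mean_rate_hz[idx],
        sem_hz=curve.sem_hz[idx],
        trials=[curve.trials[i] for i in idx],
    )


def interpolate_half(curve: TuningCurve, half: str) -> np.ndarray:
    """Dense 1-degree interpolation of one half-range of a sampled curve.

    Only the samples falling in the half are used; interpolation is linear
    and periodic within the half (period 180 degrees), matching the circular
    shift applied by :func:`half_shift`.
    """
    sub = _half_trials(curve, half)
    lo = 0.0 if half == "A" else 180.0
    W, order = _interp_matrix(
        sub.headings_deg, resolution_deg=1.0, period_deg=180.0, origin_deg=lo
    )
    return W @ sub.mean_rate_hz[order]


def pursuit_di(
    no_pursuit: TuningCurve,
    leftward: TuningCurve,
    rightward: TuningCurve,
    predicted_shift_deg: float = DEFAULT_PREDICTED_SHIFT_DEG,
    alpha: float = 0.05,
    check_half_significance: bool = True,
) -> PursuitDIResult:
    """3-step partial-shift pursuit DI from the three pursuit-block curves.

    Half-curves failing the tuning-significance test (one-way ANOVA on the
    raw trials within the half) are dropped; with zero valid halves the
    result is unclassified with di = None.
    """
    if check_half_significance and tuning_significance(no_pursuit) >= alpha:
        return PursuitDIResult(
            di=None, half_shifts_deg={}, scale_factors={}, n_valid_halves=0,
            category="unclassified",
        )
    ref_halves = {h: interpolate_half(no_pursuit, h) for h in "AB"}

    half_shifts: dict[tuple[str, str], int] = {}
    scale_factors: dict[str, float] = {}
    aligned: list[float] = []
    for direction, curve in (("leftward", leftward), ("rightward", rightward)):
        try:
            scaled, factor = scale_to_reference(curve, no_pursuit)
        except FlatCurveError:
            continue
        scale_factors[direction] = factor
        halves = {h: interpolate_half(scaled, h) for h in "AB"}
        for half in "AB":
            if check_half_significance:
                sub = _half_trials(scaled, half)
                if (
                    len(sub.headings_deg) < 2
                    or tuning_significance(sub) >= alpha
                ):
                    continue
            try:
                s = half_shift(ref_halves[half], halves[half])
            except FlatCurveError:
                continue
            half_shifts[(direction, half)] = s
            aligned.append(SIGN_ALIGNMENT[(direction, half)] * s)

    if not aligned:
        return PursuitDIResult(
            di=None, half_shifts_deg=half_shifts, scale_factors=scale_factors,
            n_valid_halves=0, category="unclassified",
        )
    di = float(np.mean(aligned) / predicted_shift_deg)
    return PursuitDIResult(
        di=di,
        half_shifts_deg=half_shifts,
        scale_factors=scale_factors,
        n_valid_halves=len(aligned),
    )


def pursuit_di_xcov(
    no_pursuit: TuningCurve,
    leftward: TuningCurve,
    rightward: TuningCurve,
    predicted_shift_deg: float = DEFAULT_PREDICTED_SHIFT_DEG,
) -> float:
    """Alternative pursuit DI using the whole-curve cross-covariance lag, as
    in the eccentric-fixation method, for method-comparison analyses.

    The lag of each pursuit curve relative to the no-pursuit curve is
    sign-aligned by pursuit direction and averaged before dividing by the
    predicted shift.
    """
    _, ref = interpolate_circular(no_pursuit)
    lags = []
    for sign, curve in ((+1, leftward), (-1, rightward)):
        _, dense = interpolate_circular(curve)
        lags.append(sign * _best_lag(ref, dense))
    return float(np.mean(lags) / predicted_shift_deg)


def classify_pursuit(di: float, ci95: tuple[float, float]) -> str:
    """Category from bootstrap CI: complete_compensation if CI includes 0 but
    not 1; complete_shift if it includes 1 but not 0; partial if strictly
    inside (0, 1); otherwise unclassified."""
    lo, hi = ci95
    if lo > hi:
        raise ValueError("CI low must not exceed high")
    has0 = lo <= 0.0 <= hi
    has1 = lo <= 1.0 <= hi
    if has0 and not has1:
        return "complete_compensation"
    if has1 and not has0:
        return "complete_shift"
    if lo > 0.0 and hi < 1.0:
        return "partial"
    return "unclassified"
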