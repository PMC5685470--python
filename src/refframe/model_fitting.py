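"""Joint eye-centered / head-centered wrapped-Gaussian model fitting across
the three static eye positions, partial-correlation model comparison, and
Fisher-Z classification.

Both models fit all three tuning curves simultaneously with 16 free
parameters: a shared preferred direction theta0 plus {A1, sigma, kappa, A2,
R0} per eye position. In the eye-centered model the peak of the curve at eye
position P sits at theta0 + P; in the head-centered model all peaks sit at
theta0. Models are compared via partial correlations between the data and
each model's predictions, normalized with Fisher's r-to-Z transform; the
classification criterion is a Z-score difference of 1.645 (one-tailed normal
95% point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core_io import TuningCurve
from .synthetic_data import wrapped_gaussian

__all__ = [
    "WrappedGaussianParams",
    "JointFitResult",
    "ModelComparisonResult",
    "FitFailureError",
    "wrapped_gaussian",
    "fit_joint",
    "goodness_filter",
    "partial_correlations",
    "fisher_z",
    "classify_model",
    "compare_models",
]

Z_CRITERION = 1.645  # one-tailed standard-normal 95% point
R2_EXCLUSION = 0.6

PARAM_NAMES = ("a1", "sigma", "kappa", "a2", "r0")


class FitFailureError(RuntimeError):
    """All optimizer restarts failed to converge."""


@dataclass(frozen=True)
class WrappedGaussianParams:
    theta_p_deg: float
    sigma: float
    a1: float
    a2: float
    kappa: float
    r0: float

    def __call__(self, theta_deg):
        return wrapped_gaussian(
            theta_deg, self.theta_p_deg, self.sigma, self.a1,
            self.a2, self.kappa, self.r0,
        )


@dataclass
class JointFitResult:
    model: str  # "eye" | "head"
    theta0_deg: float
    params: dict[float, WrappedGaussianParams]  # eye position -> parameters
    r2: float
    sse: float
    n_free: int = 16
    predictions: dict[float, np.ndarray] = field(default_factory=dict)

    def predict(self, eye_pos: float, theta_deg):
        return self.params[eye_pos](theta_deg)


def _peak_offset(model: str, eye_pos: float) -> float:
    if model == "eye":
        return eye_pos
    if model == "head":
        return 0.0
    raise ValueError(f"unknown model {model!r}")


def _unpack(x: np.ndarray, eyes: list[float], model: str) -> dict[float, WrappedGaussianParams]:
    theta0 = x[0]
    out = {}
    for i, e in enumerate(eyes):
        a1, sigma, kappa, a2, r0 = x[1 + 5 * i : 6 + 5 * i]
        out[e] = WrappedGaussianParams(
            theta_p_deg=theta0 + _peak_offset(model, e),
            sigma=sigma, a1=a1, a2=a2, kappa=kappa, r0=r0,
        )
    return out


def fit_joint(
    curves: dict[float, TuningCurve],
    model: str,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
) -> JointFitResult:
    """Simultaneous bounded least-squares fit of all curves.

    Restarts combine deterministic initializations (theta0 at each curve's
    argmax heading and its antipode, corrected for the model's peak offset)
    with seeded random ones; the best final residual wins.
    """
    eyes = sorted(curves)
    if any(len(curves[e].headings_deg) < 5 for e in eyes):
        raise ValueError("need >= 5 headings per curve")
    rng = np.random.default_rng(seed)
    obs = np.concatenate([curves[e].mean_rate_hz for e in eyes])
    max_rate = max(float(obs.max()), 1e-6)

    headings = [np.asarray(curves[e].headings_deg, float) for e in eyes]
    offsets = [_peak_offset(model, e) for e in eyes]
    n_pts = [len(h) for h in headings]
    n_total = sum(n_pts)
    starts = np.concatenate([[0], np.cumsum(n_pts)])

    def residuals(x):
        params = _unpack(x, eyes, model)
        pred = np.concatenate([params[e](headings[i]) for i, e in enumerate(eyes)])
        return pred - obs

    def jacobian(x):
        """Analytic Jacobian of the residuals; column 0 is theta0."""
        J = np.zeros((n_total, len(x)))
        theta0 = x[0]
        for i in range(len(eyes)):
            a1, sigma, kappa, a2, _r0 = x[1 + 5 * i : 6 + 5 * i]
            d = np.deg2rad(headings[i] - theta0 - offsets[i])
            e1 = np.exp(-2.0 * (1.0 - np.cos(d)) / (sigma**2 * kappa))
            e2 = np.exp(-2.0 * (1.0 + np.cos(d)) / sigma**2)
            sl = slice(starts[i], starts[i + 1])
            dd_dtheta0 = -np.pi / 180.0
            de1_dd = e1 * (-2.0 * np.sin(d)) / (sigma**2 * kappa)
            de2_dd = e2 * (2.0 * np.sin(d)) / sigma**2
            J[sl, 0] = a1 * (de1_dd + a2 * de2_dd) * dd_dtheta0
            J[sl, 1 + 5 * i] = e1 + a2 * e2
            J[sl, 2 + 5 * i] = a1 * (
                e1 * 4.0 * (1.0 - np.cos(d)) / (sigma**3 * kappa)
                + a2 * e2 * 4.0 * (1.0 + np.cos(d)) / sigma**3
            )
            J[sl, 3 + 5 * i] = a1 * e1 * 2.0 * (1.0 - np.cos(d)) / (sigma**2 * kappa**2)
            J[sl, 4 + 5 * i] = a1 * e2
            J[sl, 5 + 5 * i] = 1.0
        return J

    lo = [-np.inf] + [1e-6, 0.1, 0.1, 0.0, 0.0] * len(eyes)
    hi = [np.inf] + [3.0 * max_rate, 10.0, 10.0, 1.0, max_rate] * len(eyes)

    inits: list[np.ndarray] = []
    per_eye0 = []
    for e in eyes:
        c = curves[e]
        amp = max(c.amplitude, 1e-3)
        per_eye0 += [amp, 2.0, 1.0, 0.05, max(float(c.mean_rate_hz.min()), 0.0)]
    for e in eyes:
        peak_h = float(curves[e].headings_deg[np.argmax(curves[e].mean_rate_hz)])
        for t0 in (peak_h - _peak_offset(model, e), peak_h - _peak_offset(model, e) + 180.0):
            inits.append(np.array([t0] + per_eye0))
    while len(inits) < n_restarts:
        x = np.array([rng.uniform(0.0, 360.0)] + per_eye0)
        x[2::5] = rng.uniform(0.5, 4.0, len(eyes))  # sigma
        inits.append(x)
    if n_restarts < len(inits):
        inits = inits[: max(n_restarts, 1)]

    best = None
    for x0 in inits:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.least_squares(
                    residuals, x0, jac=jacobian, bounds=(lo, hi),
                    xtol=1e-8, ftol=1e-8, gtol=1e-8,
                )
        except Exception:  # noqa: BLE001 — a failed restart is not fatal
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError(f"{model} model: no restart converged")

    params = _unpack(best.x, eyes, model)
    preds = {e: params[e](curves[e].headings_deg) for e in eyes}
    pred_vec = np.concatenate([preds[e] for e in eyes])
    r2 = _r2(obs, pred_vec)
    return JointFitResult(
        model=model,
        theta0_deg=float(best.x[0]) % 360.0,
        params=params,
        r2=r2,
        sse=float(2.0 * best.cost),
        predictions=preds,
    )


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """Squared Pearson correlation between observed and fitted rates."""
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def goodness_filter(r2: float, threshold: float = R2_EXCLUSION) -> bool:
    """True (keep) if r2 >= threshold; the boundary is inclusive."""
    return r2 >= threshold


def partial_correlations(
    data: np.ndarray, eye_pred: np.ndarray, head_pred: np.ndarray
) -> tuple[float, float]:
    """Partial correlations of the data with each model, removing the
    component explained by the competing model.

    R_e = (r_e - r_h*r_eh) / sqrt((1 - r_h^2)(1 - r_eh^2)) and symmetrically
    for R_h, where r_e, r_h are the plain data-model correlations and r_eh
    the inter-model correlation.
    """
    data = np.asarray(data, float)
    e = np.asarray(eye_pred, float)
    h = np.asarray(head_pred, float)
    if not (len(data) == len(e) == len(h)):
        raise ValueError("vectors must share length")
    r_e = _corr(data, e)
    r_h = _corr(data, h)
    r_eh = _corr(e, h)
    if abs(r_eh) >= 1.0 - 1e-12:
        raise ValueError("model predictions are perfectly correlated")
    eps = 1e-12
    R_e = (r_e - r_h * r_eh) / np.sqrt(max((1 - r_h**2) * (1 - r_eh**2), eps))
    R_h = (r_h - r_e * r_eh) / np.sqrt(max((1 - r_e**2) * (1 - r_eh**2), eps))
    return float(np.clip(R_e, -1.0, 1.0)), float(np.clip(R_h, -1.0, 1.0))


def _corr(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fisher_z(r: float, n_points: int, scaled: bool = True) -> float:
    """Fisher r-to-Z transform, Z = atanh(r)*sqrt(n - 3).

    With ``scaled`` the sqrt(n-3) factor makes 1.645 the one-tailed normal
    95% criterion; the unscaled atanh variant is available for comparison.
    |r| >= 1 is clipped to 1 - 1e-6.
    """
    if n_points <= 3:
        raise ValueError("need more than 3 data points")
    r = float(np.clip(r, -1.0 + 1e-6, 1.0 - 1e-6))
    z = np.arctanh(r)
    return float(z * np.sqrt(n_points - 3)) if scaled else float(z)


def classify_model(z_e: float, z_h: float, criterion: float = Z_CRITERION) -> str:
    """eye if Z_e - Z_h >= criterion; head if Z_h - Z_e >= criterion; else
    unclassified (the intermediate band)."""
    if z_e - z_h >= criterion:
        return "eye"
    if z_h - z_e >= criterion:
        return "head"
    return "unclassified"


@dataclass
class ModelComparisonResult:
    eye_fit: JointFitResult
    head_fit: JointFitResult
    r_e: float
    r_h: float
    R_e: float
    R_h: float
    z_e: float
    z_h: float
    z_diff: float
    n_points: int
    category: str
    excluded: bool
    exclusion_reason: str | None = None


def compare_models(
    curves: dict[float, TuningCurve],
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    scaled_z: bool = True,
) -> ModelComparisonResult:
    """Full model-comparison pipeline for one neuron/modality.

    Fits both models, applies the r2 >= 0.6 goodness filter on the better
    model, computes partial correlations on the concatenated mean rates over
    all conditions, Fisher-Z scores, and the category.
    """
    rng = np.random.default_rng(seed)
    eye_fit = fit_joint(curves, "eye", n_restarts=n_restarts, seed=rng)
    head_fit = fit_joint(curves, "head", n_restarts=n_restarts, seed=rng)
    eyes = sorted(curves)
    data = np.concatenate([curves[e].mean_rate_hz for e in eyes])
    e_pred = np.concatenate([eye_fit.predictions[e] for e in eyes])
    h_pred = np.concatenate([head_fit.predictions[e] for e in eyes])
    r_e = _corr(data, e_pred)
    r_h = _corr(data, h_pred)
    R_e, R_h = partial_correlations(data, e_pred, h_pred)
    n = len(data)
    z_e = fisher_z(R_e, n, scaled=scaled_z)
    z_h = fisher_z(R_h, n, scaled=scaled_z)
    best_r2 = max(eye_fit.r2, head_fit.r2)
    excluded = not goodness_filter(best_r2)
    return ModelComparisonResult(
        eye_fit=eye_fit,
        head_fit=head_fit,
        r_e=r_e,
        r_h=r_h,
        R_e=R_e,
        R_h=R_h,
        z_e=z_e,
        z_h=z_h,
        z_diff=z_e - z_h,
        n_points=n,
        category=classify_model(z_e, z_h),
        excluded=excluded,
        exclusion_reason=f"r2 {best_r2:.3f} < {R2_EXCLUSION}" if excluded else None,
    )
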