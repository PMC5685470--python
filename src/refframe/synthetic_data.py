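"""Synthetic trial-table generator with known ground truth.

Generates wrapped-Gaussian heading tuning whose preferred direction shifts by
a controllable fraction ``lambda_frame`` of the gaze displacement (0 = gaze
invariant, 1 = fully gaze-following), with optional multiplicative
eye-position gain fields, pursuit-induced half-range shifts controlled by a
compensation parameter ``c``, trial-to-trial noise, and simulated
heading-report behavior. Every downstream analysis stage is verifiable by
parameter recovery against these generative parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import ConditionGrid, TrialTable, estimation_schedule

__all__ = [
    "GainSpec",
    "NoiseSpec",
    "NeuronSpec",
    "MotionProfile",
    "wrapped_gaussian",
    "mean_rate",
    "simulate_fixation_block",
    "simulate_pursuit_block",
    "gaussian_velocity_profile",
    "simulate_behavior",
    "generate_population",
]

#: predicted half-range tuning shift (degrees) for zero pursuit compensation
DEFAULT_PREDICTED_SHIFT_DEG = 30.0


def wrapped_gaussian(
    theta_deg, theta_p_deg: float, sigma: float, a1: float,
    a2: float = 0.0, kappa: float = 1.0, r0: float = 0.0,
):
    """Modified wrapped Gaussian: a main peak at ``theta_p_deg`` plus an
    optional second peak 180 degrees out of phase.

    R(theta) = A1*[exp(-2(1-cos(theta-theta_p))/(sigma^2*kappa))
                   + A2*exp(-2(1-cos(theta-theta_p-180))/sigma^2)] + R0

    ``kappa`` scales the width of the first peak only.
    """
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - theta_p_deg)
    main = np.exp(-2.0 * (1.0 - np.cos(d)) / (sigma**2 * kappa))
    anti = np.exp(-2.0 * (1.0 + np.cos(d)) / sigma**2)  # cos(d - pi) = -cos d
    return a1 * (main + a2 * anti) + r0


@dataclass(frozen=True)
class GainSpec:
    """Multiplicative eye-position gain field.

    kind 'monotonic': factor 1 + strength*(eye/20); kind 'nonmonotonic':
    factor 1 + strength*|eye|/20 (negative strength = center-max). 'none'
    ignores strength.
    """

    kind: str = "none"  # none | monotonic | nonmonotonic
    strength: float = 0.0

    def factor(self, eye_pos_deg) -> np.ndarray:
        e = np.asarray(eye_pos_deg, dtype=float)
        if self.kind == "none":
            return np.ones_like(e)
        if self.kind == "monotonic":
            return 1.0 + self.strength * e / 20.0
        if self.kind == "nonmonotonic":
            return 1.0 + self.strength * np.abs(e) / 20.0
        raise ValueError(f"unknown gain kind {self.kind!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Trial noise model. 'gaussian_fano' draws Gaussian noise with variance
    fano*mean (clipped at 0); 'poisson' samples a 1 s spike count."""

    kind: str = "gaussian_fano"  # none | gaussian_fano | poisson
    fano: float = 1.5

    def sample(self, means: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        means = np.asarray(means, dtype=float)
        if self.kind == "none":
            return means.copy()
        if self.kind == "gaussian_fano":
            sd = np.sqrt(self.fano * np.maximum(means, 0.0))
            return np.clip(rng.normal(means, sd), 0.0, None)
        if self.kind == "poisson":
            return rng.poisson(np.maximum(means, 0.0)).astype(float)
        raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters for one synthetic neuron."""

    theta_p_deg: float = 90.0
    sigma: float = 1.5
    a1: float = 50.0
    a2: float = 0.0
    kappa: float = 1.0
    r0: float = 5.0
    lambda_frame: float = 1.0  # 0 = head-centered, 1 = eye-centered
    gain: GainSpec = field(default_factory=GainSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    pursuit_comp: float = 1.0  # c; 1 = complete compensation

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.sigma <= 0 or self.kappa <= 0:
            raise ValueError("A1, sigma and kappa must be positive")
        if not 0.0 <= self.a2 <= 1.0:
            raise ValueError("A2 must lie in [0, 1]")
        if self.r0 < 0:
            raise ValueError("R0 must be non-negative")


def mean_rate(spec: NeuronSpec, heading_deg, eye_pos_deg=0.0):
    """Noise-free mean firing rate at the given heading and eye position.

    The preferred direction sits at theta_p + lambda_frame*eye_pos and the
    whole curve is multiplied by the gain factor for that eye position.
    """
    peak = spec.theta_p_deg + spec.lambda_frame * np.asarray(eye_pos_deg, float)
    base = wrapped_gaussian(
        heading_deg, peak, spec.sigma, spec.a1, spec.a2, spec.kappa, spec.r0
    )
    return base * spec.gain.factor(eye_pos_deg)


def _trial_rows(neuron_id, modality, protocol, eye, pdir, headings, rates_by_rep):
    rows = []
    for rep, rates in enumerate(rates_by_rep, start=1):
        for h, r in zip(headings, rates):
            rows.append(
                {
                    "neuron_id": neuron_id,
                    "modality": modality,
                    "protocol": protocol,
                    "eye_pos_deg": eye,
                    "pursuit_dir": pdir,
                    "heading_deg": float(h) % 360.0,
                    "repetition": rep,
                    "rate_hz": float(r),
                }
            )
    return rows


def simulate_fixation_block(
    spec: NeuronSpec,
    grid: ConditionGrid | None = None,
    reps: int = 5,
    seed: int | np.random.Generator = 0,
    neuron_id: str = "syn0",
    modality: str = "visual",
) -> TrialTable:
    """Simulate an eccentric-fixation block: noisy trials at every
    (heading, eye position) cell of the grid."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid = grid or ConditionGrid.standard()
    rng = np.random.default_rng(seed)
    rows = []
    for eye in grid.eye_positions_deg:
        means = mean_rate(spec, np.asarray(grid.headings_deg), eye)
        rates = [spec.noise.sample(means, rng) for _ in range(reps)]
        rows += _trial_rows(
            neuron_id, modality, "eccentric_fixation", float(eye), "none",
            grid.headings_deg, rates,
        )
    return TrialTable(pd.DataFrame(rows))


def _shift_half(dense: np.ndarray, lo: int, shift: float) -> np.ndarray:
    """Circularly shift the 180-sample half starting at index ``lo`` by
    ``shift`` degrees (content moves toward larger headings for shift > 0).
    Fractional shifts are linearly interpolated, periodic within the half."""
    out = dense.copy()
    half = dense[lo : lo + 180]
    pos = (np.arange(180) - shift) % 180.0
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    out[lo : lo + 180] = (1.0 - frac) * half[i0] + frac * half[(i0 + 1) % 180]
    return out


def pursuit_mean_curves(
    spec: NeuronSpec, predicted_shift_deg: float = DEFAULT_PREDICTED_SHIFT_DEG
) -> dict[str, np.ndarray]:
    """Dense (1 degree) noise-free tuning for the three pursuit conditions.

    For an uncompensated neuron (c=0) the [0,180) and [180,360) half-ranges
    of the no-pursuit tuning shift by the full predicted displacement with
    opposite signs, the direction pattern mirroring between leftward and
    rightward pursuit; compensation c scales the shift by (1-c).
    """
    dense = mean_rate(spec, np.arange(360.0), 0.0)
    s = (1.0 - spec.pursuit_comp) * predicted_shift_deg
    left = _shift_half(_shift_half(dense, 0, +s), 180, -s)
    right = _shift_half(_shift_half(dense, 0, -s), 180, +s)
    return {"none": dense, "leftward": left, "rightward": right}


def simulate_pursuit_block(
    spec: NeuronSpec,
    reps: int = 5,
    seed: int | np.random.Generator = 0,
    heading_step: float = 15.0,
    predicted_shift_deg: float = DEFAULT_PREDICTED_SHIFT_DEG,
    neuron_id: str = "syn0",
) -> TrialTable:
    """Simulate a pursuit block: no-pursuit plus leftward/rightward pursuit.

    The default 15-degree heading grid is finer than the experimental 45
    degrees so that the partial-shift analysis, which interpolates linearly
    between sampled headings, can resolve the generated half-range shifts.
    """
    rng = np.random.default_rng(seed)
    headings = np.arange(0.0, 360.0, heading_step)
    idx = np.round(headings).astype(int) % 360
    curves = pursuit_mean_curves(spec, predicted_shift_deg)
    rows = []
    for pdir, dense in curves.items():
        means = dense[idx]
        rates = [spec.noise.sample(means, rng) for _ in range(reps)]
        rows += _trial_rows(neuron_id, "visual", "pursuit", 0.0, pdir, headings, rates)
    return TrialTable(pd.DataFrame(rows))


@dataclass
class MotionProfile:
    """Gaussian-bell translation velocity profile."""

    duration_s: float
    distance_m: float
    times_s: np.ndarray
    velocity_mps: np.ndarray

    @property
    def peak_velocity_mps(self) -> float:
        return float(self.velocity_mps.max())

    @property
    def peak_accel_mps2(self) -> float:
        return float(np.abs(np.gradient(self.velocity_mps, self.times_s)).max())


def gaussian_velocity_profile(
    duration_s: float = 2.0,
    distance_m: float = 0.11,
    truncation_sigmas: float = 3.0,
    n_samples: int = 2001,
) -> MotionProfile:
    """Bell-shaped velocity trace whose integral equals ``distance_m``.

    The Gaussian is centered mid-trajectory with the stated number of sigmas
    fitted into each half of the window, and renormalized after truncation so
    the travelled distance is exact.
    """
    if duration_s <= 0 or distance_m <= 0 or truncation_sigmas <= 0:
        raise ValueError("all arguments must be positive")
    t = np.linspace(0.0, duration_s, n_samples)
    sig = duration_s / (2.0 * truncation_sigmas)
    v = np.exp(-0.5 * ((t - duration_s / 2.0) / sig) ** 2)
    v *= distance_m / np.trapezoid(v, t)
    return MotionProfile(duration_s, distance_m, t, v)


def simulate_behavior(
    bias_gain: float,
    noise_sd_deg: float,
    grid: ConditionGrid | None = None,
    reps: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate heading reports biased toward the fixation side.

    reported = true + bias_gain*eye_pos + Gaussian noise, wrapped to
    [0, 360). bias_gain = 1 models a fully gaze-referenced reporter.
    """
    grid = grid or ConditionGrid(
        list(np.arange(0.0, 360.0, 20.0)), [-20.0, 0.0, 20.0]
    )
    rng = np.random.default_rng(seed)
    rows = []
    for heading, eye in estimation_schedule(grid):
        for rep in range(1, reps + 1):
            reported = heading + bias_gain * eye + rng.normal(0.0, noise_sd_deg)
            rows.append(
                {
                    "true_heading_deg": heading,
                    "eye_pos_deg": eye,
                    "repetition": rep,
                    "reported_heading_deg": reported % 360.0,
                }
            )
    return pd.DataFrame(rows)


def generate_population(
    n_neurons: int,
    seed: int | np.random.Generator = 0,
    lambda_frame: float = 1.0,
    noise: NoiseSpec | None = None,
    gain: GainSpec | None = None,
    pursuit_comp: float = 1.0,
    grid: ConditionGrid | None = None,
    reps: int = 5,
    a1_range: tuple[float, float] = (30.0, 80.0),
    sigma_range: tuple[float, float] = (1.0, 2.5),
    r0_range: tuple[float, float] = (2.0, 10.0),
) -> tuple[list[NeuronSpec], TrialTable]:
    """Reproducible population of synthetic neurons plus one combined table.

    Preferred headings are uniform on the circle; amplitudes, widths and
    baselines are uniform in the stated ranges. All randomness flows from
    the single seed through a split generator.
    """
    rng = np.random.default_rng(seed)
    noise = noise if noise is not None else NoiseSpec()
    gain = gain if gain is not None else GainSpec()
    grid = grid or ConditionGrid.standard()
    specs: list[NeuronSpec] = []
    tables: list[pd.DataFrame] = []
    for i in range(n_neurons):
        spec = NeuronSpec(
            theta_p_deg=float(rng.uniform(0.0, 360.0)),
            sigma=float(rng.uniform(*sigma_range)),
            a1=float(rng.uniform(*a1_range)),
            r0=float(rng.uniform(*r0_range)),
            lambda_frame=lambda_frame,
            gain=gain,
            noise=noise,
            pursuit_comp=pursuit_comp,
        )
        specs.append(spec)
        block = simulate_fixation_block(
            spec, grid, reps=reps, seed=rng, neuron_id=f"syn{i:04d}"
        )
        tables.append(block.df)
    if not specs:
        return [], TrialTable(
            pd.DataFrame(
                columns=[
                    "neuron_id", "modality", "protocol", "eye_pos_deg",
                    "pursuit_dir", "heading_deg", "repetition", "rate_hz",
                ]
            )
        )
    return specs, TrialTable(pd.concat(tables, ignore_index=True))


def vary(spec: NeuronSpec, **changes) -> NeuronSpec:
    """Return a copy of ``spec`` with the given fields replaced."""
    return replace(spec, **changes)
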