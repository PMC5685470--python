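"""Heading-estimation behavior: mapping saccade ring endpoints to reported
headings, circular summary statistics, and fixation-dependent estimation
error.

Reports are made by saccade onto a target ring centered on the fixation
location; the ring angle maps one-to-one onto heading azimuth (ring 0 deg =
rightward heading, ring 90 deg = up = forward heading).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "endpoint_to_heading",
    "target_position",
    "score_trial",
    "circ_mean_deg",
    "circ_sd_deg",
    "estimate_summary",
    "estimation_error",
    "estimate_bias_gain",
    "signed_circular_diff",
]

RING_DIAMETER_DEG = 20.0
REWARD_WINDOW_DEG = (5.0, 5.0)


def endpoint_to_heading(
    endpoint: tuple[float, float], ring_center: tuple[float, float] = (0.0, 0.0)
) -> float:
    """Reported heading (degrees, [0, 360)) from a saccade endpoint.

    The polar angle of the endpoint about the ring center, with 0 deg =
    right and 90 deg = up, maps directly onto heading azimuth (0 = rightward,
    90 = forward).
    """
    dx = endpoint[0] - ring_center[0]
    dy = endpoint[1] - ring_center[1]
    if dx == 0 and dy == 0:
        raise ValueError("endpoint at ring center: angle undefined")
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def target_position(
    heading_deg: float,
    ring_center: tuple[float, float] = (0.0, 0.0),
    ring_diameter_deg: float = RING_DIAMETER_DEG,
) -> tuple[float, float]:
    """Screen position of the ring dot representing ``heading_deg``."""
    r = ring_diameter_deg / 2.0
    a = np.radians(heading_deg)
    return (
        ring_center[0] + r * float(np.cos(a)),
        ring_center[1] + r * float(np.sin(a)),
    )


def score_trial(
    endpoint: tuple[float, float],
    true_heading_deg: float,
    ring_center: tuple[float, float] = (0.0, 0.0),
    ring_diameter_deg: float = RING_DIAMETER_DEG,
    window_deg: tuple[float, float] = REWARD_WINDOW_DEG,
) -> bool:
    """True iff the endpoint falls in the axis-aligned reward window centered
    on the true heading's ring dot (default 5 x 5 deg, i.e. +-2.5 deg)."""
    tx, ty = target_position(true_heading_deg, ring_center, ring_diameter_deg)
    wx, wy = window_deg
    return bool(
        abs(endpoint[0] - tx) <= wx / 2.0 and abs(endpoint[1] - ty) <= wy / 2.0
    )


def circ_mean_deg(angles_deg) -> float:
    """Circular mean in degrees, [0, 360): atan2 of summed unit vectors."""
    a = np.radians(np.asarray(angles_deg, float))
    s, c = np.sin(a).sum(), np.cos(a).sum()
    if s == 0 and c == 0:
        raise ValueError("zero resultant: circular mean undefined")
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if mean >= 360.0 else mean  # guard float wrap to exactly 360


def circ_sd_deg(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar) in degrees."""
    a = np.radians(np.asarray(angles_deg, float))
    rbar = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    rbar = min(rbar, 1.0)
    if rbar == 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def signed_circular_diff(a_deg: float, b_deg: float) -> float:
    """Signed difference a - b wrapped to (-180, 180]."""
    d = (a_deg - b_deg) % 360.0
    return d if d <= 180.0 else d - 360.0


def estimate_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Circular mean and SD of reported headings per (true heading, eye
    position) group. Requires >= 2 records per group."""
    required = {"true_heading_deg", "eye_pos_deg", "reported_heading_deg"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    rows = []
    for (h, e), grp in records.groupby(["true_heading_deg", "eye_pos_deg"]):
        if len(grp) < 2:
            raise ValueError(f"group (heading {h}, eye {e}) has < 2 records")
        vals = grp["reported_heading_deg"].to_numpy()
        rows.append(
            {
                "true_heading_deg": h,
                "eye_pos_deg": e,
                "circ_mean_deg": circ_mean_deg(vals),
                "circ_sd_deg": circ_sd_deg(vals),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def estimation_error(summaries: pd.DataFrame) -> dict[float, float]:
    """Per-eccentric-fixation estimation error relative to central fixation.

    For each eccentric eye position, the signed circular difference of the
    mean estimate (eccentric - central) is averaged over matched headings.
    Positive error = shift toward the fixation side. Headings missing from
    either condition are skipped with a warning.
    """
    central = summaries[summaries["eye_pos_deg"] == 0.0].set_index("true_heading_deg")
    if central.empty:
        raise ValueError("no central-fixation summaries")
    out: dict[float, float] = {}
    for eye in sorted(summaries["eye_pos_deg"].unique()):
        if eye == 0.0:
            continue
        ecc = summaries[summaries["eye_pos_deg"] == eye].set_index("true_heading_deg")
        matched = ecc.index.intersection(central.index)
        if len(matched) < len(ecc.index) or len(matched) < len(central.index):
            import warnings

            warnings.warn(
                f"eye {eye}: only {len(matched)} matched headings", stacklevel=2
            )
        if len(matched) == 0:
            continue
        diffs = [
            signed_circular_diff(
                ecc.loc[h, "circ_mean_deg"], central.loc[h, "circ_mean_deg"]
            )
            for h in matched
        ]
        out[float(eye)] = float(np.mean(diffs))
    return out


def estimate_bias_gain(errors: dict[float, float]) -> float:
    """Eye-position bias gain: mean of error / eye position over eccentric
    fixations (gain 1 = fully gaze-referenced reports)."""
    if not errors:
        raise ValueError("no eccentric-fixation errors")
    return float(np.mean([err / eye for eye, err in errors.items()]))
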