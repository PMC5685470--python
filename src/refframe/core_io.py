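"""Trial-table data model, CSV I/O, tuning-curve construction and significance.

The trial table is a tidy, long-format table: one row per completed trial,
keyed by (neuron_id, modality, protocol, condition, heading, repetition) and
carrying either a precomputed firing rate or raw spike times. All analysis
stages consume :class:`TuningCurve` objects built from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialTable",
    "TuningCurve",
    "ConditionGrid",
    "TrialTableError",
    "MissingHeadingError",
    "load_trial_table",
    "write_trial_table",
    "firing_rate_from_spikes",
    "build_tuning",
    "tuning_significance",
    "estimation_schedule",
]

MODALITIES = ("visual", "vestibular")
PROTOCOLS = ("eccentric_fixation", "pursuit", "estimation")
PURSUIT_DIRS = ("none", "leftward", "rightward")

#: default spike-count window (seconds): middle 1 s of the 2 s stimulus
DEFAULT_SPIKE_WINDOW = (0.5, 1.5)

REQUIRED_COLUMNS = (
    "neuron_id",
    "modality",
    "protocol",
    "eye_pos_deg",
    "pursuit_dir",
    "heading_deg",
    "repetition",
)


class TrialTableError(ValueError):
    """Raised for malformed trial tables."""


class MissingHeadingError(TrialTableError):
    """A heading required by the condition grid is absent from the data."""


@dataclass
class TrialTable:
    """Validated wrapper around a tidy trial DataFrame.

    Exactly one of ``rate_hz`` / ``spike_times_s`` is populated per row.
    ``spike_times_s`` holds a list of spike times in seconds within [0, 2].
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def neuron_ids(self) -> list[str]:
        return sorted(self.df["neuron_id"].unique())

    def rates(self, window: tuple[float, float] = DEFAULT_SPIKE_WINDOW) -> pd.Series:
        """Firing rate per row, computing it from spike times where needed."""
        out = self.df["rate_hz"].copy()
        need = out.isna()
        if need.any():
            out.loc[need] = [
                firing_rate_from_spikes(ts, window)
                for ts in self.df.loc[need, "spike_times_s"]
            ]
        return out.astype(float)

    def select(self, **criteria) -> "TrialTable":
        mask = pd.Series(True, index=self.df.index)
        for col, val in criteria.items():
            mask &= self.df[col] == val
        return TrialTable(self.df[mask].reset_index(drop=True))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {', '.join(missing)}")
    if "rate_hz" not in df.columns and "spike_times_s" not in df.columns:
        raise TrialTableError("need at least one of 'rate_hz' / 'spike_times_s'")
    df = df.copy()
    for col in ("rate_hz", "spike_times_s"):
        if col not in df.columns:
            df[col] = np.nan if col == "rate_hz" else None

    bad_rows: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header on line 1
        if row["modality"] not in MODALITIES:
            bad_rows.append(f"line {line}: unknown modality {row['modality']!r}")
        if row["protocol"] not in PROTOCOLS:
            bad_rows.append(f"line {line}: unknown protocol {row['protocol']!r}")
        if row["pursuit_dir"] not in PURSUIT_DIRS:
            bad_rows.append(f"line {line}: unknown pursuit_dir {row['pursuit_dir']!r}")
        has_rate = pd.notna(row["rate_hz"])
        has_spikes = isinstance(row["spike_times_s"], (list, tuple, np.ndarray))
        if has_rate == has_spikes:
            bad_rows.append(
                f"line {line}: exactly one of rate_hz/spike_times_s must be set"
            )
        elif has_rate and row["rate_hz"] < 0:
            bad_rows.append(f"line {line}: negative rate_hz")
        if row["repetition"] < 1:
            bad_rows.append(f"line {line}: repetition must be >= 1")
    if bad_rows:
        raise TrialTableError("invalid trial rows:\n" + "\n".join(bad_rows))

    heading = df["heading_deg"].astype(float)
    out_of_range = (heading < 0) | (heading >= 360)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} heading(s) outside [0, 360) normalized mod 360",
            stacklevel=3,
        )
        df["heading_deg"] = np.mod(heading, 360.0)
    df["repetition"] = df["repetition"].astype(int)
    return df.reset_index(drop=True)


def load_trial_table(path, column_map: dict[str, str] | None = None) -> TrialTable:
    """Read a comma-separated trial table.

    Parameters
    ----------
    path : str or path-like
        UTF-8 CSV with a mandatory header row.
    column_map : dict, optional
        Maps file column names to the canonical field names, for ingesting
        externally deposited files whose headers differ.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "spike_times_s" in df.columns:
        df["spike_times_s"] = df["spike_times_s"].map(_parse_spike_times)
    return TrialTable(df)


def _parse_spike_times(cell) -> list[float] | None:
    if isinstance(cell, (list, tuple, np.ndarray)):
        return list(cell)
    if pd.isna(cell) or cell == "":
        return None
    return [float(tok) for tok in str(cell).split(";")]


def write_trial_table(table: TrialTable, path) -> None:
    """Write a trial table as CSV (spike times joined with ';')."""
    df = table.df.copy()
    df["spike_times_s"] = df["spike_times_s"].map(
        lambda ts: ";".join(f"{t:g}" for t in ts)
        if isinstance(ts, (list, tuple, np.ndarray))
        else ""
    )
    df.to_csv(path, index=False)


def firing_rate_from_spikes(
    spike_times_s, window: tuple[float, float] = DEFAULT_SPIKE_WINDOW
) -> float:
    """Spike count in the half-open window [start, end) divided by its length."""
    start, end = window
    if end <= start:
        raise ValueError(f"window end {end} must exceed start {start}")
    ts = np.asarray(spike_times_s, dtype=float)
    n = int(np.count_nonzero((ts >= start) & (ts < end)))
    return n / (end - start)


@dataclass
class TuningCurve:
    """Per-heading mean firing rate for one neuron under one condition."""

    headings_deg: np.ndarray
    mean_rate_hz: np.ndarray
    sem_hz: np.ndarray
    trials: list[np.ndarray]
    eye_pos_deg: float | None = None
    pursuit_dir: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.headings_deg = np.asarray(self.headings_deg, dtype=float)
        self.mean_rate_hz = np.asarray(self.mean_rate_hz, dtype=float)
        self.sem_hz = np.asarray(self.sem_hz, dtype=float)
        n = len(self.headings_deg)
        if not (len(self.mean_rate_hz) == len(self.sem_hz) == len(self.trials) == n):
            raise ValueError("headings, means, sems and trials must share length")

    @property
    def n_reps(self) -> int:
        return min(len(t) for t in self.trials)

    @property
    def amplitude(self) -> float:
        """Peak-to-trough of the mean curve (the 'evoked response')."""
        return float(self.mean_rate_hz.max() - self.mean_rate_hz.min())


def build_tuning(
    table: TrialTable,
    neuron_id: str,
    modality: str,
    *,
    protocol: str = "eccentric_fixation",
    eye_pos_deg: float | None = None,
    pursuit_dir: str | None = None,
    grid_headings=None,
    window: tuple[float, float] = DEFAULT_SPIKE_WINDOW,
) -> TuningCurve:
    """Collapse trials to a per-heading mean ± s.e.m. tuning curve.

    ``grid_headings``, if given, lists the headings that must be present;
    a heading on the grid with no data raises :class:`MissingHeadingError`.
    """
    crit = {"neuron_id": neuron_id, "modality": modality, "protocol": protocol}
    if eye_pos_deg is not None:
        crit["eye_pos_deg"] = eye_pos_deg
    if pursuit_dir is not None:
        crit["pursuit_dir"] = pursuit_dir
    sub = table.select(**crit)
    if len(sub) == 0:
        raise TrialTableError(f"no trials match {crit}")
    rates = sub.rates(window)
    headings = np.sort(sub.df["heading_deg"].unique())
    if grid_headings is not None:
        missing = sorted(set(np.mod(grid_headings, 360.0)) - set(headings))
        if missing:
            raise MissingHeadingError(f"no trials at heading(s) {missing}")
    means, sems, trials, flags = [], [], [], []
    for h in headings:
        vals = rates[sub.df["heading_deg"] == h].to_numpy()
        trials.append(vals)
        means.append(vals.mean())
        if len(vals) > 1:
            sems.append(vals.std(ddof=1) / np.sqrt(len(vals)))
        else:
            sems.append(0.0)  # single repetition: sem 0 by convention
            flags.append(f"n=1 at heading {h:g}; sem set to 0")
    return TuningCurve(
        headings_deg=np.asarray(headings),
        mean_rate_hz=np.asarray(means),
        sem_hz=np.asarray(sems),
        trials=trials,
        eye_pos_deg=eye_pos_deg,
        pursuit_dir=pursuit_dir,
        flags=flags,
    )


def tuning_significance(curve: TuningCurve) -> float:
    """One-way ANOVA p-value for a heading effect on per-trial firing rates.

    Degenerate inputs (no variance anywhere, or single repetitions) return
    p = 1.0 and flag the curve rather than raising.
    """
    if len(curve.headings_deg) < 2:
        raise ValueError("need at least 2 headings for ANOVA")
    if curve.n_reps < 2:
        curve.flags.append("ANOVA not testable with n=1 repetitions")
        return 1.0
    pooled = np.concatenate(curve.trials)
    if np.ptp(pooled) == 0:
        curve.flags.append("degenerate ANOVA: zero variance")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*curve.trials)
    if np.isnan(p):
        curve.flags.append("degenerate ANOVA: NaN p-value")
        return 1.0
    return float(p)


@dataclass
class ConditionGrid:
    """Stimulus condition grid: headings x static eye positions."""

    headings_deg: list[float]
    eye_positions_deg: list[float]
    plane: str = "horizontal"
    reps: int = 5

    @classmethod
    def standard(cls, heading_step: float = 45.0, eccentricity: float = 20.0,
                 plane: str = "horizontal", reps: int = 5) -> "ConditionGrid":
        headings = list(np.arange(0.0, 360.0, heading_step))
        return cls(headings, [-eccentricity, 0.0, eccentricity], plane, reps)


def estimation_schedule(grid: ConditionGrid) -> list[tuple[float, float]]:
    """Cartesian product of headings x eye positions (the trial schedule)."""
    if not grid.headings_deg or not grid.eye_positions_deg:
        raise ValueError("headings and eye positions must be non-empty")
    return [
        (float(h), float(e))
        for e in grid.eye_positions_deg
        for h in grid.headings_deg
    ]
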