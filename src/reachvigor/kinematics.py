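"""Trajectory processing and per-trial kinematic metrics.

Raw 200-Hz hand position traces are low-pass filtered (zero-phase
Butterworth), differentiated with five-point stencils, and segmented into a
movement by a moving-window variability criterion on speed and acceleration.
Per-trial metrics (reaction time, movement duration, peak velocity, endpoint
and angular error, maximum excursion) feed the accuracy and utility
analyses; experiment-specific outlier rules remove malformed trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Trajectory",
    "TrialMetrics",
    "lowpass_filter",
    "fivepoint_derivative",
    "differentiate",
    "radial_velocity",
    "detect_onset_offset",
    "trial_metrics",
    "filter_outliers",
    "trials_to_frame",
]

#: Default onset/offset detection thresholds: moving-window standard
#: deviation of speed (m/s) and acceleration magnitude (m/s^2).
VEL_SD_THRESHOLD = 0.0006
ACC_SD_THRESHOLD = 0.0075
#: Moving-window length in samples (50 ms at 200 Hz).
DETECTION_WINDOW = 10


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled planar hand path with the target-onset event (s)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    target_onset: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("time, x, y must have equal length")
        if len(t) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("positions must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class TrialMetrics:
    """Derived per-trial metrics (SI units; angles in degrees)."""

    t_r_s: float
    t_m_s: float
    peak_vel_mps: float
    endpoint_x_m: float
    endpoint_y_m: float
    endpoint_error_m: float
    angular_error_deg: float
    max_excursion_m: float
    reaction_velocity_mps: float
    direction_deg: float
    success: bool | None = None

    def __post_init__(self) -> None:
        if self.t_r_s < 0:
            raise ValueError("reaction time must be non-negative")
        if self.t_m_s <= 0:
            raise ValueError("movement duration must be positive")
        if self.max_excursion_m < 0:
            raise ValueError("max excursion must be non-negative")


def lowpass_filter(traj: Trajectory, cutoff: float = 10.0, order: int = 4) -> Trajectory:
    """Zero-phase low-pass Butterworth filter applied to x and y."""
    if traj.fs < 2 * cutoff:
        raise ValueError("sampling rate must be at least twice the cutoff")
    b, a = signal.butter(order, cutoff, fs=traj.fs)
    padlen = 3 * max(len(a), len(b))
    if len(traj.x) <= padlen:
        raise ValueError(f"trajectory too short to filter (need > {padlen} samples)")
    return Trajectory(
        time=traj.time,
        x=signal.filtfilt(b, a, traj.x),
        y=signal.filtfilt(b, a, traj.y),
        target_onset=traj.target_onset,
    )


# One-sided five-point stencil coefficients for the first derivative at the
# first/second sample (mirrored with opposite sign at the end).
_EDGE0 = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / 12.0
_EDGE1 = np.array([-3.0, -10.0, 18.0, -6.0, 1.0]) / 12.0


def fivepoint_derivative(y, dt: float) -> np.ndarray:
    """Five-point central-difference first derivative.

    Interior points use the degree-4-exact stencil
    ``(y[k-2] - 8 y[k-1] + 8 y[k+1] - y[k+2]) / (12 h)``; the two samples at
    each edge use the matching one-sided five-point stencils.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 samples for five-point differentiation")
    out = np.empty(n)
    out[2:-2] = (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12 * dt)
    out[0] = _EDGE0 @ y[:5] / dt
    out[1] = _EDGE1 @ y[:5] / dt
    out[-1] = -(_EDGE0 @ y[-5:][::-1]) / dt
    out[-2] = -(_EDGE1 @ y[-5:][::-1]) / dt
    return out


def differentiate(y, dt: float, order: int = 1) -> np.ndarray:
    """First or second derivative by (repeated) five-point differentiation."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    d = fivepoint_derivative(y, dt)
    return d if order == 1 else fivepoint_derivative(d, dt)


def radial_velocity(traj: Trajectory, home: tuple[float, float]) -> np.ndarray:
    """Five-point derivative of the Euclidean distance from the home circle."""
    r = np.hypot(traj.x - home[0], traj.y - home[1])
    return fivepoint_derivative(r, traj.dt)


def _moving_std(x: np.ndarray, window: int, align: str = "center") -> np.ndarray:
    """Moving-window standard deviation with the given alignment."""
    s = pd.Series(x)
    if align == "center":
        out = s.rolling(window, center=True, min_periods=1).std(ddof=0)
    elif align == "lead":  # window [k, k + window - 1]
        out = s.iloc[::-1].rolling(window, min_periods=1).std(ddof=0).iloc[::-1]
    else:
        raise ValueError(f"unknown alignment {align!r}")
    return out.to_numpy()


def detect_onset_offset(
    traj: Trajectory,
    vel_sd_thresh: float = VEL_SD_THRESHOLD,
    acc_sd_thresh: float = ACC_SD_THRESHOLD,
    window: int = DETECTION_WINDOW,
) -> tuple[int, int]:
    """Detect movement onset and offset sample indices.

    Onset is the first sample at or after target onset where the moving-window
    standard deviations of speed and acceleration magnitude both exceed their
    thresholds.  Offset is the first sample after peak speed where both fall
    below threshold and stay below for a full window; if the trace never
    settles, the last sample is returned with a warning.
    """
    dt = traj.dt
    vx = fivepoint_derivative(traj.x, dt)
    vy = fivepoint_derivative(traj.y, dt)
    speed = np.hypot(vx, vy)
    ax = fivepoint_derivative(vx, dt)
    ay = fivepoint_derivative(vy, dt)
    acc = np.hypot(ax, ay)

    v_sd = _moving_std(speed, window)
    a_sd = _moving_std(acc, window)
    active = (v_sd > vel_sd_thresh) & (a_sd > acc_sd_thresh)

    start = int(np.searchsorted(traj.time, traj.target_onset))
    idx = np.flatnonzero(active[start:])
    if len(idx) == 0:
        raise ValueError("no movement detected: variability never exceeds thresholds")
    onset = start + int(idx[0])

    peak = onset + int(np.argmax(speed[onset:]))
    # offset requires BOTH variability signals to settle (the speed-std alone
    # dips spuriously at peak velocity, where the profile is momentarily flat);
    # a forward-looking window avoids the half-window lag of the centred one
    v_sd_lead = _moving_std(speed, window, align="lead")
    a_sd_lead = _moving_std(acc, window, align="lead")
    quiet = (v_sd_lead <= vel_sd_thresh) & (a_sd_lead <= acc_sd_thresh)
    offset = None
    k = peak + 1
    n = len(speed)
    while k < n:
        if quiet[k]:
            run_end = min(n, k + window)
            if np.all(quiet[k:run_end]):
                offset = k
                break
            k += int(np.argmax(~quiet[k:run_end])) + 1
        else:
            k += 1
    if offset is None:
        warnings.warn("movement never settles below thresholds; offset set to trace end")
        offset = n - 1
    return onset, offset


def trial_metrics(
    traj: Trajectory,
    home: tuple[float, float],
    direction_deg: float,
    experiment: int = 2,
    target_distance: float = 0.10,
    **detect_kwargs,
) -> TrialMetrics:
    """Compute per-trial metrics from a (filtered) trajectory.

    Movement duration runs from onset to offset, except for the out-and-back
    experiment (4) where it runs from onset to the time of maximum excursion.
    The endpoint is taken at the movement end; angular error is the signed
    angle (deg, positive counterclockwise) between the home-to-endpoint ray
    and the home-to-target ray.
    """
    onset, offset = detect_onset_offset(traj, **detect_kwargs)
    dt = traj.dt
    rel_x = traj.x - home[0]
    rel_y = traj.y - home[1]
    dist = np.hypot(rel_x, rel_y)

    exc_idx = onset + int(np.argmax(dist[onset : offset + 1]))
    end_idx = exc_idx if experiment == 4 else offset
    if end_idx <= onset:
        raise ValueError("movement end precedes onset")

    vx = fivepoint_derivative(traj.x, dt)
    vy = fivepoint_derivative(traj.y, dt)
    speed = np.hypot(vx, vy)

    th = np.radians(direction_deg)
    target = np.array([target_distance * np.cos(th), target_distance * np.sin(th)])
    ep = np.array([rel_x[end_idx], rel_y[end_idx]])
    ang = np.degrees(np.arctan2(ep[1], ep[0]) - th)
    ang = (ang + 180.0) % 360.0 - 180.0

    return TrialMetrics(
        t_r_s=float(traj.time[onset] - traj.target_onset),
        t_m_s=float((end_idx - onset) * dt),
        peak_vel_mps=float(np.max(speed[onset : offset + 1])),
        endpoint_x_m=float(ep[0]),
        endpoint_y_m=float(ep[1]),
        endpoint_error_m=float(np.linalg.norm(ep - target)),
        angular_error_deg=float(ang),
        max_excursion_m=float(dist[exc_idx]),
        reaction_velocity_mps=float(speed[onset]),
        direction_deg=float(direction_deg),
    )


def trials_to_frame(trials: list[TrialMetrics], **extra) -> pd.DataFrame:
    """Tidy DataFrame from a batch of trial metrics; ``extra`` adds columns."""
    df = pd.DataFrame([asdict(t) for t in trials])
    for k, v in extra.items():
        df[k] = v
    return df


# Prescribed-speed experiment absolute bounds.
_EXP1_RULES = {
    "endpoint_error_m": 0.10,
    "t_m_min": 0.2,
    "t_m_max": 2.0,
    "t_r_max": 0.50,
    "angular_error_max_deg": 50.0,
}
_IQR_COLUMNS = ("t_m_s", "t_r_s", "reaction_velocity_mps", "angular_error_deg")


def filter_outliers(
    trials: pd.DataFrame,
    ruleset: str,
    group_cols: tuple[str, ...] = ("subject_id", "added_mass_kg"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove outlier trials under the experiment-specific rules.

    ``ruleset='exp1'`` applies the absolute bounds of the prescribed-speed
    protocol (endpoint error > 10 cm; duration outside [0.2, 2] s; reaction
    time > 0.5 s; |angular error| > 50 deg).  ``ruleset='exp234'`` removes
    trials outside the 1.5x-IQR fences of duration, reaction time, reaction
    velocity, or angular error, computed within ``group_cols`` cells, plus
    maximum excursion above 14 cm for the stop-at-target experiments; pass
    ``max_excursion_limit=None`` via a pre-filtered frame for the
    out-and-back experiment.

    Returns (kept, removed, log) where the log lists trial index and reasons.
    """
    if trials.empty:
        warnings.warn("filter_outliers received an empty trial table")
        empty_log = pd.DataFrame(columns=["index", "reason"])
        return trials, trials, empty_log

    reasons: dict[int, list[str]] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in trials.index[mask.fillna(False)]:
            reasons.setdefault(idx, []).append(reason)

    if ruleset == "exp1":
        r = _EXP1_RULES
        flag(trials["endpoint_error_m"] > r["endpoint_error_m"], "endpoint_error>10cm")
        flag(
            (trials["t_m_s"] < r["t_m_min"]) | (trials["t_m_s"] > r["t_m_max"]),
            "duration outside [0.2, 2] s",
        )
        flag(trials["t_r_s"] > r["t_r_max"], "reaction_time>0.5s")
        flag(
            trials["angular_error_deg"].abs() > r["angular_error_max_deg"],
            "|angular_error|>50deg",
        )
    elif ruleset == "exp234":
        grouped = trials.groupby(list(group_cols), observed=True)
        for col in _IQR_COLUMNS:
            q1 = grouped[col].transform(lambda s: s.quantile(0.25))
            q3 = grouped[col].transform(lambda s: s.quantile(0.75))
            iqr = q3 - q1
            out = (trials[col] < q1 - 1.5 * iqr) | (trials[col] > q3 + 1.5 * iqr)
            flag(out, f"{col} outside 1.5*IQR")
        if "experiment" in trials.columns:
            stoppers = trials["experiment"].isin([2, 3])
        else:
            stoppers = pd.Series(True, index=trials.index)
        flag(stoppers & (trials["max_excursion_m"] > 0.14), "max_excursion>14cm")
    else:
        raise ValueError(f"unknown ruleset {ruleset!r}")

    removed_idx = list(reasons)
    log = pd.DataFrame(
        {"index": removed_idx, "reason": ["; ".join(reasons[i]) for i in removed_idx]}
    )
    removed = trials.loc[removed_idx]
    kept = trials.drop(index=removed_idx)
    return kept, removed, log
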