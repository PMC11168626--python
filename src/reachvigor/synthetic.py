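"""Synthetic cohorts for the reaching experiments.

Generates complete datasets with the statistical structure the analysis
assumes, so every pipeline stage can be tested end to end without raw data:

* prescribed-speed reaching blocks with steady-state gas exchange whose
  moving-time metabolic rate follows the power-law rate model;
* self-paced trial tables whose durations, reaction times, endpoints and
  success labels follow the configured generative rules (lognormal
  durations around condition means; reaction time linear in effective mass;
  endpoint scatter calibrated so that success probability matches the
  logistic speed-accuracy model under the experiment's target geometry);
* full 200-Hz minimum-jerk trajectories with measurement noise and known
  ground truth, for testing the kinematic processing chain.

Trajectories are kinematic templates plus noise; no muscle dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from . import constants
from .accuracy import (
    SuccessCriterion,
    SpeedAccuracyParams,
    label_success,
    success_probability,
)
from .kinematics import Trajectory
from .metabolics import (
    BROCKWAY_CO2,
    BROCKWAY_O2,
    BlockSummary,
    GasSeries,
    MetabolicParams,
    moving_rate,
    rate_model,
)

__all__ = [
    "PopulationConfig",
    "SubjectParams",
    "ExperimentDesign",
    "TrialTruth",
    "experiment_design",
    "sample_subject",
    "minimum_jerk",
    "calibrate_endpoint_sigma",
    "simulate_trial",
    "simulate_trial_record",
    "simulate_metabolic_block",
    "simulate_experiment",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level generative parameters.

    Means anchor to the reported cohort statistics; between-subject standard
    deviations are back-computed from standard errors where reported (e.g.
    resting rate 73.33 +/- 3.60 W SE over 8 subjects -> sd ~ 10.2 W) and set
    to plausible magnitudes otherwise.
    """

    body_mass_mean: float = 68.4
    body_mass_sd: float = 11.0
    height_mean: float = 1.736
    height_sd: float = 0.10
    resting_rate_mean: float = constants.RESTING_RATE_W
    resting_rate_sd: float = constants.RESTING_RATE_SE_W * np.sqrt(8)
    #: multiplicative jitter (lognormal sigma) on the metabolic a, b coefficients
    metabolic_a_sigma: float = 0.05
    metabolic_b_sigma: float = 0.10
    #: per-subject deviation of the accuracy logistic intercept (logit units)
    accuracy_intercept_sd: float = 0.3
    #: reaction time = intercept + slope * effective mass + trial noise
    rt_intercept_mean: float = 0.164
    rt_intercept_sd: float = 0.015
    rt_mass_slope_mean: float = constants.RT_MASS_SLOPE_SELF_PACED
    rt_mass_slope_sd: float = 1.0e-3
    rt_trial_sd: float = 0.02
    #: per-subject offset on condition effective mass (kg)
    effective_mass_sd: float = 0.2
    #: self-paced duration structure: subject-level multiplicative scale and
    #: within-subject lognormal coefficient of variation
    duration_subject_sigma: float = 0.08
    duration_trial_cv: float = 0.10
    #: realized movement duration (onset to offset) exceeds the prescribed
    #: timing window (measured at first target entry) by this overhead (s);
    #: places the fastest prescribed window near 0.5 s realized, where the
    #: fitted power law matches the observed gross-power range
    duration_overhead_s: float = 0.25
    #: sd of the moving-rate measurement error per block (W), matching the
    #: residual scale of the metabolic-rate fit
    rate_noise_sd: float = 25.0
    #: additive position measurement noise on trajectories (m); encoder-level
    #: (tens of microns) so the filtered acceleration noise floor stays below
    #: the movement-detection settle threshold
    position_noise_sd: float = 1.0e-5
    respiratory_exchange_ratio: float = 0.85

    def __post_init__(self) -> None:
        for name in ("body_mass_mean", "height_mean", "resting_rate_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "body_mass_sd", "height_sd", "resting_rate_sd", "metabolic_a_sigma",
            "metabolic_b_sigma", "accuracy_intercept_sd", "rt_intercept_sd",
            "rt_mass_slope_sd", "rt_trial_sd", "effective_mass_sd",
            "duration_subject_sigma", "duration_trial_cv", "rate_noise_sd",
            "position_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.7 <= self.respiratory_exchange_ratio <= 1.0:
            raise ValueError("respiratory exchange ratio must lie in [0.7, 1.0]")


@dataclass(frozen=True)
class SubjectParams:
    subject_id: int
    body_mass: float
    height: float
    resting_rate: float
    a_scale: float
    b_scale: float
    accuracy_intercept_dev: float
    rt_intercept: float
    rt_mass_slope: float
    effective_mass_offset: float
    duration_scale: float


@dataclass(frozen=True)
class ExperimentDesign:
    experiment: int
    added_masses: tuple[float, ...]
    trials_per_block: int
    criterion: SuccessCriterion
    directions_deg: tuple[float, ...] = constants.DIRECTIONS_DEG
    target_distance: float = constants.TARGET_DISTANCE_M
    speed_windows: dict | None = None          # experiment 1 only
    speed_windows_by_mass: dict | None = None  # experiment 1 only
    duration_means: tuple[float, ...] | None = None  # self-paced experiments


@dataclass(frozen=True)
class TrialTruth:
    """Generator ground truth returned alongside a simulated trajectory."""

    onset_time: float
    movement_duration: float
    reaction_time: float
    endpoint: tuple[float, float]
    success_probability: float


def experiment_design(experiment: int) -> ExperimentDesign:
    """Packaged design (masses, trial counts, geometry) for experiments 1-4."""
    if experiment == 1:
        return ExperimentDesign(
            experiment=1,
            added_masses=tuple(sorted(constants.EFFECTIVE_MASS_KG[1])),
            trials_per_block=200,
            criterion=constants.SUCCESS_CRITERIA[1],
            speed_windows=dict(constants.SPEED_WINDOWS),
            speed_windows_by_mass=dict(constants.SPEED_WINDOWS_BY_MASS),
        )
    if experiment in (2, 3, 4):
        return ExperimentDesign(
            experiment=experiment,
            added_masses=tuple(sorted(constants.EFFECTIVE_MASS_KG[experiment])),
            trials_per_block=400 if experiment in (2, 3) else 200,
            criterion=constants.SUCCESS_CRITERIA[experiment],
            duration_means=constants.OBSERVED_DURATIONS_S[
                2 if experiment in (2, 4) else 3
            ],
        )
    raise ValueError("experiment must be 1, 2, 3 or 4")


def sample_subject(
    config: PopulationConfig, rng: np.random.Generator, subject_id: int = 0
) -> SubjectParams:
    """Draw one subject from the configured population distributions."""
    return SubjectParams(
        subject_id=subject_id,
        body_mass=float(
            np.clip(rng.normal(config.body_mass_mean, config.body_mass_sd), 40, 120)
        ),
        height=float(
            np.clip(rng.normal(config.height_mean, config.height_sd), 1.4, 2.1)
        ),
        resting_rate=float(
            np.clip(
                rng.normal(config.resting_rate_mean, config.resting_rate_sd), 30, 150
            )
        ),
        a_scale=float(rng.lognormal(0.0, config.metabolic_a_sigma)),
        b_scale=float(rng.lognormal(0.0, config.metabolic_b_sigma)),
        accuracy_intercept_dev=float(rng.normal(0.0, config.accuracy_intercept_sd)),
        rt_intercept=float(rng.normal(config.rt_intercept_mean, config.rt_intercept_sd)),
        rt_mass_slope=float(
            rng.normal(config.rt_mass_slope_mean, config.rt_mass_slope_sd)
        ),
        effective_mass_offset=float(rng.normal(0.0, config.effective_mass_sd)),
        duration_scale=float(rng.lognormal(0.0, config.duration_subject_sigma)),
    )


def minimum_jerk(
    start: tuple[float, float],
    end: tuple[float, float],
    duration: float,
    fs: float = constants.SAMPLING_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk point-to-point path sampled at ``fs``.

    Returns (t, x, y) over [0, duration] with the fifth-order polynomial
    smoothness profile s(u) = 10u^3 - 15u^4 + 6u^5.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration shorter than two samples")
    t = np.arange(n + 1) / fs
    u = t / duration
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    x = start[0] + (end[0] - start[0]) * s
    y = start[1] + (end[1] - start[1]) * s
    return t, x, y


def _circle_prob(sigma: float, radius: float) -> float:
    # P(||N(0, sigma^2 I_2)|| < radius), Rayleigh CDF
    return 1.0 - np.exp(-(radius**2) / (2 * sigma**2))


def _arc_prob(sigma: float, criterion: SuccessCriterion) -> float:
    lo, hi = criterion.radial_band
    aim = 0.5 * (lo + hi)
    half_w = aim * np.tan(np.radians(criterion.angular_limit_deg))
    p_rad = stats.norm.cdf((hi - aim) / sigma) - stats.norm.cdf((lo - aim) / sigma)
    p_tan = 2 * stats.norm.cdf(half_w / sigma) - 1
    return float(p_rad * p_tan)


def calibrate_endpoint_sigma(p: float, criterion: SuccessCriterion) -> float:
    """Isotropic endpoint noise sd (m) whose success probability equals ``p``.

    Closed-form (Rayleigh inversion) for circular targets; 1-D root finding
    for the radial-arc geometry.  ``p`` is clipped away from 0 and 1.
    """
    if criterion.kind == "quadrant":
        return 0.0
    if p >= 1 - 1e-9:  # certain success: no endpoint scatter
        return 0.0
    p = float(np.clip(p, 1e-9, 1 - 1e-9))
    if criterion.kind == "circle":
        return criterion.radius / np.sqrt(-2.0 * np.log1p(-p))
    f = lambda s: _arc_prob(s, criterion) - p
    return float(brentq(f, 1e-6, 1.0, xtol=1e-10))


def _aim_point(design: ExperimentDesign, direction_rad: float) -> np.ndarray:
    if design.criterion.kind == "arc":
        lo, hi = design.criterion.radial_band
        r = 0.5 * (lo + hi)
    else:
        r = design.target_distance
    return r * np.array([np.cos(direction_rad), np.sin(direction_rad)])


def _trial_endpoint(
    subject: SubjectParams,
    design: ExperimentDesign,
    effective_mass: float,
    t_m: float,
    direction_deg: float,
    accuracy: SpeedAccuracyParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Endpoint (home-relative) drawn so success follows the logistic."""
    betas = SpeedAccuracyParams(
        accuracy.beta0 + subject.accuracy_intercept_dev, accuracy.beta1, accuracy.beta2
    )
    p = success_probability(betas, t_m, effective_mass)
    sigma = calibrate_endpoint_sigma(p, design.criterion)
    aim = _aim_point(design, np.radians(direction_deg))
    return aim + rng.normal(0.0, sigma, size=2), float(p)


def simulate_trial_record(
    subject: SubjectParams,
    design: ExperimentDesign,
    added_mass: float,
    effective_mass: float,
    t_m: float,
    direction_deg: float,
    accuracy: SpeedAccuracyParams,
    rng: np.random.Generator,
    config: PopulationConfig,
) -> dict:
    """One trial as a tidy row, without synthesising the 200-Hz trace."""
    t_r = max(
        0.05,
        subject.rt_intercept
        + subject.rt_mass_slope * effective_mass
        + rng.normal(0.0, config.rt_trial_sd),
    )
    endpoint, p = _trial_endpoint(
        subject, design, effective_mass, t_m, direction_deg, accuracy, rng
    )
    th = np.radians(direction_deg)
    target = design.target_distance * np.array([np.cos(th), np.sin(th)])
    ang = np.degrees(np.arctan2(endpoint[1], endpoint[0]) - th)
    ang = (ang + 180.0) % 360.0 - 180.0
    row = {
        "subject_id": subject.subject_id,
        "experiment": design.experiment,
        "added_mass_kg": added_mass,
        "effective_mass_kg": effective_mass,
        "direction_deg": direction_deg,
        "t_r_s": t_r,
        "t_m_s": t_m,
        "peak_vel_mps": 1.875 * design.target_distance / t_m,
        "endpoint_x_m": endpoint[0],
        "endpoint_y_m": endpoint[1],
        "endpoint_error_m": float(np.linalg.norm(endpoint - target)),
        "angular_error_deg": float(ang),
        "max_excursion_m": float(np.linalg.norm(endpoint)),
        "reaction_velocity_mps": 0.0,
        "success_probability": p,
    }
    row["success"] = label_success(row, design.criterion)
    return row


def simulate_trial(
    subject: SubjectParams,
    design: ExperimentDesign,
    added_mass: float,
    effective_mass: float,
    direction_deg: float,
    rng: np.random.Generator,
    duration: float | None = None,
    accuracy: SpeedAccuracyParams | None = None,
    config: PopulationConfig | None = None,
    home: tuple[float, float] = (0.0, 0.0),
    target_onset: float = 0.2,
    hold_after: float = 0.4,
) -> tuple[Trajectory, TrialTruth]:
    """Simulate one full trajectory with known ground truth.

    The hand rests at ``home`` until ``target_onset`` plus the drawn reaction
    time, follows a minimum-jerk path to the perturbed endpoint over the
    movement duration, then holds.  Additive white measurement noise of sd
    ``config.position_noise_sd`` is applied to both coordinates.
    """
    config = config or PopulationConfig()
    accuracy = accuracy or constants.SPEED_ACCURACY_PARAMS[2]
    if duration is None:
        means = dict(
            zip(design.added_masses, design.duration_means or (0.8,) * 4)
        )
        mu = means[added_mass] * subject.duration_scale
        duration = float(
            mu * rng.lognormal(0.0, config.duration_trial_cv)
        )
    fs = constants.SAMPLING_RATE_HZ
    if duration * fs < 2:
        raise ValueError("infeasible movement duration (< 2 samples)")
    t_r = max(
        0.05,
        subject.rt_intercept
        + subject.rt_mass_slope * effective_mass
        + rng.normal(0.0, config.rt_trial_sd),
    )
    endpoint, p = _trial_endpoint(
        subject, design, effective_mass, duration, direction_deg, accuracy, rng
    )

    n_pre = int(round((target_onset + t_r) * fs))
    _, mx, my = minimum_jerk(home, (home[0] + endpoint[0], home[1] + endpoint[1]), duration, fs)
    n_post = int(round(hold_after * fs))
    x = np.concatenate([np.full(n_pre, home[0]), mx, np.full(n_post, mx[-1])])
    y = np.concatenate([np.full(n_pre, home[1]), my, np.full(n_post, my[-1])])
    if config.position_noise_sd > 0:
        x = x + rng.normal(0.0, config.position_noise_sd, size=len(x))
        y = y + rng.normal(0.0, config.position_noise_sd, size=len(y))
    time = np.arange(len(x)) / fs
    traj = Trajectory(time=time, x=x, y=y, target_onset=target_onset)
    truth = TrialTruth(
        onset_time=n_pre / fs,
        movement_duration=duration,
        reaction_time=t_r,
        endpoint=(float(endpoint[0]), float(endpoint[1])),
        success_probability=p,
    )
    return traj, truth


def simulate_metabolic_block(
    subject: SubjectParams,
    effective_mass: float,
    window: tuple[float, float],
    n_trials: int,
    rng: np.random.Generator,
    metabolic: MetabolicParams = constants.METABOLIC_PARAMS,
    config: PopulationConfig | None = None,
    block_duration: float = 300.0,
    intertrial: float = 0.5,
    gas_dt: float = 5.0,
    transient: bool = False,
    noiseless: bool = False,
) -> tuple[GasSeries, BlockSummary, float]:
    """One prescribed-speed reaching block with gas exchange.

    The target moving rate comes from the rate model with subject-jittered
    coefficients; block-average measured power is composed by time-weighting
    moving and resting rates (the inverse of the moving-time normalisation),
    then perturbed so the recovered moving rate has sd ``rate_noise_sd``.
    Gas flows split the power at the configured respiratory exchange ratio.
    Returns (gas series, block summary, true moving rate in W).
    """
    config = config or PopulationConfig()
    lo, hi = window
    if not (0 < lo < hi):
        raise ValueError("invalid speed window")
    params = MetabolicParams(
        a=metabolic.a * subject.a_scale,
        b=metabolic.b * subject.b_scale,
        i=metabolic.i,
        j=metabolic.j,
        k=metabolic.k,
    )
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    t_m = np.clip(rng.normal(mid, half / 2, size=n_trials), lo, hi)
    if noiseless:
        t_m = np.full(n_trials, mid)
    t_r = np.maximum(
        0.05,
        subject.rt_intercept
        + subject.rt_mass_slope * effective_mass
        + (0.0 if noiseless else rng.normal(0.0, config.rt_trial_sd, size=n_trials)),
    )
    T_m = float(np.sum(t_m))
    T_trial = float(T_m + np.sum(t_r) + n_trials * intertrial)

    rate_true = float(rate_model(params, effective_mass, float(np.mean(t_m))))
    e_rest = subject.resting_rate
    e_parvo_true = (rate_true * T_m + e_rest * (T_trial - T_m)) / T_trial
    if noiseless:
        e_parvo = e_parvo_true
    else:
        e_parvo = e_parvo_true + rng.normal(0.0, config.rate_noise_sd * T_m / T_trial)

    times = np.arange(0.0, block_duration + gas_dt / 2, gas_dt)
    power = np.full_like(times, e_parvo)
    if transient:
        # first ~2 min: exponential on-kinetics from rest; the steady-state
        # window (final 3 min) must exclude it
        power = e_rest + (e_parvo - e_rest) * (1.0 - np.exp(-times / 30.0))
    if not noiseless:
        ar = np.zeros_like(times)
        eps = rng.normal(0.0, 0.02 * e_parvo, size=len(times))
        for k in range(1, len(times)):
            ar[k] = 0.7 * ar[k - 1] + eps[k]
        power = np.maximum(power + ar - np.mean(ar[times >= times[-1] - 180.0]), 1.0)
    rer = config.respiratory_exchange_ratio
    vo2 = power / (BROCKWAY_O2 + BROCKWAY_CO2 * rer)
    vco2 = rer * vo2
    gas = GasSeries(time=times, vo2=vo2, vco2=vco2)

    measured = power[times >= times[-1] - 180.0].mean()
    block = BlockSummary(
        T_m=T_m, T_trial=T_trial, n=n_trials, e_parvo=float(measured), e_rest=e_rest
    )
    return gas, block, rate_true


def simulate_experiment(
    experiment: int,
    n_subjects: int,
    seed: int,
    config: PopulationConfig | None = None,
    design: ExperimentDesign | None = None,
    accuracy: SpeedAccuracyParams | None = None,
    trials_per_block: int | None = None,
    noiseless: bool = False,
    accuracy_trials: bool = True,
) -> dict:
    """Generate a full synthetic experiment.

    Returns a dict with a tidy ``trials`` DataFrame and, for the metabolic
    experiment, a ``blocks`` DataFrame (one row per speed-by-mass block,
    matching the metabolic fitting schema) and a ``gas`` mapping from
    (subject_id, added_mass, speed) to :class:`GasSeries`.  Deterministic
    given ``seed``.
    """
    config = config or PopulationConfig()
    design = design or experiment_design(experiment)
    accuracy = accuracy or constants.SPEED_ACCURACY_PARAMS[2]
    rng = np.random.default_rng(seed)
    subjects = [sample_subject(config, rng, subject_id=s) for s in range(n_subjects)]
    table = constants.EFFECTIVE_MASS_KG[experiment]
    n_tr = trials_per_block or design.trials_per_block

    trial_rows: list[dict] = []
    block_rows: list[dict] = []
    gas: dict = {}

    for subj in subjects:
        for added in design.added_masses:
            m_eff = table[added] + subj.effective_mass_offset
            if design.experiment == 1:
                windows = design.speed_windows_by_mass[added]
                for wname in windows:
                    w_lo, w_hi, n_win = design.speed_windows[wname]
                    lo = w_lo + config.duration_overhead_s
                    hi = w_hi + config.duration_overhead_s
                    n_blk = min(n_win, n_tr)
                    g, block, rate_true = simulate_metabolic_block(
                        subj, m_eff, (lo, hi), n_blk, rng,
                        config=config, noiseless=noiseless,
                    )
                    block_rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "added_mass_kg": added,
                            "effective_mass_kg": m_eff,
                            "speed_condition": wname,
                            "mean_movement_duration_s": block.T_m / block.n,
                            "gross_power_W": moving_rate(block),
                            "true_rate_W": rate_true,
                        }
                    )
                    gas[(subj.subject_id, added, wname)] = g
                    if not accuracy_trials:
                        continue
                    # accuracy trials: durations span the window
                    mid = 0.5 * (lo + hi)
                    for k in range(n_blk // 4):
                        for d in design.directions_deg:
                            t_m = float(np.clip(rng.normal(mid, (hi - lo) / 4), lo, hi))
                            trial_rows.append(
                                simulate_trial_record(
                                    subj, design, added, m_eff, t_m, d,
                                    accuracy, rng, config,
                                )
                            )
            else:
                means = dict(zip(design.added_masses, design.duration_means))
                mu = means[added] * subj.duration_scale
                for k in range(n_tr):
                    d = design.directions_deg[k % len(design.directions_deg)]
                    t_m = float(mu * rng.lognormal(0.0, config.duration_trial_cv))
                    trial_rows.append(
                        simulate_trial_record(
                            subj, design, added, m_eff, t_m, d, accuracy, rng, config
                        )
                    )

    out = {"trials": pd.DataFrame(trial_rows), "subjects": subjects}
    if design.experiment == 1:
        out["blocks"] = pd.DataFrame(block_rows)
        out["gas"] = gas
    return out
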