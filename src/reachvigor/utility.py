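"""Movement utility models and predicted preferred durations.

The central model treats the preferred movement duration as the maximiser
of a net reward rate: expected reward (reward alpha scaled by the
probability of hitting the target) minus effort (resting expenditure during
the reaction time plus the gross metabolic cost of the movement), divided by
the total time to reward,

    J(t_m) = [alpha * P(t_m, m) - er_rate * t_r - e_m(t_m, m)] / (t_r + t_m).

Two alternative forms probe the role of temporal discounting: one with no
time cost at all, and one discounting only the reward.  The reward alpha is
in joules-equivalent units (it is differenced with metabolic cost) and is
fit by least squares to observed group-mean durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .accuracy import SpeedAccuracyParams, success_probability
from .metabolics import MetabolicParams, movement_cost
from . import constants

__all__ = [
    "UtilityContext",
    "Condition",
    "AlphaFit",
    "UTILITY_FORMS",
    "experiment_conditions",
    "utility_value",
    "optimal_movement_duration",
    "fit_alpha",
    "predict_durations",
    "compare_time_cost_models",
    "bootstrap_full_chain",
]

UTILITY_FORMS = ("nrr", "no_time", "reward_time")

#: Movement-duration optimisation bounds (s).
DURATION_BOUNDS = (0.2, 2.0)
#: Reward-parameter search bracket; widened on demand.  Negative rewards are
#: admitted because the reward-only-discounting form fits best at alpha < 0.
ALPHA_BRACKET = (-500.0, 500.0)


@dataclass(frozen=True)
class UtilityContext:
    """Everything the utility needs for one condition."""

    alpha: float
    resting_rate: float
    reaction_time: float
    effective_mass: float
    metabolic: MetabolicParams
    accuracy: SpeedAccuracyParams

    def __post_init__(self) -> None:
        if self.resting_rate <= 0:
            raise ValueError("resting_rate must be positive")
        if self.reaction_time < 0:
            raise ValueError("reaction_time must be non-negative")
        if self.effective_mass <= 0:
            raise ValueError("effective_mass must be positive")


@dataclass(frozen=True)
class Condition:
    """One mass condition: label, effective mass (kg), reaction time (s),
    and optionally the observed group-mean movement duration (s)."""

    label: str
    effective_mass: float
    reaction_time: float
    observed_duration: float | None = None


@dataclass
class AlphaFit:
    alpha: float
    sse: float
    predictions: np.ndarray


def experiment_conditions(experiment: int) -> list[Condition]:
    """Packaged condition sets (effective masses, reaction times, observed
    mean durations) for the self-paced experiments 2 and 3."""
    if experiment not in (2, 3):
        raise ValueError("packaged conditions exist for experiments 2 and 3 only")
    masses = constants.EFFECTIVE_MASS_KG[experiment]
    rts = constants.REACTION_TIMES_S[experiment]
    obs = constants.OBSERVED_DURATIONS_S[experiment]
    return [
        Condition(
            label=f"{added:g} kg",
            effective_mass=m_eff,
            reaction_time=rt,
            observed_duration=o,
        )
        for (added, m_eff), rt, o in zip(sorted(masses.items()), rts, obs)
    ]


def utility_value(ctx: UtilityContext, t_m, form: str = "nrr"):
    """Evaluate the movement utility at duration(s) ``t_m``."""
    t_m = np.asarray(t_m, dtype=float)
    if np.any(t_m <= 0):
        raise ValueError("t_m must be positive")
    P = success_probability(ctx.accuracy, t_m, ctx.effective_mass)
    e_m = movement_cost(ctx.metabolic, ctx.effective_mass, t_m)
    e_r = ctx.resting_rate * ctx.reaction_time
    T = ctx.reaction_time + t_m
    if form == "nrr":
        out = (ctx.alpha * P - e_r - e_m) / T
    elif form == "no_time":
        out = ctx.alpha * P - e_r - e_m
    elif form == "reward_time":
        out = ctx.alpha * P / T - e_r - e_m
    else:
        raise ValueError(f"unknown utility form {form!r}")
    return float(out) if np.ndim(out) == 0 else out


def optimal_movement_duration(
    ctx: UtilityContext,
    form: str = "nrr",
    bounds: tuple[float, float] = DURATION_BOUNDS,
    grid_points: int = 721,
) -> float:
    """Duration (s) maximising the utility over ``bounds``.

    A coarse grid locates the global maximum (the utility can be flat or
    multimodal for extreme rewards); bounded scalar optimisation then refines
    it.  A warning is issued if the maximum sits at a bound.
    """
    lo, hi = bounds
    grid = np.linspace(lo, hi, grid_points)
    vals = utility_value(ctx, grid, form=form)
    k = int(np.argmax(vals))
    a = grid[max(0, k - 1)]
    b = grid[min(grid_points - 1, k + 1)]
    if a == b:
        t_star = float(grid[k])
    else:
        res = minimize_scalar(
            lambda t: -utility_value(ctx, t, form=form),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-9},
        )
        t_star = float(res.x)
    if t_star - lo < 1e-6 or hi - t_star < 1e-6:
        warnings.warn(
            f"utility maximum at the duration bound ({t_star:.4f} s); "
            "the optimum may be degenerate"
        )
    return t_star


def _context(alpha, cond, metabolic, accuracy, resting_rate) -> UtilityContext:
    return UtilityContext(
        alpha=alpha,
        resting_rate=resting_rate,
        reaction_time=cond.reaction_time,
        effective_mass=cond.effective_mass,
        metabolic=metabolic,
        accuracy=accuracy,
    )


def predict_durations(
    alpha: float,
    form: str,
    conditions: list[Condition],
    metabolic: MetabolicParams,
    accuracy: SpeedAccuracyParams,
    resting_rate: float = constants.RESTING_RATE_W,
    bounds: tuple[float, float] = DURATION_BOUNDS,
) -> np.ndarray:
    """Utility-maximising duration for every condition."""
    return np.array(
        [
            optimal_movement_duration(
                _context(alpha, c, metabolic, accuracy, resting_rate),
                form=form,
                bounds=bounds,
            )
            for c in conditions
        ]
    )


def fit_alpha(
    form: str,
    conditions: list[Condition],
    metabolic: MetabolicParams,
    accuracy: SpeedAccuracyParams,
    resting_rate: float = constants.RESTING_RATE_W,
    bracket: tuple[float, float] = ALPHA_BRACKET,
    bounds: tuple[float, float] = DURATION_BOUNDS,
    _depth: int = 0,
) -> AlphaFit:
    """Least-squares fit of the reward parameter alpha.

    Minimises the sum of squared differences between predicted and observed
    group-mean durations over alpha, by a coarse scan followed by bounded
    refinement.  The bracket expands (up to twice) if the optimum lands on
    its edge.  Deterministic.
    """
    observed = np.array([c.observed_duration for c in conditions], dtype=float)
    if np.any(~np.isfinite(observed)):
        raise ValueError("every condition must carry an observed duration")

    def sse(alpha: float) -> float:
        pred = predict_durations(
            alpha, form, conditions, metabolic, accuracy, resting_rate, bounds
        )
        return float(np.sum((pred - observed) ** 2))

    lo, hi = bracket
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary warnings during the scan
        scan = np.linspace(lo, hi, 21)
        scan_sse = [sse(a) for a in scan]
        k = int(np.argmin(scan_sse))
        a_lo = scan[max(0, k - 1)]
        a_hi = scan[min(len(scan) - 1, k + 1)]
        res = minimize_scalar(
            sse, bounds=(a_lo, a_hi), method="bounded", options={"xatol": 1e-6}
        )
    alpha = float(res.x)
    if min(alpha - lo, hi - alpha) < 1e-3 * (hi - lo):
        if _depth >= 2:
            raise RuntimeError(
                f"alpha optimum not bracketed in {bracket} after expansion"
            )
        wider = (lo - (hi - lo), hi + (hi - lo))
        return fit_alpha(
            form, conditions, metabolic, accuracy, resting_rate, wider, bounds,
            _depth=_depth + 1,
        )
    pred = predict_durations(
        alpha, form, conditions, metabolic, accuracy, resting_rate, bounds
    )
    return AlphaFit(alpha=alpha, sse=float(res.fun), predictions=pred)


def compare_time_cost_models(
    conditions_exp2: list[Condition],
    conditions_exp3: list[Condition],
    metabolic: MetabolicParams,
    accuracy_exp2: SpeedAccuracyParams,
    accuracy_exp3: SpeedAccuracyParams,
    resting_rate: float = constants.RESTING_RATE_W,
) -> pd.DataFrame:
    """Fit each utility form on experiment-2 means; predict experiment 3.

    Returns a DataFrame indexed by utility form with the fitted alpha and the
    mean squared prediction error (s^2) on each experiment.  Experiment-3
    predictions reuse the experiment-2 alpha (no refitting).
    """
    obs2 = np.array([c.observed_duration for c in conditions_exp2])
    obs3 = np.array([c.observed_duration for c in conditions_exp3])
    rows = {}
    for form in UTILITY_FORMS:
        fit = fit_alpha(form, conditions_exp2, metabolic, accuracy_exp2, resting_rate)
        pred3 = predict_durations(
            fit.alpha, form, conditions_exp3, metabolic, accuracy_exp3, resting_rate
        )
        rows[form] = {
            "alpha": fit.alpha,
            "mse_exp2": float(np.mean((fit.predictions - obs2) ** 2)),
            "mse_exp3": float(np.mean((pred3 - obs3) ** 2)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bootstrap_full_chain(
    subject_durations: pd.DataFrame,
    metabolic: MetabolicParams,
    accuracy: SpeedAccuracyParams,
    conditions: list[Condition],
    resting_rate: float = constants.RESTING_RATE_W,
    form: str = "nrr",
    n_rep: int = 1000,
    seed: int | None = None,
) -> dict:
    """Bootstrap the reward fit and the predicted durations.

    ``subject_durations`` is a tidy frame with columns ``subject_id``,
    ``condition`` (matching ``Condition.label`` order after sorting) and
    ``t_m_s``.  Each replicate resamples subjects with replacement, recomputes
    condition-mean observed durations, refits alpha, and recomputes the
    predictions.  Returns replicate arrays, means and percentile CIs.
    Deterministic given ``seed``; failed replicates are skipped and counted.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    rng = np.random.default_rng(seed)
    labels = [c.label for c in conditions]
    wide = subject_durations.pivot_table(
        index="subject_id", columns="condition", values="t_m_s"
    )[labels]
    subjects = wide.to_numpy()
    n_sub = subjects.shape[0]

    alphas, preds = [], []
    n_failed = 0
    for _ in range(n_rep):
        idx = rng.integers(0, n_sub, size=n_sub)
        means = subjects[idx].mean(axis=0)
        conds = [
            Condition(c.label, c.effective_mass, c.reaction_time, mu)
            for c, mu in zip(conditions, means)
        ]
        try:
            fit = fit_alpha(form, conds, metabolic, accuracy, resting_rate)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        alphas.append(fit.alpha)
        preds.append(fit.predictions)
    if not alphas:
        raise RuntimeError("all bootstrap replicates failed")
    alphas = np.asarray(alphas)
    preds = np.asarray(preds)
    return {
        "alpha": alphas,
        "alpha_mean": float(alphas.mean()),
        "alpha_ci": (
            float(np.percentile(alphas, 2.5)),
            float(np.percentile(alphas, 97.5)),
        ),
        "predictions": preds,
        "prediction_mean": preds.mean(axis=0),
        "prediction_ci_low": np.percentile(preds, 2.5, axis=0),
        "prediction_ci_high": np.percentile(preds, 97.5, axis=0),
        "n_failed": n_failed,
    }
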