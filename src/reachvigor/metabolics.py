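"""Metabolic cost of reaching: gas exchange to power, rate model, optima.

Indirect calorimetry gives O2 uptake and CO2 output; these convert to
metabolic power (W) through the Brockway equation.  Block-level power is
normalised to the gross metabolic rate attributable to moving time, and the
resulting rates are fit, across effective masses ``m`` and movement
durations ``t_m``, to

    rate(m, t_m) = a + b * m**i / t_m**j            (base model)
    rate(m, t_m) = a * m**k + b * m**i / t_m**j     (alternative model)

Multiplying by duration gives the gross cost of a single movement,

    cost(m, t_m) = a*t_m + b * m**i * t_m**(1-j),

which for j > 1 is convex in t_m with an interior minimum at

    t* = ((j - 1) * b * m**i / a)**(1/j),

the metabolically optimal movement duration.  Uncertainty on the optima is
quantified by case-resampling bootstrap of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "GasSeries",
    "BlockSummary",
    "MetabolicParams",
    "FitResult",
    "BootstrapResult",
    "brockway_power",
    "steady_state_power",
    "moving_rate",
    "cost_per_movement",
    "rate_model",
    "movement_cost",
    "optimal_duration",
    "minimum_cost",
    "fit_rate_model",
    "bootstrap_optimal_durations",
]

#: Brockway coefficients for flows in mL/s, output in W.
BROCKWAY_O2 = 16.58
BROCKWAY_CO2 = 4.51


@dataclass(frozen=True)
class GasSeries:
    """Gas-exchange time series: time (s), VO2 and VCO2 flows (mL/s)."""

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        vo2 = np.asarray(self.vo2, dtype=float)
        vco2 = np.asarray(self.vco2, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "vo2", vo2)
        object.__setattr__(self, "vco2", vco2)
        if not (len(t) == len(vo2) == len(vco2)):
            raise ValueError("time, vo2 and vco2 must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(vo2 < 0) or np.any(vco2 < 0):
            raise ValueError("gas flows must be non-negative")


@dataclass(frozen=True)
class BlockSummary:
    """Timing and power summary of one reaching block.

    ``T_m``: summed movement time in the steady-state window (s);
    ``T_trial``: total window time including reaction and intertrial periods;
    ``n``: number of movements; ``e_parvo``: measured average metabolic rate
    over the window (W); ``e_rest``: resting metabolic rate (W).
    """

    T_m: float
    T_trial: float
    n: int
    e_parvo: float
    e_rest: float

    def __post_init__(self) -> None:
        if not (0 < self.T_m <= self.T_trial):
            raise ValueError("require 0 < T_m <= T_trial")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class MetabolicParams:
    """Coefficients of the metabolic-rate model.

    ``a``: offset for the cost of not moving (W); ``b``: mass-speed scaling;
    ``i``: mass exponent; ``j``: duration exponent (j > 1 gives an interior
    cost minimum); ``k``: optional resting-mass exponent (alternative model).
    """

    a: float
    b: float
    i: float
    j: float
    k: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.b < 0:
            raise ValueError("b must be non-negative")


@dataclass
class FitResult:
    params: MetabolicParams
    se: dict[str, float]
    mse: float
    aic: float
    n_obs: int
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass
class BootstrapResult:
    """Per-mass bootstrap summary of the metabolically optimal duration."""

    masses: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    replicates: np.ndarray = field(repr=False, default=None)  # (n_rep, n_mass)
    n_failed: int = 0


def brockway_power(vo2, vco2):
    """Metabolic power (W) from O2 uptake and CO2 output in mL/s."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas flows must be non-negative")
    out = BROCKWAY_O2 * vo2 + BROCKWAY_CO2 * vco2
    return float(out) if out.ndim == 0 else out


def steady_state_power(series: GasSeries, window: float = 180.0) -> float:
    """Mean Brockway power over the trailing ``window`` seconds of a block."""
    t = series.time
    if t[-1] - t[0] < window:
        raise ValueError(
            f"series spans {t[-1] - t[0]:.1f} s, shorter than window {window:.1f} s"
        )
    mask = t >= t[-1] - window
    return float(np.mean(brockway_power(series.vo2[mask], series.vco2[mask])))


def moving_rate(block: BlockSummary) -> float:
    """Gross metabolic rate attributed to moving time (W).

    Removes the resting expenditure of the non-moving fraction of the window
    and reattributes the remainder to the time actually spent moving.
    """
    return (
        block.e_parvo * block.T_trial - block.e_rest * (block.T_trial - block.T_m)
    ) / block.T_m


def cost_per_movement(rate: float, T_m: float, n: int) -> float:
    """Gross cost of one movement (J): rate times average movement duration."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rate * (T_m / n)


def rate_model(params: MetabolicParams, m: float, t_m) -> float | np.ndarray:
    """Gross metabolic rate (W) at effective mass ``m`` and duration ``t_m``."""
    t_m = np.asarray(t_m, dtype=float)
    if np.any(t_m <= 0):
        raise ValueError("t_m must be positive")
    if m <= 0:
        raise ValueError("m must be positive")
    offset = params.a if params.k is None else params.a * m**params.k
    out = offset + params.b * m**params.i / t_m**params.j
    return float(out) if out.ndim == 0 else out


def movement_cost(params: MetabolicParams, m: float, t_m) -> float | np.ndarray:
    """Gross metabolic cost (J) of a movement of duration ``t_m``."""
    t_m = np.asarray(t_m, dtype=float)
    if np.any(t_m <= 0):
        raise ValueError("t_m must be positive")
    offset = params.a if params.k is None else params.a * m**params.k
    out = offset * t_m + params.b * m**params.i * t_m ** (1.0 - params.j)
    return float(out) if out.ndim == 0 else out


def optimal_duration(
    params: MetabolicParams,
    m: float,
    bounds: tuple[float, float] = (0.1, 3.0),
) -> float:
    """Movement duration (s) minimising the gross cost per movement.

    Closed form ``t* = ((j-1) * b * m**i / (a * m**k))**(1/j)`` (k = 0 for the
    base model); validated to lie within ``bounds``.
    """
    if params.j <= 1:
        raise ValueError("no interior minimum: duration exponent j must exceed 1")
    if params.b * m**params.i <= 0:
        raise ValueError("no interior minimum: b * m**i must be positive")
    offset = params.a if params.k is None else params.a * m**params.k
    t_star = ((params.j - 1) * params.b * m**params.i / offset) ** (1.0 / params.j)
    lo, hi = bounds
    if not (lo < t_star < hi):
        raise ValueError(
            f"stationary point {t_star:.4f} s falls outside bounds {bounds}"
        )
    return float(t_star)


def minimum_cost(params: MetabolicParams, m: float) -> float:
    """Gross cost (J) at the metabolically optimal duration."""
    return float(movement_cost(params, m, optimal_duration(params, m)))


def _model_fn(variant: str):
    if variant == "base":
        def f(X, a, b, i, j):
            m, t = X
            return a + b * m**i / t**j
        p0 = (100.0, 1.0, 1.0, 4.0)
        names = ("a", "b", "i", "j")
    elif variant == "alternative":
        def f(X, a, b, i, j, k):
            m, t = X
            return a * m**k + b * m**i / t**j
        p0 = (100.0, 1.0, 1.0, 4.0, 0.0)
        names = ("a", "b", "i", "j", "k")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return f, p0, names


def fit_rate_model(
    m,
    t_m,
    power,
    variant: str = "base",
    p0: tuple[float, ...] | None = None,
) -> FitResult:
    """Nonlinear least-squares fit of the metabolic-rate model.

    Parameters are fit on untransformed power in W.  AIC is computed under a
    Gaussian likelihood with the residual variance profiled out, constants
    included: ``n*log(2*pi*RSS/n) + n + 2*(p+1)``.
    """
    m = np.asarray(m, dtype=float)
    t_m = np.asarray(t_m, dtype=float)
    power = np.asarray(power, dtype=float)
    n = len(power)
    if not (len(m) == len(t_m) == n):
        raise ValueError("m, t_m and power must have equal length")
    if n < 8:
        raise ValueError("need at least 8 observations")
    if len(np.unique(m)) < 2:
        warnings.warn("single mass level: mass exponent i is unidentifiable")
    if len(np.unique(t_m)) < 3:
        raise ValueError("need at least 3 distinct durations")

    fn, default_p0, names = _model_fn(variant)
    if p0 is None:
        p0 = default_p0
    try:
        popt, pcov = optimize.curve_fit(
            fn, (m, t_m), power, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise RuntimeError(f"metabolic-rate fit failed to converge: {exc}") from exc

    resid = power - fn((m, t_m), *popt)
    rss = float(np.sum(resid**2))
    p = len(popt)
    mse = rss / n
    aic = n * np.log(2 * np.pi * max(rss, 1e-300) / n) + n + 2 * (p + 1)
    se = {
        nm: float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else np.nan
        for nm, v in zip(names, np.diag(pcov))
    }
    kwargs = dict(zip(names, popt))
    params = MetabolicParams(**kwargs)
    return FitResult(params=params, se=se, mse=mse, aic=aic, n_obs=n, residuals=resid)


def bootstrap_optimal_durations(
    m,
    t_m,
    power,
    masses,
    n_rep: int = 1000,
    seed: int | None = None,
    variant: str = "base",
    bounds: tuple[float, float] = (0.1, 3.0),
) -> BootstrapResult:
    """Case-resampling bootstrap of the metabolically optimal durations.

    Each replicate resamples observations with replacement, refits the rate
    model, and evaluates the optimal duration at every mass in ``masses``.
    Replicates whose fit fails or whose optimum leaves ``bounds`` are skipped
    and counted.  Deterministic given ``seed``.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    m = np.asarray(m, dtype=float)
    t_m = np.asarray(t_m, dtype=float)
    power = np.asarray(power, dtype=float)
    masses = np.asarray(masses, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(power)

    # warm start from the full-data fit
    full = fit_rate_model(m, t_m, power, variant=variant)
    fn, _, names = _model_fn(variant)
    p_full = tuple(getattr(full.params, nm) for nm in names)

    reps = []
    n_failed = 0
    for _ in range(n_rep):
        idx = rng.integers(0, n, size=n)
        try:
            res = fit_rate_model(
                m[idx], t_m[idx], power[idx], variant=variant, p0=p_full
            )
            row = [optimal_duration(res.params, mm, bounds=bounds) for mm in masses]
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        reps.append(row)
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    reps = np.asarray(reps)
    return BootstrapResult(
        masses=masses,
        mean=reps.mean(axis=0),
        ci_low=np.percentile(reps, 2.5, axis=0),
        ci_high=np.percentile(reps, 97.5, axis=0),
        replicates=reps,
        n_failed=n_failed,
    )
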