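"""Speed-accuracy tradeoff: success labelling and logistic fitting.

A trial's success depends on the target geometry (circle, radial arc, or
open quadrant).  The probability of success is modelled as a logistic in
movement duration ``t_m`` and effective mass ``m``:

    logit P = beta0 + beta1 * t_m + beta2 * m

fit by a logit-linked binomial mixed model with a per-subject random
intercept (variational approximation), falling back to an ordinary logistic
regression when subject structure is absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SuccessCriterion",
    "SpeedAccuracyParams",
    "SpeedAccuracyFit",
    "SeparationError",
    "label_success",
    "success_probability",
    "fit_speed_accuracy",
]


class SeparationError(ValueError):
    """Raised when the logistic outcome is perfectly separated."""


@dataclass(frozen=True)
class SuccessCriterion:
    """Target geometry defining trial success.

    ``circle``: endpoint error strictly less than ``radius``.
    ``arc``: maximum excursion strictly inside ``radial_band`` and absolute
    angular error strictly below ``angular_limit_deg``.  The angular limit
    defaults to the full 7-degree arc width applied to the error magnitude;
    pass 3.5 for the geometric half-width reading.
    ``quadrant``: always successful (out-and-back, no stopping criterion).
    """

    kind: str
    radius: float = 0.014
    radial_band: tuple[float, float] = (0.10, 0.11)
    angular_limit_deg: float = 7.0

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "arc", "quadrant"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        lo, hi = self.radial_band
        if not (0 < lo < hi):
            raise ValueError("radial_band must satisfy 0 < lower < upper")
        if self.angular_limit_deg <= 0:
            raise ValueError("angular_limit_deg must be positive")

    @classmethod
    def circle(cls, radius: float = 0.014) -> "SuccessCriterion":
        return cls(kind="circle", radius=radius)

    @classmethod
    def arc(
        cls,
        radial_band: tuple[float, float] = (0.10, 0.11),
        angular_limit_deg: float = 7.0,
    ) -> "SuccessCriterion":
        return cls(kind="arc", radial_band=radial_band, angular_limit_deg=angular_limit_deg)

    @classmethod
    def quadrant(cls) -> "SuccessCriterion":
        return cls(kind="quadrant")


@dataclass(frozen=True)
class SpeedAccuracyParams:
    """Logistic coefficients: intercept, duration slope (1/s), mass slope (1/kg)."""

    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "beta2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SpeedAccuracyFit:
    params: SpeedAccuracyParams
    se: dict[str, float]
    random_intercept_sd: float | None
    method: str  # "mixed_vb" or "fixed_logit"


def label_success(metrics, criterion: SuccessCriterion) -> bool:
    """Label one trial as success under the criterion (strict inequalities).

    ``metrics`` may be a :class:`~reachvigor.kinematics.TrialMetrics`, a
    mapping, or a pandas row exposing ``endpoint_error_m``,
    ``max_excursion_m`` and ``angular_error_deg`` as needed by the kind.
    """

    def get(name: str) -> float:
        if hasattr(metrics, name):
            return getattr(metrics, name)
        try:
            return metrics[name]
        except (KeyError, TypeError) as exc:
            raise ValueError(
                f"criterion {criterion.kind!r} needs metric {name!r}"
            ) from exc

    if criterion.kind == "circle":
        return bool(get("endpoint_error_m") < criterion.radius)
    if criterion.kind == "arc":
        lo, hi = criterion.radial_band
        exc = get("max_excursion_m")
        ang = get("angular_error_deg")
        return bool(lo < exc < hi and abs(ang) < criterion.angular_limit_deg)
    return True  # quadrant: crossing is the only requirement


def success_probability(params: SpeedAccuracyParams, t_m, m) -> float | np.ndarray:
    """P(success | t_m, m) under the logistic speed-accuracy model."""
    t_m = np.asarray(t_m, dtype=float)
    if np.any(t_m <= 0):
        raise ValueError("t_m must be positive")
    z = params.beta0 + params.beta1 * t_m + params.beta2 * np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def fit_speed_accuracy(
    success,
    t_m,
    m,
    subject_ids=None,
    method: str = "auto",
) -> SpeedAccuracyFit:
    """Fit the speed-accuracy logistic.

    With ``subject_ids`` spanning at least two subjects (and ``method`` not
    forced to ``"fixed"``), a binomial mixed model with per-subject random
    intercepts is fit by the variational Bayes approximation in statsmodels;
    otherwise an ordinary logistic regression is used and flagged in the
    result.  Reported estimates and standard errors are the fixed effects.
    """
    y = np.asarray(success, dtype=float)
    t_m = np.asarray(t_m, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (len(y) == len(t_m) == len(m)):
        raise ValueError("success, t_m and m must have equal length")
    if y.min() == y.max():
        raise SeparationError(
            "all outcomes identical: logistic coefficients are not identifiable"
        )

    X = sm.add_constant(np.column_stack([t_m, m]))
    use_mixed = (
        method in ("auto", "mixed")
        and subject_ids is not None
        and pd.Series(subject_ids).nunique() >= 2
    )
    if use_mixed:
        groups = pd.Categorical(pd.Series(subject_ids).astype(str))
        exog_vc = pd.get_dummies(groups).to_numpy(dtype=float)
        ident = np.zeros(exog_vc.shape[1], dtype=int)
        model = sm.BinomialBayesMixedGLM(y, X, exog_vc, ident)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_vb()
        beta = fit.fe_mean
        se = fit.fe_sd
        re_sd = float(np.exp(fit.vcp_mean[0]))
        how = "mixed_vb"
    else:
        if method == "mixed":
            raise ValueError("mixed fit requested but fewer than 2 subjects given")
        try:
            fit = sm.Logit(y, X).fit(disp=False)
        except Exception as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(fit.bse)):
            raise SeparationError(
                "non-finite standard errors: outcome is (quasi-)separated"
            )
        beta = fit.params
        se = fit.bse
        re_sd = None
        how = "fixed_logit"

    if not np.all(np.isfinite(beta)):
        raise SeparationError("non-finite coefficient estimates")
    params = SpeedAccuracyParams(beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]))
    if params.beta1 <= 0 or params.beta2 >= 0:
        warnings.warn(
            "fitted signs deviate from the expected speed-accuracy pattern "
            "(beta1 > 0, beta2 < 0)"
        )
    return SpeedAccuracyFit(
        params=params,
        se={"beta0": float(se[0]), "beta1": float(se[1]), "beta2": float(se[2])},
        random_intercept_sd=re_sd,
        method=how,
    )
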