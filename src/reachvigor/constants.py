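"""Published group-level constants packaged for reproduction.

These are the group-average quantities reported for the four reaching
experiments: the fitted metabolic-rate parameters, cohort-mean effective
masses per added-mass condition, speed-accuracy logistic coefficients,
reaction times, observed mean movement durations, resting metabolic rate,
and the task geometry.  Downstream analyses default to these constants so
that table reproduction does not depend on anthropometric refits.
"""

from __future__ import annotations

from .accuracy import SpeedAccuracyParams, SuccessCriterion
from .metabolics import MetabolicParams

#: Fitted metabolic-rate model (W): a + b * m**i / t_m**j.
METABOLIC_PARAMS = MetabolicParams(a=98.25, b=0.86, i=0.83, j=5.83)

#: Cohort-mean resting metabolic rate (W).
RESTING_RATE_W = 73.33
#: Standard error of the resting rate across the 8 metabolic-cohort subjects.
RESTING_RATE_SE_W = 3.60

#: Cohort-mean effective mass (kg) per added mass (kg), by experiment.
#: Experiment 3 reuses the experiment-2 values.
EFFECTIVE_MASS_KG = {
    1: {0.0: 2.44, 2.27: 4.834, 4.55: 7.127, 9.09: 11.691},
    2: {0.0: 2.506, 1.36: 3.959, 2.27: 4.894, 3.64: 6.282},
    3: {0.0: 2.506, 1.36: 3.959, 2.27: 4.894, 3.64: 6.282},
    4: {0.0: 2.506, 1.36: 3.959, 2.27: 4.894, 3.64: 6.282},
}

#: Speed-accuracy logistic coefficients fit under each experiment's criterion.
SPEED_ACCURACY_PARAMS = {
    2: SpeedAccuracyParams(beta0=-1.20, beta1=5.96, beta2=-0.11),
    3: SpeedAccuracyParams(beta0=-2.81, beta1=6.06, beta2=-0.09),
}

#: Group-mean reaction times (s) per added-mass condition (ascending mass).
REACTION_TIMES_S = {
    2: (0.178, 0.185, 0.190, 0.196),
    3: (0.205, 0.215, 0.219, 0.229),
}

#: Group-mean observed movement durations (s) per condition (ascending mass).
OBSERVED_DURATIONS_S = {
    2: (0.780, 0.843, 0.867, 0.904),
    3: (0.846, 0.902, 0.927, 0.973),
}

#: Fitted reward parameter (bootstrap mean and 95% CI), from experiment 2.
ALPHA_BOOTSTRAP_MEAN = 57.182
ALPHA_CI = (36.669, 82.390)

#: Reaction-time dependence on added mass (s per kg added).
RT_MASS_SLOPE_PRESCRIBED = 2.40e-3   # speed-constrained reaching
RT_MASS_SLOPE_SELF_PACED = 5.61e-3   # self-paced reaching

#: Prescribed speed windows: name -> (lower s, upper s, trials per block).
SPEED_WINDOWS = {
    "VVS": (1.25, 1.35, 160),
    "VS": (1.05, 1.15, 170),
    "S": (0.85, 0.95, 200),
    "M": (0.65, 0.75, 220),
    "F": (0.45, 0.55, 240),
    "VF": (0.325, 0.425, 250),
    "VVF": (0.225, 0.275, 260),
}
#: Speed windows completed at each added mass in the metabolic experiment:
#: light masses take the six fastest windows, heavy masses the six slowest.
SPEED_WINDOWS_BY_MASS = {
    0.0: ("VS", "S", "M", "F", "VF", "VVF"),
    2.27: ("VS", "S", "M", "F", "VF", "VVF"),
    4.55: ("VVS", "VS", "S", "M", "F", "VF"),
    9.09: ("VVS", "VS", "S", "M", "F", "VF"),
}

#: Task geometry (m / deg).
TARGET_DISTANCE_M = 0.10
TARGET_RADIUS_M = 0.014
HOME_RADIUS_M = 0.011
CURSOR_RADIUS_M = 0.004
DIRECTIONS_DEG = (45.0, 135.0, 225.0, 315.0)
ARC_RADIAL_BAND_M = (0.10, 0.11)
ARC_WIDTH_DEG = 7.0

#: Success criterion per experiment.
SUCCESS_CRITERIA = {
    1: SuccessCriterion.circle(TARGET_RADIUS_M),
    2: SuccessCriterion.circle(TARGET_RADIUS_M),
    3: SuccessCriterion.arc(ARC_RADIAL_BAND_M, ARC_WIDTH_DEG),
    4: SuccessCriterion.quadrant(),
}

#: Cohort anthropometrics (mean body mass kg, mean height m), by experiment.
COHORT_ANTHROPOMETRY = {
    1: (66.7, 1.734),
    2: (68.4, 1.736),
    3: (67.5, 1.715),
}

#: Sampling rate of the kinematic recordings (Hz).
SAMPLING_RATE_HZ = 200.0
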