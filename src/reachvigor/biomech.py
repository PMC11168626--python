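"""Effective mass of a two-link planar arm with a point mass at the hand.

The scalar inertia felt at the hand ("effective mass") is anisotropic: it
depends on arm posture and on the direction in which the hand is
accelerated.  It is obtained from the operational-space mass matrix

    M = (J^-1)^T I(theta) J^-1

where ``J`` is the planar two-link Jacobian and ``I(theta)`` the joint-space
inertia matrix of the arm (upper arm; forearm+hand segment; optional point
mass added at the hand).  Applying a unit acceleration along a direction
``u`` and taking the magnitude of the required hand force, ``||M u||``,
gives the effective mass in that direction.

Segment parameters are built from standard anthropometric regressions
(Winter's segment-parameter table) and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ArmModel",
    "Posture",
    "SingularPostureError",
    "WINTER_COEFFICIENTS",
    "build_arm_model",
    "combined_centroid",
    "jacobian",
    "inertia_matrix",
    "operational_mass_matrix",
    "effective_mass_direction",
    "mean_effective_mass",
    "inverse_kinematics",
    "DEFAULT_DIRECTIONS_DEG",
    "DEFAULT_HOME",
]

#: Reach directions used throughout the protocol (degrees from right horizontal).
DEFAULT_DIRECTIONS_DEG = (45.0, 135.0, 225.0, 315.0)

#: Default home-circle position relative to the shoulder (m): 25 cm anterior.
DEFAULT_HOME = (0.0, 0.25)

#: Winter's anthropometric regression coefficients.  Lengths as fractions of
#: stature H; masses as fractions of body mass M; centroid location and
#: radius of gyration as fractions of the segment length.
WINTER_COEFFICIENTS = {
    "upper_arm_length": 0.186,
    "forearm_length": 0.146,       # elbow to wrist
    "hand_length": 0.108,
    "hand_com": 0.506,             # wrist to hand COM, fraction of hand length
    "upper_arm_mass": 0.028,
    "forearm_hand_mass": 0.022,
    "upper_arm_com": 0.436,
    "forearm_hand_com": 0.682,     # fraction of forearm length, from elbow
    "upper_arm_rho": 0.322,
    "forearm_hand_rho": 0.468,
}


class SingularPostureError(ValueError):
    """Raised when the arm posture makes the Jacobian non-invertible."""


@dataclass(frozen=True)
class ArmModel:
    """Segment parameters of a two-link arm (bare, without added mass).

    Attributes
    ----------
    l1, l2
        Upper-arm length and elbow-to-hand length (m).
    m1, m2
        Upper-arm mass and forearm+hand mass (kg).
    r1, r2
        Centroid distances of the upper arm (from shoulder) and of the
        forearm+hand segment (from elbow), in metres.
    I_com1, I_com2
        Segment moments of inertia about their own centres of mass (kg m^2).
    """

    l1: float
    l2: float
    m1: float
    m2: float
    r1: float
    r2: float
    I_com1: float
    I_com2: float

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "m1", "m2", "r1", "r2", "I_com1", "I_com2"):
            if getattr(self, name) < 0:
                raise ValueError(f"ArmModel.{name} must be non-negative")
        if self.r1 > self.l1:
            raise ValueError("upper-arm centroid r1 cannot exceed l1")
        if self.r2 > self.l2:
            raise ValueError("forearm centroid r2 cannot exceed l2")


@dataclass(frozen=True)
class Posture:
    """Shoulder and elbow joint angles (rad).

    ``theta_e`` must lie in (0, pi) for an invertible Jacobian.
    """

    theta_s: float
    theta_e: float

    @property
    def is_singular(self) -> bool:
        return abs(np.sin(self.theta_e)) < 1e-9


def build_arm_model(
    body_mass: float,
    height: float,
    coefficients: dict | None = None,
) -> ArmModel:
    """Construct arm segment parameters from anthropometric regressions.

    Parameters
    ----------
    body_mass
        Whole-body mass (kg), > 0.
    height
        Stature (m), > 0.
    coefficients
        Optional overrides for :data:`WINTER_COEFFICIENTS` entries.
    """
    if body_mass <= 0 or height <= 0:
        raise ValueError("body_mass and height must be positive")
    c = dict(WINTER_COEFFICIENTS)
    if coefficients:
        unknown = set(coefficients) - set(c)
        if unknown:
            raise ValueError(f"unknown anthropometric coefficients: {sorted(unknown)}")
        c.update(coefficients)

    l1 = c["upper_arm_length"] * height
    lf = c["forearm_length"] * height
    lh = c["hand_length"] * height
    # Reach point = hand centre (robot handle in the palm).
    l2 = lf + c["hand_com"] * lh
    m1 = c["upper_arm_mass"] * body_mass
    m2 = c["forearm_hand_mass"] * body_mass
    r1 = c["upper_arm_com"] * l1
    r2 = c["forearm_hand_com"] * lf
    I1 = m1 * (c["upper_arm_rho"] * l1) ** 2
    I2 = m2 * (c["forearm_hand_rho"] * lf) ** 2
    return ArmModel(l1=l1, l2=l2, m1=m1, m2=m2, r1=r1, r2=r2, I_com1=I1, I_com2=I2)


def combined_centroid(arm: ArmModel, added_mass: float) -> float:
    """Mass-weighted centroid r22 of the forearm+hand plus a point mass at the hand.

    With zero added mass this is the bare segment centroid ``arm.r2``; as the
    added mass dominates, it approaches the hand position ``arm.l2``.
    """
    if added_mass < 0:
        raise ValueError("added_mass must be non-negative")
    total = arm.m2 + added_mass
    if total == 0:
        return arm.l2
    return (arm.m2 * arm.r2 + added_mass * arm.l2) / total


def jacobian(arm: ArmModel, posture: Posture) -> np.ndarray:
    """Planar two-link Jacobian dx/dtheta (2x2)."""
    ts, te = posture.theta_s, posture.theta_e
    s1, c1 = np.sin(ts), np.cos(ts)
    s12, c12 = np.sin(ts + te), np.cos(ts + te)
    return np.array(
        [
            [-arm.l1 * s1 - arm.l2 * s12, -arm.l2 * s12],
            [arm.l1 * c1 + arm.l2 * c12, arm.l2 * c12],
        ]
    )


def inertia_matrix(arm: ArmModel, added_mass: float, posture: Posture) -> np.ndarray:
    """Joint-space inertia matrix I(theta) of the loaded arm (2x2, symmetric).

    The forearm+hand segment and the added point mass at the hand are treated
    as one composite rigid body on link 2, with combined mass ``m2 + added``,
    centroid ``r22`` (see :func:`combined_centroid`) and centroidal inertia
    transferred by the parallel-axis theorem.  This is algebraically identical
    to summing the Lagrangian contributions of the segment and the point mass
    separately; in particular the (2, 2) entry equals
    ``m2*r2**2 + added*l2**2 + I_com2``.
    """
    if added_mass < 0:
        raise ValueError("added_mass must be non-negative")
    m2c = arm.m2 + added_mass
    r22 = combined_centroid(arm, added_mass)
    # parallel-axis transfer of the segment and point-mass inertias to r22
    I2c = (
        arm.I_com2
        + arm.m2 * (arm.r2 - r22) ** 2
        + added_mass * (arm.l2 - r22) ** 2
    )
    ce = np.cos(posture.theta_e)
    l1 = arm.l1
    i11 = (
        arm.m1 * arm.r1**2
        + arm.I_com1
        + m2c * (l1**2 + r22**2 + 2 * l1 * r22 * ce)
        + I2c
    )
    i12 = m2c * (r22**2 + l1 * r22 * ce) + I2c
    i22 = m2c * r22**2 + I2c
    return np.array([[i11, i12], [i12, i22]])


def operational_mass_matrix(
    arm: ArmModel, added_mass: float, posture: Posture
) -> np.ndarray:
    """Operational-space (endpoint) mass matrix M = J^-T I J^-1."""
    if posture.is_singular:
        raise SingularPostureError(
            f"degenerate posture theta_e={posture.theta_e:.6g} rad: "
            "Jacobian is singular (straight or folded arm)"
        )
    J = jacobian(arm, posture)
    Jinv = np.linalg.inv(J)
    return Jinv.T @ inertia_matrix(arm, added_mass, posture) @ Jinv


def effective_mass_direction(
    arm: ArmModel, added_mass: float, posture: Posture, direction: float
) -> float:
    """Effective mass (kg) for a unit hand acceleration along ``direction`` (rad).

    Magnitude of the hand force required to produce a unit acceleration in
    the given direction: ``||M u||``.  Invariant under direction -> direction+pi.
    """
    M = operational_mass_matrix(arm, added_mass, posture)
    u = np.array([np.cos(direction), np.sin(direction)])
    return float(np.linalg.norm(M @ u))


def inverse_kinematics(x: float, y: float, arm: ArmModel) -> Posture:
    """Joint angles placing the hand at (x, y) relative to the shoulder.

    Returns the elbow-positive branch (theta_e in (0, pi)).  Raises if the
    point is outside the reachable annulus.
    """
    d2 = x * x + y * y
    c = (d2 - arm.l1**2 - arm.l2**2) / (2 * arm.l1 * arm.l2)
    if c > 1 + 1e-12 or c < -1 - 1e-12:
        raise ValueError(f"point ({x:.3f}, {y:.3f}) is out of reach for this arm")
    te = float(np.arccos(np.clip(c, -1.0, 1.0)))
    ts = float(
        np.arctan2(y, x)
        - np.arctan2(arm.l2 * np.sin(te), arm.l1 + arm.l2 * np.cos(te))
    )
    return Posture(theta_s=ts, theta_e=te)


def mean_effective_mass(
    arm: ArmModel,
    added_mass: float,
    directions_deg: tuple[float, ...] = DEFAULT_DIRECTIONS_DEG,
    home: tuple[float, float] = DEFAULT_HOME,
    evaluation_distance: float = 0.05,
) -> float:
    """Effective mass averaged over reach directions.

    For each target direction the posture is taken from inverse kinematics at
    the reach midpoint, ``evaluation_distance`` metres from the home position
    (which is expressed in shoulder coordinates).
    """
    if len(directions_deg) == 0:
        raise ValueError("directions_deg must be non-empty")
    vals = []
    hx, hy = home
    for deg in directions_deg:
        th = np.radians(deg)
        px = hx + evaluation_distance * np.cos(th)
        py = hy + evaluation_distance * np.sin(th)
        posture = inverse_kinematics(px, py, arm)
        vals.append(effective_mass_direction(arm, added_mass, posture, th))
    return float(np.mean(vals))


def scaled_arm(arm: ArmModel, **overrides: float) -> ArmModel:
    """Return a copy of ``arm`` with selected fields replaced."""
    return replace(arm, **overrides)
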