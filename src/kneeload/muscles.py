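"""Moment-arm model and the deterministic moment-to-muscle-force reduction.

The reduction distributes net joint moments to a small set of muscle groups
in a fixed sequence rather than by optimisation:

1. the ankle plantarflexion moment is shared by gastrocnemius and soleus,
2. the hip extension moment is shared by hamstrings and gluteus maximus,
3. the quadriceps force balances the net knee extension demand plus the
   knee-flexion contributions of the biarticular muscles computed in steps
   1-2 (co-contraction); the gastrocnemius and hamstrings are the
   biarticular knee flexors entering this balance.

Within a joint, agonists share the moment in proportion to their
cross-sectional areas::

    F_m = CSA_m * M / sum_j r_j * CSA_j

which satisfies moment closure ``sum_m r_m * F_m = M`` exactly.  Moments in
the antagonist direction produce zero force for the group (muscles only
pull).  Residual tibial shear and frontal-plane distraction loads are
assigned to the cruciate and collateral ligaments by sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KNEE_STRUCTURES, LIGAMENTS, MUSCLES, default_model_config
from .subjects import SubjectProfile
from .trial import TrialTimeSeries


def height_scale_factor(group_mean_height_m: float, grand_mean_height_m: float) -> float:
    """Dimensionless hip/ankle moment-arm scale: group mean over grand mean.

    Hip and ankle moment arms from the literature are not gender-specific;
    they are made so by scaling with the ratio of the gender-group mean
    height to the grand mean height of the cohort (e.g. 1.75 m / 1.69 m for
    men).
    """
    if group_mean_height_m <= 0 or grand_mean_height_m <= 0:
        raise ValueError("heights must be positive")
    return group_mean_height_m / grand_mean_height_m


class _Poly:
    """Polynomial of joint angle with a declared validity range.

    Evaluation outside the range clamps the angle to the boundary and emits
    a warning: silent extrapolation of fitted quadratics is dangerous.
    """

    def __init__(self, coeffs, angle_range, name: str):
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.lo, self.hi = float(angle_range[0]), float(angle_range[1])
        self.name = name

    def __call__(self, angle):
        angle = np.asarray(angle, dtype=float)
        if np.any(angle < self.lo) or np.any(angle > self.hi):
            warnings.warn(
                f"{self.name}: angle outside [{self.lo}, {self.hi}] rad; clamped",
                RuntimeWarning,
                stacklevel=2,
            )
            angle = np.clip(angle, self.lo, self.hi)
        return np.polynomial.polynomial.polyval(angle, self.coeffs)


@dataclass
class MomentArmModel:
    """Per-gender moment arms and line-of-action orientations.

    Moment arms (m) and orientations (rad, relative to the tibial long axis)
    are polynomials of the relevant joint angle.  ``height_scale`` multiplies
    hip and ankle arms only; knee arms are already gender-specific.
    """

    gender: str
    height_scale: float = 1.0
    config: dict = field(default_factory=default_model_config)

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValueError(f"no moment-arm variant for gender {self.gender!r}")
        if self.height_scale <= 0:
            raise ValueError("height_scale must be positive")
        arms = self.config["moment_arms"][self.gender]
        self._arms = {
            key: _Poly(entry["coeffs"], entry["angle_range"], f"arm {key} ({self.gender})")
            for key, entry in arms.items()
        }
        orient = self.config["knee_orientation"][self.gender]
        self._orient = {
            key: _Poly(entry["coeffs"], entry["angle_range"], f"orientation {key} ({self.gender})")
            for key, entry in orient.items()
        }

    @classmethod
    def for_subject(
        cls, subject: SubjectProfile, config: dict | None = None
    ) -> "MomentArmModel":
        """Model for a subject, with hip/ankle arms height-scaled using the
        configured gender-group and grand mean heights."""
        config = config or default_model_config()
        heights = config["heights"]
        group = heights[f"{subject.gender}_mean_m"]
        scale = height_scale_factor(group, heights["grand_mean_m"])
        return cls(subject.gender, scale, config)

    def arm(self, muscle: str, joint: str, angle) -> np.ndarray:
        """Moment arm (m) of ``muscle`` about ``joint`` at ``angle`` (rad)."""
        key = f"{muscle}_{joint}"
        if key not in self._arms:
            raise KeyError(f"no moment arm configured for {key!r}")
        r = self._arms[key](angle)
        if joint in ("hip", "ankle"):
            r = r * self.height_scale
        return r

    def orientation(self, structure: str, knee_angle) -> np.ndarray:
        """Line-of-action angle (rad) of a knee-crossing structure."""
        if structure not in self._orient:
            raise KeyError(f"no orientation configured for {structure!r}")
        return self._orient[structure](knee_angle)

    def frontal_arm_fraction(self, structure: str) -> float:
        """Signed frontal-plane arm about the lateral contact point, as a
        fraction of the midcondylar distance (−0.5 = acts through the joint
        centre)."""
        return float(self.config["frontal_arm_fraction"][structure])

    @property
    def csa_cm2(self) -> dict:
        return dict(self.config["csa_cm2"])


def distribute_moment(moment, arms: dict, csa_cm2: dict) -> dict:
    """CSA-proportional distribution of an agonist moment to muscle forces.

    Parameters
    ----------
    moment : float or ndarray
        Net joint moment in the agonist direction (N·m); values <= 0 yield
        zero force for every muscle in the group.
    arms : dict of muscle -> moment arm (m), scalar or per-sample array.
    csa_cm2 : dict of muscle -> cross-sectional area (cm^2).

    Returns
    -------
    dict of muscle -> force (N), same shape as ``moment``; satisfies
    ``sum_m r_m F_m = moment`` exactly wherever ``moment > 0``.
    """
    moment = np.asarray(moment, dtype=float)
    denom = None
    for muscle, r in arms.items():
        r = np.asarray(r, dtype=float)
        if np.any((r == 0) & (moment != 0)):
            raise ValueError(f"zero moment arm for {muscle!r} with nonzero moment")
        term = r * csa_cm2[muscle]
        denom = term if denom is None else denom + term
    gate = moment > 0
    forces = {}
    for muscle, r in arms.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(gate, csa_cm2[muscle] * moment / denom, 0.0)
        forces[muscle] = f if moment.ndim else float(f)
    return forces


def quadriceps_force(knee_ext_moment, biarticular: dict, r_quad) -> np.ndarray:
    """Quadriceps force balancing extension demand plus co-contraction.

    ``biarticular`` maps each biarticular knee flexor to a tuple
    ``(force_n, knee_flexion_arm_m)``; their flexion torque must be
    counteracted by the quadriceps in addition to the net extension demand::

        F_quad = max(0, (M_ext + sum_b r_b * F_b) / r_quad)

    The result is clamped at zero (muscles only pull).
    """
    m = np.asarray(knee_ext_moment, dtype=float)
    r_quad = np.asarray(r_quad, dtype=float)
    if np.any(r_quad == 0):
        raise ValueError("quadriceps knee moment arm is zero")
    cocontraction = np.zeros_like(m)
    for force, arm in biarticular.values():
        cocontraction = cocontraction + np.asarray(arm, float) * np.asarray(force, float)
    f = np.maximum(0.0, (m + cocontraction) / r_quad)
    return f if f.ndim else float(f)


def ligament_forces(
    anterior_shear_n,
    frontal_distraction_n,
    knee_angle,
    model: MomentArmModel,
) -> dict:
    """Resolve residual joint loads into ligament forces.

    Anterior tibial shear (positive) is resisted by the ACL, posterior shear
    by the PCL — mutually exclusive by sign.  A frontal-plane distraction
    residual on the medial compartment (positive) loads the MCL, on the
    lateral compartment (negative) the LCL.  Each residual is divided by the
    cosine of the configured ligament orientation to give the force along the
    ligament line of action; all outputs are non-negative.
    """
    shear = np.asarray(anterior_shear_n, dtype=float)
    frontal = np.asarray(frontal_distraction_n, dtype=float)
    cos = {lig: np.cos(model.orientation(lig, knee_angle)) for lig in LIGAMENTS}
    out = {
        "acl": np.maximum(0.0, shear) / cos["acl"],
        "pcl": np.maximum(0.0, -shear) / cos["pcl"],
        "mcl": np.maximum(0.0, frontal) / cos["mcl"],
        "lcl": np.maximum(0.0, -frontal) / cos["lcl"],
    }
    if not shear.ndim and not frontal.ndim:
        out = {k: float(v) for k, v in out.items()}
    return out


@dataclass
class MuscleForceSet:
    """Per-sample forces (N) for the five muscle groups and four ligaments."""

    forces: pd.DataFrame  # columns = MUSCLES + LIGAMENTS

    def __post_init__(self) -> None:
        missing = [c for c in MUSCLES + LIGAMENTS if c not in self.forces.columns]
        if missing:
            raise ValueError(f"force set missing structures: {missing}")
        if (self.forces[MUSCLES + LIGAMENTS].to_numpy() < -1e-9).any():
            raise ValueError("muscle/ligament forces must be non-negative")

    def __getitem__(self, structure: str) -> np.ndarray:
        return self.forces[structure].to_numpy()

    def __len__(self) -> int:
        return len(self.forces)


def reduce_trial(
    trial: TrialTimeSeries,
    model: MomentArmModel,
    anterior_shear_n=None,
    frontal_distraction_n=None,
) -> MuscleForceSet:
    """Run the full reduction sequence on one trial.

    Net moments are consumed from the trial channels; the knee extension
    demand is the negative of ``knee_flex_moment``.  Residual shear /
    distraction loads for the ligaments default to zero (plain-table trials
    carry no residual channels).
    """
    csa = model.csa_cm2
    th_ankle = trial["ankle_flex_angle"]
    th_hip = trial["hip_flex_angle"]
    th_knee = trial["knee_flex_angle"]

    ankle = distribute_moment(
        trial["ankle_pf_moment"],
        {
            "gastrocnemius": model.arm("gastrocnemius", "ankle", th_ankle),
            "soleus": model.arm("soleus", "ankle", th_ankle),
        },
        csa,
    )
    hip = distribute_moment(
        trial["hip_ext_moment"],
        {
            "hamstrings": model.arm("hamstrings", "hip", th_hip),
            "gluteus_maximus": model.arm("gluteus_maximus", "hip", th_hip),
        },
        csa,
    )
    f_quad = quadriceps_force(
        -trial["knee_flex_moment"],
        {
            "hamstrings": (hip["hamstrings"], model.arm("hamstrings", "knee", th_knee)),
            "gastrocnemius": (
                ankle["gastrocnemius"],
                model.arm("gastrocnemius", "knee", th_knee),
            ),
        },
        model.arm("quadriceps", "knee", th_knee),
    )
    n = len(trial)
    shear = np.zeros(n) if anterior_shear_n is None else np.asarray(anterior_shear_n, float)
    frontal = (
        np.zeros(n) if frontal_distraction_n is None else np.asarray(frontal_distraction_n, float)
    )
    lig = ligament_forces(shear, frontal, th_knee, model)
    return MuscleForceSet(
        pd.DataFrame(
            {
                "gastrocnemius": ankle["gastrocnemius"],
                "soleus": ankle["soleus"],
                "hamstrings": hip["hamstrings"],
                "gluteus_maximus": hip["gluteus_maximus"],
                "quadriceps": f_quad,
                **{k: np.broadcast_to(v, (n,)) for k, v in lig.items()},
            }
        )
    )
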