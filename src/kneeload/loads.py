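"""Medial tibiofemoral contact force: the contact-point moment balance,
bodyweight / bodyweight·height scaling, and peak extraction.

The medial contact force is obtained by summing moments about the *lateral*
tibiofemoral contact point in the frontal plane::

    F_med = -( sum_i r_i F_i / d_hat  +  F_RJF / 2  +  tau_KAM / d_hat )

where ``r_i`` and ``F_i`` are the frontal-plane arm (about the lateral
contact point) and axial force of the i-th knee-crossing muscle or ligament,
``F_RJF`` the resultant (intersegmental) knee joint force, ``tau_KAM`` the
frontal-plane knee moment, and ``d_hat`` the distance between the medial and
lateral contact points.

Sign conventions (one table governs every term):

- compressive ``F_RJF`` is negative (so a pure resultant splits half to the
  medial side after the leading minus sign);
- ``tau_KAM`` is negative for adduction, which loads the medial compartment;
- a muscle acting through the joint centre has ``r_i = -d_hat/2``, so muscle
  compression likewise adds medial load.

Under physiological compression ``F_med`` comes out positive (N), and is
reported in bodyweights; knee moments are reported in BW·Ht.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import KNEE_STRUCTURES
from .muscles import MomentArmModel, MuscleForceSet
from .subjects import SubjectProfile
from .trial import PhaseWindow, TrialTimeSeries


def mjcf_sample(sum_r_f_nm, f_rjf_n, tau_kam_nm, d_hat_m):
    """Evaluate the contact-point moment balance for one or many samples.

    Parameters
    ----------
    sum_r_f_nm : float or ndarray
        Summed muscle/ligament moment terms ``sum_i r_i F_i`` (N·m) about the
        lateral contact point (negative under compression; see module
        conventions).
    f_rjf_n : float or ndarray
        Resultant knee joint force (N, compression negative).
    tau_kam_nm : float or ndarray
        Frontal-plane knee moment (N·m, adduction negative).
    d_hat_m : float
        Midcondylar (contact-point) distance in metres.

    Returns
    -------
    Medial contact force in newtons (positive = medial compression).
    """
    if d_hat_m <= 0:
        raise ValueError("midcondylar distance d_hat must be positive")
    sum_r_f_nm = np.asarray(sum_r_f_nm, dtype=float)
    f_med = -(sum_r_f_nm / d_hat_m + np.asarray(f_rjf_n, float) / 2.0 + np.asarray(tau_kam_nm, float) / d_hat_m)
    return f_med if f_med.ndim else float(f_med)


def scale_by_bodyweight(force_n, bodyweight_n: float):
    """Force in multiples of bodyweight."""
    if bodyweight_n <= 0:
        raise ValueError("bodyweight must be positive")
    out = np.asarray(force_n, dtype=float) / bodyweight_n
    return out if out.ndim else float(out)


def scale_moment(moment_nm, bodyweight_n: float, height_m: float):
    """Moment in multiples of bodyweight × height (dimensionless)."""
    if bodyweight_n <= 0 or height_m <= 0:
        raise ValueError("bodyweight and height must be positive")
    out = np.asarray(moment_nm, dtype=float) / (bodyweight_n * height_m)
    return out if out.ndim else float(out)


@dataclass
class JointLoadSeries:
    """Per-sample knee loading derived from one trial.

    ``f_med_n`` is the medial contact force (N); ``f_med_bw`` the same in
    bodyweights.  ``tau_kam_nm`` keeps the signed frontal-plane convention
    (adduction negative); ``kam_mag_nm`` is the adduction magnitude used for
    peak reporting.  ``kfm_nm`` is the *external* knee flexion moment (equal
    to the internal extension demand), the quantity conventionally
    normalised by BW·Ht in gait studies.
    """

    f_rjf_n: np.ndarray
    tau_kam_nm: np.ndarray
    kfm_nm: np.ndarray
    f_med_n: np.ndarray
    f_med_bw: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.f_med_n)
        for name in ("f_rjf_n", "tau_kam_nm", "kfm_nm", "f_med_bw"):
            if len(getattr(self, name)) != n:
                raise ValueError("joint-load channels must have equal length")
        if not np.all(np.isfinite(self.f_med_n)):
            raise ValueError("medial contact force must be finite")

    @property
    def kam_mag_nm(self) -> np.ndarray:
        return np.maximum(0.0, -self.tau_kam_nm)

    def __len__(self) -> int:
        return len(self.f_med_n)


def compute_joint_loads(
    trial: TrialTimeSeries,
    forces: MuscleForceSet,
    model: MomentArmModel,
    subject: SubjectProfile,
) -> JointLoadSeries:
    """Evaluate the contact-force balance over a whole trial.

    The resultant knee joint force is approximated quasi-statically by the
    vertical ground reaction force (``F_RJF = -fz``, compression negative);
    full 3-D inverse dynamics is upstream of this package.  Each
    knee-crossing structure contributes its axial component
    ``F_i cos(phi_i(theta_knee))`` at the configured frontal-plane arm
    fraction of the midcondylar distance.
    """
    th_knee = trial["knee_flex_angle"]
    d_hat = subject.midcondylar_d_m
    sum_rf = np.zeros(len(trial))
    for structure in KNEE_STRUCTURES:
        axial = forces[structure] * np.cos(model.orientation(structure, th_knee))
        sum_rf += model.frontal_arm_fraction(structure) * d_hat * axial
    f_rjf = -trial["fz"]
    tau = trial["knee_add_moment"]
    f_med = mjcf_sample(sum_rf, f_rjf, tau, d_hat)
    return JointLoadSeries(
        f_rjf_n=f_rjf,
        tau_kam_nm=tau,
        kfm_nm=-trial["knee_flex_moment"],
        f_med_n=f_med,
        f_med_bw=scale_by_bodyweight(f_med, subject.bodyweight_n),
    )


@dataclass
class PeakSummary:
    """Peak knee loads for one trial window.

    Walking windows yield two peaks per quantity (first and second half of
    stance); other movements yield one.  MJCF peaks are in BW, moment peaks
    in BW·Ht.
    """

    movement: str
    mjcf_peaks_bw: list
    kam_peaks_bwht: list
    kfm_peaks_bwht: list


def _window_peaks(values: np.ndarray, window: PhaseWindow, two_peaks: bool) -> list:
    seg = values[window.slice()]
    if len(seg) == 0:
        raise ValueError("empty peak-extraction window")
    if not two_peaks:
        return [float(np.max(seg))]
    half = len(seg) // 2
    if half == 0:
        return [float(np.max(seg)), float(np.max(seg))]
    return [float(np.max(seg[:half])), float(np.max(seg[half:]))]


def extract_peaks(
    loads: JointLoadSeries,
    window: PhaseWindow,
    movement: str,
    subject: SubjectProfile,
) -> PeakSummary:
    """Extract movement-appropriate peaks from a phase window.

    Walking stance is split at its midpoint and each half contributes one
    peak (the classic double-hump pattern); running and sit/stand movements
    contribute a single peak.
    """
    if window.end_index > len(loads):
        raise ValueError("window extends past the trial")
    two = movement == "walk"
    bw, ht = subject.bodyweight_n, subject.height_m
    return PeakSummary(
        movement=movement,
        mjcf_peaks_bw=_window_peaks(loads.f_med_bw, window, two),
        kam_peaks_bwht=[
            p / (bw * ht) for p in _window_peaks(loads.kam_mag_nm, window, two)
        ],
        kfm_peaks_bwht=[
            p / (bw * ht) for p in _window_peaks(loads.kfm_nm, window, two)
        ],
    )


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Symmetric percent difference: |a−b| over the mean of the means, ×100."""
    denom = (mean_a + mean_b) / 2.0
    if denom == 0:
        raise ValueError("percent difference undefined for zero mean of means")
    return abs(mean_a - mean_b) / denom * 100.0
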