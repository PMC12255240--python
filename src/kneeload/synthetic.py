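"""Synthetic study inputs with known ground truth.

The study's raw motion-capture exports are not deposited, so every
downstream stage is exercised on generated data: gait and sit-to-stand
trials with planted muscle forces, pseudo-ultrasound tile sets with planted
landmarks, and two-way rating tables with planted variance components.

Design of the gait/STS generators:

- curves are built from smooth low-order bases (raised-cosine bumps and
  half-cosine steps) whose spectral content lies below the conditioning
  cutoffs, so filtering cannot distort the planted ground truth;
- net joint moments are CONSTRUCTED from the planted muscle forces through
  the same moment-arm model the reduction uses, which makes the reduction
  exactly invertible at zero noise.  Within each CSA-sharing group the
  planted forces follow a common activation envelope scaled by CSA, the
  unique configuration the CSA-proportional rule can recover;
- noise is i.i.d. Gaussian per channel (the simplest model that exposes the
  filters);
- only the floor-plate force is generated for sit-to-stand (no separate
  seat plate), matching what the phase-detection equations consume;
- returned ground-truth event indices are the samples at which the
  *noise-free* analytic channels satisfy the phase definitions, evaluated
  directly on the clean curves (independently of the detector's smoothing
  machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import LIGAMENTS, default_model_config
from .loads import JointLoadSeries, compute_joint_loads
from .muscles import MomentArmModel, MuscleForceSet
from .subjects import SubjectProfile
from .trial import CHANNELS, TrialTimeSeries

__all__ = [
    "GaitTrialSpec",
    "StsTrialSpec",
    "TileSetSpec",
    "GaitGroundTruth",
    "StsGroundTruth",
    "generate_gait_trial",
    "generate_sts_trace",
    "generate_tile_set",
    "make_speckle_master",
    "generate_rating_table",
    "rating_grid",
]

MOVEMENT_CLASSES = ("walk", "run_selfselect", "run_set")

#: Default additive Gaussian noise SDs per channel group.  Chosen as plausible
#: force-plate / inverse-dynamics residual magnitudes: a few newtons on forces,
#: about one newton-metre on net moments, ~0.6 degrees on angles.
DEFAULT_NOISE = {"grf": 5.0, "moments": 1.0, "angles": 0.01, "pelvis_vz": 0.005}

# Per-movement construction parameters.  Bumps are (centre, width, amplitude)
# in stance-phase coordinates; vertical-force amplitudes are in bodyweights,
# frontal knee moments in BW*Ht, activations in N/cm^2 of group CSA.
_GAIT_PARAMS = {
    "walk": dict(
        stride_s=1.10,
        stance_frac=0.62,
        speed_mps=1.30,
        fz_bumps=[(0.30, 0.60, 1.15), (0.70, 0.60, 1.10)],
        kam_bumps=[(0.30, 0.55, 0.034), (0.72, 0.55, 0.030)],
        quad_bump=(0.40, 0.80),
        quad_amp_n=1300.0,
        ankle_bump=(0.60, 0.80),
        ankle_intensity=13.0,
        hip_bump=(0.35, 0.70),
        hip_intensity=9.0,
        knee_angle=(0.55, 0.45, 0.30),  # offset, amplitude, phase shift
    ),
    "run_selfselect": dict(
        stride_s=0.72,
        stance_frac=0.36,
        speed_mps=2.85,
        fz_bumps=[(0.50, 1.00, 2.50)],
        kam_bumps=[(0.50, 0.90, 0.045)],
        quad_bump=(0.45, 0.90),
        quad_amp_n=2600.0,
        ankle_bump=(0.55, 0.90),
        ankle_intensity=30.0,
        hip_bump=(0.40, 0.80),
        hip_intensity=16.0,
        knee_angle=(0.75, 0.55, 0.30),
    ),
}
_GAIT_PARAMS["run_set"] = dict(_GAIT_PARAMS["run_selfselect"], speed_mps=3.0)


def _bump(x, centre, width):
    """Raised-cosine (Hann) bump on |x - centre| < width/2, zero elsewhere."""
    x = np.asarray(x, dtype=float)
    inside = np.abs(x - centre) < width / 2.0
    out = np.zeros_like(x)
    out[inside] = np.cos(np.pi * (x[inside] - centre) / width) ** 2
    return out


def _halfcos_step(u):
    """Smooth monotone step 0 -> 1 on u in [0, 1]."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _default_subject(gender: str = "male") -> SubjectProfile:
    height = {"male": 1.751, "female": 1.628}[gender]
    mass = {"male": 71.8, "female": 59.9}[gender]
    return SubjectProfile(gender=gender, height_m=height, mass_kg=mass)


# --------------------------------------------------------------------------
# gait trials
# --------------------------------------------------------------------------


@dataclass
class GaitTrialSpec:
    """Specification of one synthetic gait trial."""

    movement_class: str = "walk"
    stride_duration_s: float | None = None
    n_strides: int = 5
    sampling_rate_grf: float = 1000.0
    sampling_rate_kin: float = 200.0
    subject: SubjectProfile = field(default_factory=_default_subject)
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0
    speed_mps: float | None = None

    def __post_init__(self) -> None:
        if self.movement_class not in MOVEMENT_CLASSES:
            raise ValueError(f"unknown movement_class {self.movement_class!r}")
        if self.stride_duration_s is None:
            self.stride_duration_s = _GAIT_PARAMS[self.movement_class]["stride_s"]
        if self.stride_duration_s <= 0:
            raise ValueError("stride duration must be positive")
        if self.sampling_rate_grf <= 0 or self.sampling_rate_kin <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_strides < 1:
            raise ValueError("need at least one stride")
        noise = dict(DEFAULT_NOISE)
        noise.update(self.noise_sd or {})
        if any(v < 0 for v in noise.values()):
            raise ValueError("noise SDs must be non-negative")
        self.noise_sd = noise
        if self.speed_mps is None:
            self.speed_mps = _GAIT_PARAMS[self.movement_class]["speed_mps"]


@dataclass
class GaitGroundTruth:
    """Planted truth accompanying a synthetic gait trial."""

    forces: MuscleForceSet
    heel_strikes: np.ndarray  # kinetic-clock indices of 20 N crossings
    loads: JointLoadSeries  # noise-free joint loading
    stride_duration_s: float
    stance_fraction: float
    speed_mps: float


def generate_gait_trial(
    spec: GaitTrialSpec,
    model: MomentArmModel | None = None,
    config: dict | None = None,
) -> tuple[TrialTimeSeries, GaitGroundTruth]:
    """Generate one gait trial and its planted ground truth.

    All channels are evaluated analytically on the kinetic (force-plate)
    clock; the lower kinematic acquisition rate only constrains the
    bandwidth of the kinematic curves, so no resampling error enters the
    planted truth.  ``n_strides + 1`` heel strikes are planted.
    """
    p = _GAIT_PARAMS[spec.movement_class]
    subject = spec.subject
    if model is None:
        model = MomentArmModel.for_subject(subject, config or default_model_config())
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_grf
    T = spec.stride_duration_s
    bw, ht = subject.bodyweight_n, subject.height_m
    sf = p["stance_frac"]

    lead = 0.30 * T
    n_contacts = spec.n_strides + 1
    duration = lead + spec.n_strides * T + sf * T + 0.10 * T
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # stride phase relative to the first planted contact
    phase = (t - lead) / T
    frac = np.mod(phase, 1.0)

    # stance-coordinate tau for the owning stride; nan outside contact
    fz = np.zeros(n)
    kam = np.zeros(n)
    env_quad = np.zeros(n)
    env_ankle = np.zeros(n)
    env_hip = np.zeros(n)
    contact_starts = []
    for j in range(n_contacts):
        t0 = lead + j * T
        tau = (t - t0) / (sf * T)
        inside = (tau >= 0.0) & (tau <= 1.0)
        tau_in = np.where(inside, tau, np.nan)
        for c, w, amp in p["fz_bumps"]:
            fz[inside] += bw * amp * _bump(tau_in[inside], c, w)
        for c, w, amp in p["kam_bumps"]:
            kam[inside] += bw * ht * amp * _bump(tau_in[inside], c, w)
        env_quad[inside] += _bump(tau_in[inside], *p["quad_bump"])
        env_ankle[inside] += _bump(tau_in[inside], *p["ankle_bump"])
        env_hip[inside] += _bump(tau_in[inside], *p["hip_bump"])
        contact_starts.append(int(np.ceil(t0 * fs)))

    # joint angles: slow stride-periodic curves inside the configured ranges
    off, amp_k, shift = p["knee_angle"]
    th_knee = off + amp_k * np.sin(2 * np.pi * (frac - shift))
    th_ankle = 0.15 * np.sin(2 * np.pi * frac)
    th_hip = 0.35 + 0.30 * np.cos(2 * np.pi * frac)
    th_add = 0.02 * np.sin(2 * np.pi * frac)
    pelvis_vz = 0.12 * np.sin(4 * np.pi * frac)

    # planted forces: CSA-shared envelopes for the two-muscle groups
    csa = model.csa_cm2
    f_quad = p["quad_amp_n"] * env_quad
    f_gas = csa["gastrocnemius"] * p["ankle_intensity"] * env_ankle
    f_sol = csa["soleus"] * p["ankle_intensity"] * env_ankle
    f_ham = csa["hamstrings"] * p["hip_intensity"] * env_hip
    f_glu = csa["gluteus_maximus"] * p["hip_intensity"] * env_hip

    # net moments constructed through the shared moment-arm model
    m_ankle = model.arm("gastrocnemius", "ankle", th_ankle) * f_gas + model.arm(
        "soleus", "ankle", th_ankle
    ) * f_sol
    m_hip = model.arm("hamstrings", "hip", th_hip) * f_ham + model.arm(
        "gluteus_maximus", "hip", th_hip
    ) * f_glu
    m_knee_ext = (
        model.arm("quadriceps", "knee", th_knee) * f_quad
        - model.arm("hamstrings", "knee", th_knee) * f_ham
        - model.arm("gastrocnemius", "knee", th_knee) * f_gas
    )
    knee_flex_moment = -m_knee_ext
    knee_add_moment = -kam  # adduction negative in the frontal-plane frame

    fy = bw * 0.15 * (
        -_bump(frac, 0.10, 0.25) + _bump(frac, 0.40, 0.25)
    )  # braking then propulsion, stride coordinates
    fx = bw * 0.03 * np.sin(2 * np.pi * frac)

    clean = {
        "time": t,
        "fx": fx,
        "fy": fy,
        "fz": fz,
        "hip_flex_angle": th_hip,
        "knee_flex_angle": th_knee,
        "knee_add_angle": th_add,
        "ankle_flex_angle": th_ankle,
        "hip_ext_moment": m_hip,
        "knee_flex_moment": knee_flex_moment,
        "knee_add_moment": knee_add_moment,
        "ankle_pf_moment": m_ankle,
        "pelvis_vz": pelvis_vz,
    }

    # planted heel strikes: first sample at/above 20 N in each contact
    heel_strikes = []
    stance_len = int(sf * T * fs) + 2
    for start in contact_starts:
        seg = fz[start : start + stance_len]
        above = np.flatnonzero(seg >= 20.0)
        if len(above):
            heel_strikes.append(start + int(above[0]))
    heel_strikes = np.asarray(heel_strikes, dtype=int)

    forces = MuscleForceSet(
        pd.DataFrame(
            {
                "gastrocnemius": f_gas,
                "soleus": f_sol,
                "hamstrings": f_ham,
                "gluteus_maximus": f_glu,
                "quadriceps": f_quad,
                **{lig: np.zeros(n) for lig in LIGAMENTS},
            }
        )
    )

    noisy = dict(clean)
    ns = spec.noise_sd
    for ch, group in [
        ("fx", "grf"),
        ("fy", "grf"),
        ("fz", "grf"),
        ("hip_ext_moment", "moments"),
        ("knee_flex_moment", "moments"),
        ("knee_add_moment", "moments"),
        ("ankle_pf_moment", "moments"),
        ("hip_flex_angle", "angles"),
        ("knee_flex_angle", "angles"),
        ("knee_add_angle", "angles"),
        ("ankle_flex_angle", "angles"),
        ("pelvis_vz", "pelvis_vz"),
    ]:
        if ns[group] > 0:
            noisy[ch] = clean[ch] + rng.normal(0.0, ns[group], n)

    trial = TrialTimeSeries(
        pd.DataFrame({c: noisy[c] for c in CHANNELS}),
        fs,
        spec.movement_class,
        meta={"speed_mps": spec.speed_mps, "subject_id": subject.subject_id},
    )
    clean_trial = TrialTimeSeries(
        pd.DataFrame({c: clean[c] for c in CHANNELS}), fs, spec.movement_class
    )
    truth = GaitGroundTruth(
        forces=forces,
        heel_strikes=heel_strikes,
        loads=compute_joint_loads(clean_trial, forces, model, subject),
        stride_duration_s=T,
        stance_fraction=sf,
        speed_mps=spec.speed_mps,
    )
    return trial, truth


# --------------------------------------------------------------------------
# sit-to-stand / stand-to-sit traces
# --------------------------------------------------------------------------


@dataclass
class StsTrialSpec:
    """Specification of one synthetic sit-stand-sit floor-plate trace.

    ``phase_boundaries`` are the construction knots (quiet-sit start, rise
    onset, quiet-stand start, descent onset, quiet-sit-again start) as
    sample indices; the *returned* ground-truth events are where the clean
    curves satisfy the formula-based phase definitions, which by design lie
    a little inside these knots.
    """

    phase_boundaries: tuple = (500, 1500, 2600, 4200, 5200)
    bodyweight_n: float = 700.0
    seat_height_cm: float = 44.0
    noise_sd: float = 0.0  # N, force channels
    noise_sd_vz: float = 0.0  # m/s, pelvis vertical velocity
    rate_hz: float = 1000.0
    seed: int = 0
    subject: SubjectProfile | None = None
    sit_load_fraction: float = 0.30  # floor-plate share of BW while seated
    n_samples: int | None = None

    def __post_init__(self) -> None:
        b = tuple(int(i) for i in self.phase_boundaries)
        if len(b) != 5 or any(b2 <= b1 for b1, b2 in zip(b, b[1:])) or b[0] < 0:
            raise ValueError("phase boundaries must be 5 strictly increasing indices")
        if self.bodyweight_n <= 0:
            raise ValueError("bodyweight must be positive")
        if self.noise_sd < 0 or self.noise_sd_vz < 0:
            raise ValueError("noise SDs must be non-negative")
        self.phase_boundaries = b
        if self.n_samples is None:
            self.n_samples = b[4] + int(self.rate_hz)


@dataclass
class StsGroundTruth:
    """Planted truth for one sit-stand-sit trace."""

    events: dict  # label -> (start_index, end_index) per the phase definitions
    boundaries: tuple  # construction knots
    forces: MuscleForceSet
    loads: JointLoadSeries
    bodyweight_n: float


def _first_sustained(mask: np.ndarray, n_sustain: int) -> int | None:
    ok = np.convolve(mask.astype(int), np.ones(n_sustain, dtype=int), mode="valid")
    idx = np.flatnonzero(ok == n_sustain)
    return int(idx[0]) if len(idx) else None


def generate_sts_trace(
    spec: StsTrialSpec,
    model: MomentArmModel | None = None,
    config: dict | None = None,
) -> tuple[TrialTimeSeries, StsGroundTruth]:
    """Generate a sit-to-stand / stand-to-sit floor-plate trace.

    The vertical force is piecewise smooth: seat-supported quiet sitting at
    a fraction of bodyweight, a half-cosine rise to quiet standing at
    BW ± <0.5% BW, a half-cosine descent, and quiet sitting again.  The
    anterior-posterior force and pelvis vertical velocity carry matching
    transition bumps.  Muscle/moment channels are constructed from planted
    envelopes exactly as in the gait generator.
    """
    subject = spec.subject or _default_subject()
    if abs(subject.bodyweight_n - spec.bodyweight_n) > 1e-6:
        subject = SubjectProfile(
            gender=subject.gender,
            height_m=subject.height_m,
            mass_kg=spec.bodyweight_n / 9.81,
            intercondylar_d_cm=subject.intercondylar_d_cm,
            midcondylar_d_cm=subject.midcondylar_d_cm,
            subject_id=subject.subject_id,
        )
    if model is None:
        model = MomentArmModel.for_subject(subject, config or default_model_config())
    rng = np.random.default_rng(spec.seed)
    fs = spec.rate_hz
    b0, b1, b2, b3, b4 = spec.phase_boundaries
    n = spec.n_samples
    if n <= b4:
        raise ValueError("n_samples must extend past the last boundary")
    t = np.arange(n) / fs
    bw = spec.bodyweight_n
    s0 = spec.sit_load_fraction
    amp = (1.0 - s0) * bw
    drop_m = spec.seat_height_cm / 100.0

    i = np.arange(n)
    u_rise = (i - b1) / (b2 - b1)
    u_desc = (i - b3) / (b4 - b3)
    rise = _halfcos_step(u_rise)
    desc = _halfcos_step(u_desc)
    fz = s0 * bw + amp * rise - amp * desc

    def _transition_bump(u):
        u = np.clip(u, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(2 * np.pi * u)) * ((u > 0) & (u < 1))

    a_fy = 0.05 * bw
    fy = a_fy * _transition_bump(u_rise) - a_fy * _transition_bump(u_desc)
    v_rise = 2.0 * drop_m / ((b2 - b1) / fs)
    v_desc = 2.0 * drop_m / ((b4 - b3) / fs)
    pelvis_vz = v_rise * _transition_bump(u_rise) - v_desc * _transition_bump(u_desc)

    # posture: seated flexion to standing extension and back
    th_knee = 1.40 - 1.30 * rise + 1.30 * desc
    th_hip = 1.10 - 1.05 * rise + 1.05 * desc
    th_ankle = 0.15 - 0.15 * rise + 0.15 * desc
    th_add = np.zeros(n)

    env = _transition_bump(u_rise) + _transition_bump(u_desc)
    csa = model.csa_cm2
    f_quad = 1800.0 * env
    f_gas = csa["gastrocnemius"] * 4.0 * env
    f_sol = csa["soleus"] * 4.0 * env
    f_ham = csa["hamstrings"] * 5.0 * env
    f_glu = csa["gluteus_maximus"] * 5.0 * env

    m_ankle = model.arm("gastrocnemius", "ankle", th_ankle) * f_gas + model.arm(
        "soleus", "ankle", th_ankle
    ) * f_sol
    m_hip = model.arm("hamstrings", "hip", th_hip) * f_ham + model.arm(
        "gluteus_maximus", "hip", th_hip
    ) * f_glu
    knee_flex_moment = -(
        model.arm("quadriceps", "knee", th_knee) * f_quad
        - model.arm("hamstrings", "knee", th_knee) * f_ham
        - model.arm("gastrocnemius", "knee", th_knee) * f_gas
    )
    knee_add_moment = -0.020 * bw * subject.height_m * env

    clean = {
        "time": t,
        "fx": np.zeros(n),
        "fy": fy,
        "fz": fz,
        "hip_flex_angle": th_hip,
        "knee_flex_angle": th_knee,
        "knee_add_angle": th_add,
        "ankle_flex_angle": th_ankle,
        "hip_ext_moment": m_hip,
        "knee_flex_moment": knee_flex_moment,
        "knee_add_moment": knee_add_moment,
        "ankle_pf_moment": m_ankle,
        "pelvis_vz": pelvis_vz,
    }

    # ground-truth events from the clean curves, per the phase definitions
    dfz = np.gradient(fz, 1.0 / fs)
    pp_fz = dfz.max() - dfz.min()
    sts_start = int(np.flatnonzero(np.abs(dfz) >= 0.10 * pp_fz)[0])
    in_band = np.abs(fz - bw) <= 0.01 * bw
    sts_end = int(np.flatnonzero(in_band & (i > sts_start))[0])
    s2s_start = int(np.flatnonzero((i >= b2) & (fz <= 0.98 * bw))[0])
    dfy = np.gradient(fy, 1.0 / fs)
    pp_fy = dfy.max() - dfy.min()
    n_sus = max(1, int(round(0.100 * fs)))
    # the clauses also hold during the earlier quiet phases; restrict to
    # samples after the descent onset
    candidates = []
    for mask in (np.abs(dfy) <= 0.01 * pp_fy, np.abs(pelvis_vz) < 0.02):
        m = mask.copy()
        m[: s2s_start + 1] = False
        hit = _first_sustained(m, n_sus)
        if hit is not None:
            candidates.append(hit)
    s2s_end = int(min(candidates))

    forces = MuscleForceSet(
        pd.DataFrame(
            {
                "gastrocnemius": f_gas,
                "soleus": f_sol,
                "hamstrings": f_ham,
                "gluteus_maximus": f_glu,
                "quadriceps": f_quad,
                **{lig: np.zeros(n) for lig in LIGAMENTS},
            }
        )
    )

    noisy = dict(clean)
    if spec.noise_sd > 0:
        for ch in ("fx", "fy", "fz"):
            noisy[ch] = clean[ch] + rng.normal(0.0, spec.noise_sd, n)
    if spec.noise_sd_vz > 0:
        noisy["pelvis_vz"] = clean["pelvis_vz"] + rng.normal(0.0, spec.noise_sd_vz, n)

    trial = TrialTimeSeries(
        pd.DataFrame({c: noisy[c] for c in CHANNELS}),
        fs,
        "sts",
        meta={"subject_id": subject.subject_id},
    )
    clean_trial = TrialTimeSeries(pd.DataFrame({c: clean[c] for c in CHANNELS}), fs, "sts")
    truth = StsGroundTruth(
        events={
            "sit_to_stand": (sts_start, sts_end),
            "stand_to_sit": (s2s_start, s2s_end),
        },
        boundaries=spec.phase_boundaries,
        forces=forces,
        loads=compute_joint_loads(clean_trial, forces, model, subject),
        bodyweight_n=bw,
    )
    return trial, truth


# --------------------------------------------------------------------------
# pseudo-ultrasound tile sets
# --------------------------------------------------------------------------


def make_speckle_master(
    height_px: int = 240,
    width_px: int = 1400,
    landmarks: tuple | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, tuple]:
    """Feature-rich pseudo-ultrasound texture with two condyle-like arcs.

    Smoothed random speckle plus two bright arcs centred under the landmark
    positions; intensities in [0, 1].  Returns (image, landmarks) with
    landmarks as ((x1, y1), (x2, y2)) pixel coordinates.
    """
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal((height_px, width_px)), sigma=2.5)
    img = (img - img.min()) / (img.max() - img.min()) * 0.6
    if landmarks is None:
        landmarks = (
            (int(0.25 * width_px), int(0.45 * height_px)),
            (int(0.75 * width_px), int(0.45 * height_px)),
        )
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    for (cx, cy) in landmarks:
        radius = 0.35 * height_px
        dist = np.sqrt((xx - cx) ** 2 + (yy - (cy + radius)) ** 2)
        img += 0.4 * np.exp(-((dist - radius) ** 2) / (2 * 4.0**2))
    return np.clip(img, 0.0, 1.0), landmarks


@dataclass
class TileSetSpec:
    """Specification of an exact-crop tile set from a master image."""

    master: np.ndarray
    tile_width_px: int
    offsets_px: tuple
    landmark_pair_px: tuple  # ((x1, y1), (x2, y2)) in master coordinates
    px_per_cm: float

    def __post_init__(self) -> None:
        offs = tuple(int(o) for o in self.offsets_px)
        w = int(self.tile_width_px)
        if w < 2:
            raise ValueError("tile width must be at least 2 px")
        if any(o2 <= o1 for o1, o2 in zip(offs, offs[1:])):
            raise ValueError("offsets must be strictly increasing")
        if offs[0] < 0 or offs[-1] + w > self.master.shape[1]:
            raise ValueError("tiles must lie inside the master image")
        for o1, o2 in zip(offs, offs[1:]):
            overlap = o1 + w - o2
            if overlap < 0.2 * w:
                raise ValueError(
                    f"consecutive tiles must overlap by >= 20% of tile width "
                    f"(offsets {o1}, {o2}, width {w})"
                )
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        for (x, y) in self.landmark_pair_px:
            h, wid = self.master.shape
            if not (0 <= x < wid and 0 <= y < h):
                raise ValueError("landmarks must lie inside the master image")
        self.offsets_px = offs
        self.tile_width_px = w


def generate_tile_set(spec: TileSetSpec) -> tuple[list, float]:
    """Exact crops of the master at the stated offsets, plus the true
    calibrated landmark distance in centimetres."""
    tiles = [
        spec.master[:, o : o + spec.tile_width_px].copy() for o in spec.offsets_px
    ]
    (x1, y1), (x2, y2) = spec.landmark_pair_px
    true_cm = float(np.hypot(x2 - x1, y2 - y1) / spec.px_per_cm)
    return tiles, true_cm


# --------------------------------------------------------------------------
# rating tables
# --------------------------------------------------------------------------


def generate_rating_table(
    n_subjects: int,
    n_raters: int,
    n_repeats: int,
    var_subject: float,
    var_rater: float,
    var_error: float,
    mu: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Two-way random-effects rating table with planted variance components.

    ``y_ijl = mu + s_i + r_j + e_ijl`` with s, r, e independent zero-mean
    Gaussians.  Returns the long table (subject, rater, session, repeat,
    distance_cm) and the theoretical ICC(2,k) for the design in which the k
    rater columns hold repeat-averaged values::

        ICC(2,k) = var_s / (var_s + (var_r + var_e / m) / k)

    with m repeats per rater.  A table with no rater or error variance has
    ICC 1 by convention.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if min(var_subject, var_rater, var_error) < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, np.sqrt(var_subject), n_subjects)
    r = rng.normal(0.0, np.sqrt(var_rater), n_raters)
    e = rng.normal(0.0, np.sqrt(var_error), (n_subjects, n_raters, n_repeats))
    y = mu + s[:, None, None] + r[None, :, None] + e
    idx_s, idx_r, idx_k = np.meshgrid(
        np.arange(n_subjects), np.arange(n_raters), np.arange(n_repeats), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "subject": [f"s{i:03d}" for i in idx_s.ravel()],
            "rater": [f"r{j}" for j in idx_r.ravel()],
            "session": 1,
            "repeat": idx_k.ravel() + 1,
            "distance_cm": y.ravel(),
        }
    )
    noise = (var_rater + var_error / n_repeats) / n_raters
    if var_subject + noise == 0:
        icc = 1.0
    else:
        icc = var_subject / (var_subject + noise)
    return table, icc


def rating_grid(
    table: pd.DataFrame, columns: str = "rater", rater: str | None = None
) -> pd.DataFrame:
    """Pivot a long rating table to the subjects × measurements grid ICC uses.

    ``columns="rater"`` averages repeats within each rater (inter-rater
    design); ``columns="repeat"`` uses the repeated measurements of a single
    rater (intra-rater design, requires ``rater``).
    """
    if columns == "rater":
        return table.pivot_table(
            index="subject", columns="rater", values="distance_cm", aggfunc="mean"
        )
    if columns == "repeat":
        if rater is None:
            raise ValueError("intra-rater grid requires a rater id")
        sub = table[table["rater"] == rater]
        return sub.pivot_table(index="subject", columns="repeat", values="distance_cm")
    raise ValueError(f"unknown grid layout {columns!r}")
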