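"""Trial time-series container and phase windows.

One trial is a uniformly sampled multichannel record on a single (kinetic)
clock: ground reaction forces, lower-limb joint angles, net joint moments and
pelvis vertical velocity.  Kinematic channels acquired at a lower rate are
expected to be resampled onto this clock before they enter the container.

Sign conventions (used consistently across the package):

==================  =========================================================
channel             convention
==================  =========================================================
fz                  vertical ground reaction force, positive upward (N)
fy                  anterior-posterior ground reaction force (N)
hip_ext_moment      positive = hip extension (N·m)
knee_flex_moment    positive = knee flexion; extension demand is its negative
knee_add_moment     frontal-plane knee moment; NEGATIVE = adduction, i.e.
                    medial-compartment loading (N·m)
ankle_pf_moment     positive = ankle plantarflexion (N·m)
angles              radians; knee flexion positive
pelvis_vz           pelvis vertical velocity, m/s, positive upward
==================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical channel order of the trial TSV dialect.
CHANNELS = [
    "time",
    "fx",
    "fy",
    "fz",
    "hip_flex_angle",
    "knee_flex_angle",
    "knee_add_angle",
    "ankle_flex_angle",
    "hip_ext_moment",
    "knee_flex_moment",
    "knee_add_moment",
    "ankle_pf_moment",
    "pelvis_vz",
]

GRF_CHANNELS = ["fx", "fy", "fz"]
ANGLE_CHANNELS = ["hip_flex_angle", "knee_flex_angle", "knee_add_angle", "ankle_flex_angle"]
MOMENT_CHANNELS = ["hip_ext_moment", "knee_flex_moment", "knee_add_moment", "ankle_pf_moment"]


@dataclass
class TrialTimeSeries:
    """Uniformly sampled multichannel trial record."""

    data: pd.DataFrame
    rate_hz: float
    movement: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trial is missing channels: {missing}")
        t = self.data["time"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, 1.0 / self.rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("time channel is not uniformly sampled at rate_hz")

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def copy_with(self, **channels: np.ndarray) -> "TrialTimeSeries":
        df = self.data.copy()
        for name, values in channels.items():
            df[name] = values
        return TrialTimeSeries(df, self.rate_hz, self.movement, dict(self.meta))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.9g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, rate_hz: float | None = None, movement: str = "unknown"
    ) -> "TrialTimeSeries":
        df = pd.read_csv(path, sep="\t")
        if rate_hz is None:
            t = df["time"].to_numpy()
            if len(t) < 2:
                raise ValueError("cannot infer rate from a single sample")
            rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(df, rate_hz, movement)


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open sample-index window ``[start, end)`` with a phase label."""

    label: str  # stance | stride | sit_to_stand | stand_to_sit
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(
                f"invalid window: start={self.start_index}, end={self.end_index}"
            )

    def __len__(self) -> int:
        return self.end_index - self.start_index

    def slice(self) -> slice:
        return slice(self.start_index, self.end_index)


@dataclass(frozen=True)
class FilterSpec:
    """Dual-pass (zero-phase) Butterworth filter specification.

    ``order`` is the per-pass order; the forward-backward application squares
    the magnitude response, so the nominal cutoff is attenuated to 0.5 rather
    than 1/sqrt(2).  No cutoff correction is applied (this matches common
    motion-analysis practice).
    """

    cutoff_hz: float
    order: int = 4
    passes: int = 2

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1 or self.passes != 2:
            raise ValueError("only dual-pass filters of order >= 1 are supported")


#: Movement-class cutoff routing: kinematic/moment channels at 10 Hz for
#: running and 6 Hz for other movements; ground reaction forces at 45 Hz.
DEFAULT_CUTOFFS = {
    "walk": {"grf": 45.0, "kin": 6.0},
    "run_selfselect": {"grf": 45.0, "kin": 10.0},
    "run_set": {"grf": 45.0, "kin": 10.0},
    "sts": {"grf": 45.0, "kin": 6.0},
}
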