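"""Subject anthropometry and knee geometry."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

G = 9.81  # m/s^2

#: Cohort-mean midcondylar (tibial plateau) distances, cm, used when no
#: ultrasound measurement is available for a subject.
DEFAULT_MIDCONDYLAR_CM = {"female": 4.86, "male": 5.53}

#: Midcondylar / intercondylar ratio applied to the ultrasound-measured
#: distance.  The measurement is taken superior to the patella with the knee
#: flexed, which underestimates the true midcondylar span; the ratio rescales
#: it using cadaver geometry.  Editable placeholder values.
DEFAULT_CONDYLAR_RATIO = {"female": 1.08, "male": 1.06}


@dataclass
class SubjectProfile:
    """Anthropometry and knee geometry for one participant.

    Parameters
    ----------
    gender : {"female", "male"}
        Gender category used to select moment-arm variants and condylar
        scaling ratios.
    height_m : float
        Standing height in metres.
    mass_kg : float
        Body mass in kilograms; bodyweight is ``mass * 9.81`` N.
    intercondylar_d_cm : float, optional
        Ultrasound-measured distance between the medial and lateral femoral
        condyle centres (cm).
    midcondylar_d_cm : float, optional
        Estimated distance between the medial and lateral tibiofemoral
        contact points (cm).  Defaults to ``intercondylar_d_cm * ratio`` when
        a measurement exists, otherwise to the gender cohort mean.
    """

    gender: str
    height_m: float
    mass_kg: float
    intercondylar_d_cm: float | None = None
    midcondylar_d_cm: float | None = None
    condylar_ratio: float | None = None
    subject_id: str = "subject"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValueError(f"unknown gender category: {self.gender!r}")
        if self.height_m <= 0 or self.mass_kg <= 0:
            raise ValueError("height and mass must be positive")
        if self.condylar_ratio is None:
            self.condylar_ratio = DEFAULT_CONDYLAR_RATIO[self.gender]
        if self.midcondylar_d_cm is None:
            if self.intercondylar_d_cm is not None:
                self.midcondylar_d_cm = self.intercondylar_d_cm * self.condylar_ratio
            else:
                self.midcondylar_d_cm = DEFAULT_MIDCONDYLAR_CM[self.gender]
        if self.midcondylar_d_cm <= 0:
            raise ValueError("midcondylar distance must be positive")

    @property
    def bodyweight_n(self) -> float:
        return self.mass_kg * G

    @property
    def midcondylar_d_m(self) -> float:
        return self.midcondylar_d_cm / 100.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject_id": self.subject_id,
            "gender": self.gender,
            "height_m": self.height_m,
            "mass_kg": self.mass_kg,
            "intercondylar_d_cm": self.intercondylar_d_cm,
            "midcondylar_d_cm": self.midcondylar_d_cm,
            "condylar_ratio": self.condylar_ratio,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubjectProfile":
        payload = json.loads(Path(path).read_text())
        payload.pop("extra", None)
        return cls(**payload)
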