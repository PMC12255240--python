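"""Model configuration: load, validate and default coefficients.

The musculoskeletal coefficients (muscle cross-sectional areas, per-gender
moment-arm and orientation polynomials, ligament resolution parameters,
condylar scaling ratios) are literature-derived quantities that users may
substitute; they live in a versioned JSON file rather than in code.  The
shipped defaults are documented placeholders in physiological ranges, and all
model-level tests are coefficient-agnostic (closure and round-trip
properties), so swapping in published fits does not break the package.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

MUSCLES = ["gastrocnemius", "soleus", "hamstrings", "gluteus_maximus", "quadriceps"]
LIGAMENTS = ["acl", "pcl", "mcl", "lcl"]
KNEE_STRUCTURES = ["quadriceps", "hamstrings", "gastrocnemius"] + LIGAMENTS

_ARM_KEYS = [
    "gastrocnemius_ankle",
    "soleus_ankle",
    "hamstrings_hip",
    "gluteus_maximus_hip",
    "quadriceps_knee",
    "hamstrings_knee",
    "gastrocnemius_knee",
]


class ConfigError(ValueError):
    """Raised when a model configuration fails schema validation."""


def _check_poly(entry: dict, where: str) -> None:
    if not isinstance(entry, dict) or "coeffs" not in entry or "angle_range" not in entry:
        raise ConfigError(f"{where}: expected {{coeffs, angle_range}}")
    coeffs = entry["coeffs"]
    rng = entry["angle_range"]
    if not coeffs or not all(isinstance(c, (int, float)) for c in coeffs):
        raise ConfigError(f"{where}: coeffs must be a non-empty numeric list")
    if len(rng) != 2 or rng[0] >= rng[1]:
        raise ConfigError(f"{where}: angle_range must be [lo, hi] with lo < hi")


def validate_model_config(config: dict) -> dict:
    """Validate the model-config schema; returns the config unchanged."""
    for key in ("csa_cm2", "moment_arms", "knee_orientation", "frontal_arm_fraction", "condylar_ratio", "heights"):
        if key not in config:
            raise ConfigError(f"model config missing key {key!r}")
    for muscle in MUSCLES:
        csa = config["csa_cm2"].get(muscle)
        if not isinstance(csa, (int, float)) or csa <= 0:
            raise ConfigError(f"csa_cm2[{muscle!r}] must be positive")
    for gender in ("female", "male"):
        arms = config["moment_arms"].get(gender, {})
        for key in _ARM_KEYS:
            if key not in arms:
                raise ConfigError(f"moment_arms[{gender}] missing {key!r}")
            _check_poly(arms[key], f"moment_arms[{gender}][{key}]")
        orient = config["knee_orientation"].get(gender, {})
        for key in KNEE_STRUCTURES:
            if key not in orient:
                raise ConfigError(f"knee_orientation[{gender}] missing {key!r}")
            _check_poly(orient[key], f"knee_orientation[{gender}][{key}]")
    for key in KNEE_STRUCTURES:
        if key not in config["frontal_arm_fraction"]:
            raise ConfigError(f"frontal_arm_fraction missing {key!r}")
    for gender in ("female", "male"):
        ratio = config["condylar_ratio"].get(gender)
        if not isinstance(ratio, (int, float)) or ratio <= 0:
            raise ConfigError(f"condylar_ratio[{gender}] must be positive")
    return config


def load_model_config(path: str | Path) -> dict:
    """Load and validate a model configuration from a JSON file."""
    config = json.loads(Path(path).read_text())
    return validate_model_config(config)


def default_model_config() -> dict:
    """Packaged default configuration (documented placeholder coefficients)."""
    text = resources.files("kneeload").joinpath("model_config.json").read_text()
    return validate_model_config(json.loads(text))
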