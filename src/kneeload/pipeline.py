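"""End-to-end orchestration: condition → segment → reduce → contact force →
peaks → group statistics, plus a one-command synthetic demo cohort.

Stages log at trial granularity and a failing trial aborts only itself (the
failure is logged with the stage and trial id), because audited exclusions
are part of this kind of study.  Everything is deterministic under a fixed
seed, and no stage reads outside the configured paths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import default_model_config, load_model_config
from .loads import compute_joint_loads, extract_peaks, percent_difference
from .muscles import MomentArmModel, reduce_trial
from .signals import (
    EventNotFoundError,
    detect_heel_strikes,
    detect_sit_to_stand,
    detect_stand_to_sit,
    extract_strides,
    filter_trial,
    stance_window,
)
from .stats import bonferroni_alpha, choose_and_run_test
from .subjects import SubjectProfile
from .synthetic import GaitTrialSpec, StsTrialSpec, generate_gait_trial, generate_sts_trace
from .trial import DEFAULT_CUTOFFS, TrialTimeSeries

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "subject",
    "gender",
    "movement",
    "mjcf_peak1_bw",
    "mjcf_peak2_bw",
    "kam_peak_bwht",
    "kfm_peak_bwht",
    "n_trials",
]

GAIT_MOVEMENTS = ("walk", "run_selfselect", "run_set")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    trials_dir: str | Path
    out_dir: str | Path
    model_config_path: str | Path | None = None
    cutoffs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CUTOFFS.items()})
    seed: int = 0
    family_alpha: float = 0.05
    n_tests: int = 18

    def __post_init__(self) -> None:
        self.trials_dir = Path(self.trials_dir)
        self.out_dir = Path(self.out_dir)
        if not self.trials_dir.is_dir():
            raise FileNotFoundError(f"trials directory not found: {self.trials_dir}")
        if self.model_config_path is not None and not Path(self.model_config_path).is_file():
            raise FileNotFoundError(f"model config not found: {self.model_config_path}")
        for mv, cuts in self.cutoffs.items():
            if cuts["grf"] <= 0 or cuts["kin"] <= 0:
                raise ValueError(f"non-positive cutoff for movement {mv!r}")

    def load_config(self) -> dict:
        if self.model_config_path is None:
            return default_model_config()
        return load_model_config(self.model_config_path)


def _movement_of(path: Path) -> str:
    stem = path.stem
    for mv in GAIT_MOVEMENTS + ("sts",):
        if stem.startswith(mv + "_"):
            return mv
    raise ValueError(f"cannot infer movement class from trial file {path.name!r}")


def _trial_meta(path: Path) -> dict:
    meta_path = path.with_suffix(".meta.json")
    if meta_path.is_file():
        return json.loads(meta_path.read_text())
    return {}


def process_gait_trial(trial: TrialTimeSeries, subject, model, movement: str) -> list:
    """Peaks for every clean stride of one gait trial."""
    filtered = filter_trial(
        trial,
        DEFAULT_CUTOFFS[movement]["grf"],
        DEFAULT_CUTOFFS[movement]["kin"],
    )
    events = detect_heel_strikes(filtered["fz"], filtered.rate_hz)
    strides = extract_strides(events, filtered)
    forces = reduce_trial(filtered, model)
    loads = compute_joint_loads(filtered, forces, model, subject)
    label = "walk" if movement == "walk" else movement
    peaks = []
    for stride in strides:
        stance = stance_window(filtered, stride)
        peaks.append(extract_peaks(loads, stance, label, subject))
    return peaks


def process_sts_trial(trial: TrialTimeSeries, subject, model) -> dict:
    """Peaks for the sit-to-stand and stand-to-sit phases of one trace."""
    filtered = filter_trial(trial, DEFAULT_CUTOFFS["sts"]["grf"], DEFAULT_CUTOFFS["sts"]["kin"])
    forces = reduce_trial(filtered, model)
    loads = compute_joint_loads(filtered, forces, model, subject)
    out = {}
    bw = subject.bodyweight_n
    for label, detect in (
        ("sit_to_stand", detect_sit_to_stand),
        ("stand_to_sit", detect_stand_to_sit),
    ):
        window = detect(filtered, bw)
        out[label] = extract_peaks(loads, window, label, subject)
    return out


def _mean_or_nan(values: list) -> float:
    return float(np.mean(values)) if values else float("nan")


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every subject directory under ``trials_dir``.

    Writes ``results.tsv`` (per-subject mean peaks per movement),
    ``speeds.tsv`` (per-subject mean movement speeds, where trial metadata
    provides them) and ``stats.tsv`` (gender comparisons) under ``out_dir``;
    returns the results and stats frames.
    """
    model_config = config.load_config()
    config.out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    speed_rows = []
    subject_dirs = sorted(p for p in config.trials_dir.iterdir() if p.is_dir())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories in {config.trials_dir}")
    for sdir in subject_dirs:
        try:
            subject = SubjectProfile.from_json(sdir / "subject.json")
        except Exception as exc:  # noqa: BLE001 - audited skip
            logger.error("stage=subject subject=%s failed: %s", sdir.name, exc)
            continue
        model = MomentArmModel.for_subject(subject, model_config)
        collected: dict = {}
        speeds: dict = {}
        for trial_path in sorted(sdir.glob("*.tsv")):
            try:
                movement = _movement_of(trial_path)
                trial = TrialTimeSeries.from_tsv(trial_path, movement=movement)
                meta = _trial_meta(trial_path)
                if movement in GAIT_MOVEMENTS:
                    peaks = process_gait_trial(trial, subject, model, movement)
                    collected.setdefault(movement, []).extend(peaks)
                    if "speed_mps" in meta:
                        speeds.setdefault(movement, []).append(meta["speed_mps"])
                else:
                    for label, summary in process_sts_trial(trial, subject, model).items():
                        collected.setdefault(label, []).append(summary)
            except (EventNotFoundError, ValueError, KeyError) as exc:
                logger.error(
                    "stage=trial subject=%s trial=%s failed: %s",
                    sdir.name,
                    trial_path.name,
                    exc,
                )
        for movement, summaries in collected.items():
            mjcf1 = [s.mjcf_peaks_bw[0] for s in summaries]
            mjcf2 = [s.mjcf_peaks_bw[1] for s in summaries if len(s.mjcf_peaks_bw) > 1]
            kam = [max(s.kam_peaks_bwht) for s in summaries]
            kfm = [max(s.kfm_peaks_bwht) for s in summaries]
            rows.append(
                {
                    "subject": subject.subject_id,
                    "gender": subject.gender,
                    "movement": movement,
                    "mjcf_peak1_bw": _mean_or_nan(mjcf1),
                    "mjcf_peak2_bw": _mean_or_nan(mjcf2),
                    "kam_peak_bwht": _mean_or_nan(kam),
                    "kfm_peak_bwht": _mean_or_nan(kfm),
                    "n_trials": len(summaries),
                }
            )
        for movement, values in speeds.items():
            speed_rows.append(
                {
                    "subject": subject.subject_id,
                    "gender": subject.gender,
                    "movement": movement,
                    "speed_mps": _mean_or_nan(values),
                }
            )
        logger.info("subject %s: %d movement summaries", sdir.name, len(collected))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results.to_csv(config.out_dir / "results.tsv", sep="\t", index=False)
    speeds_df = pd.DataFrame(speed_rows, columns=["subject", "gender", "movement", "speed_mps"])
    speeds_df.to_csv(config.out_dir / "speeds.tsv", sep="\t", index=False)
    stats_df = group_statistics(
        results, speeds_df, family_alpha=config.family_alpha, n_tests=config.n_tests
    )
    stats_df.to_csv(config.out_dir / "stats.tsv", sep="\t", index=False)
    return results, stats_df


def group_statistics(
    results: pd.DataFrame,
    speeds: pd.DataFrame | None = None,
    family_alpha: float = 0.05,
    n_tests: int = 18,
) -> pd.DataFrame:
    """Male-vs-female comparisons of the peak knee loads (and speeds).

    Knee-load tests are one-tailed (hypothesis: women's scaled loads exceed
    men's ... tested as female > male) at the Bonferroni-corrected α;
    walking speed is compared two-tailed and running speeds one-tailed at
    the family α.
    """
    alpha_knee = bonferroni_alpha(family_alpha, n_tests)
    records = []

    def _compare(metric, movement, a, b, tails, alpha):
        if len(a) < 3 or len(b) < 3:
            logger.warning("skipping %s/%s: fewer than 3 per group", movement, metric)
            return
        res = choose_and_run_test(a, b, tails=tails, alpha=alpha)
        records.append(
            {
                "movement": movement,
                "metric": metric,
                "test": res.test,
                "n_female": res.n_a,
                "n_male": res.n_b,
                "mean_female": res.mean_a,
                "mean_male": res.mean_b,
                "p": res.p,
                "cohens_d": res.cohens_d,
                "alpha": res.alpha,
                "significant": res.significant,
                "percent_difference": percent_difference(res.mean_a, res.mean_b)
                if (res.mean_a + res.mean_b) != 0
                else float("nan"),
            }
        )

    metrics = {
        "mjcf_peak1_bw": "mjcf_peak1_bw",
        "kam_peak_bwht": "kam_peak_bwht",
        "kfm_peak_bwht": "kfm_peak_bwht",
    }
    for movement, sub in results.groupby("movement"):
        for metric in metrics:
            f = sub.loc[sub.gender == "female", metric].dropna().to_numpy()
            m = sub.loc[sub.gender == "male", metric].dropna().to_numpy()
            _compare(metric, movement, f, m, tails=1, alpha=alpha_knee)
        if movement == "walk":
            f = sub.loc[sub.gender == "female", "mjcf_peak2_bw"].dropna().to_numpy()
            m = sub.loc[sub.gender == "male", "mjcf_peak2_bw"].dropna().to_numpy()
            _compare("mjcf_peak2_bw", movement, f, m, tails=1, alpha=alpha_knee)
    if speeds is not None and len(speeds):
        for movement, sub in speeds.groupby("movement"):
            f = sub.loc[sub.gender == "female", "speed_mps"].dropna().to_numpy()
            m = sub.loc[sub.gender == "male", "speed_mps"].dropna().to_numpy()
            tails = 2 if movement == "walk" else 1
            # running speed hypothesis is male > female; put male first
            if tails == 1:
                if len(m) >= 3 and len(f) >= 3:
                    res = choose_and_run_test(m, f, tails=1, alpha=family_alpha)
                    records.append(
                        {
                            "movement": movement,
                            "metric": "speed_mps",
                            "test": res.test,
                            "n_female": res.n_b,
                            "n_male": res.n_a,
                            "mean_female": res.mean_b,
                            "mean_male": res.mean_a,
                            "p": res.p,
                            "cohens_d": res.cohens_d,
                            "alpha": res.alpha,
                            "significant": res.significant,
                            "percent_difference": percent_difference(res.mean_a, res.mean_b),
                        }
                    )
            else:
                _compare("speed_mps", movement, f, m, tails=2, alpha=family_alpha)
    return pd.DataFrame(records)


def make_demo_cohort(
    out_dir: str | Path,
    n_per_gender: int = 10,
    seed: int = 0,
    n_walk: int = 3,
    n_run: int = 2,
    n_sts: int = 3,
) -> Path:
    """Write a synthetic cohort mirroring the study's five conditions.

    Per subject: walking, self-selected running, 3.0 m/s set-speed running
    and sit-stand-sit trials, each with a ground-truth sidecar.  Trial
    counts default to a scaled-down demo; pass larger counts for
    study-scale cohorts (10 walking, 5 + 5 running, 10 sit-to-stand).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    anthro = {
        "female": {"height": (1.628, 0.059), "mass": (59.9, 7.2), "dhat": (4.86, 0.20)},
        "male": {"height": (1.751, 0.067), "mass": (71.8, 8.7), "dhat": (5.53, 0.20)},
    }
    speed_dist = {
        "female": {"walk": (1.28, 0.18), "run_selfselect": (2.71, 0.37), "run_set": (3.0, 0.01)},
        "male": {"walk": (1.31, 0.19), "run_selfselect": (2.97, 0.56), "run_set": (3.0, 0.01)},
    }
    for gender in ("female", "male"):
        for i in range(n_per_gender):
            sid = f"{gender[0]}{i:02d}"
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            a = anthro[gender]
            subject = SubjectProfile(
                gender=gender,
                height_m=max(1.40, rng.normal(*a["height"])),
                mass_kg=max(40.0, rng.normal(*a["mass"])),
                midcondylar_d_cm=max(3.5, rng.normal(*a["dhat"])),
                subject_id=sid,
            )
            subject.to_json(sdir / "subject.json")
            counts = {"walk": n_walk, "run_selfselect": n_run, "run_set": n_run}
            for movement, n_trials in counts.items():
                mu, sd = speed_dist[gender][movement]
                for k in range(n_trials):
                    spec = GaitTrialSpec(
                        movement_class=movement,
                        subject=subject,
                        seed=int(rng.integers(2**31 - 1)),
                        speed_mps=float(max(0.5, rng.normal(mu, sd))),
                        stride_duration_s=float(
                            np.clip(
                                rng.normal(1.10 if movement == "walk" else 0.72, 0.04),
                                0.5,
                                1.5,
                            )
                        ),
                    )
                    trial, truth = generate_gait_trial(spec)
                    path = sdir / f"{movement}_{k:02d}.tsv"
                    trial.to_tsv(path)
                    path.with_suffix(".meta.json").write_text(
                        json.dumps(
                            {
                                "speed_mps": spec.speed_mps,
                                "stride_duration_s": spec.stride_duration_s,
                                "heel_strikes": truth.heel_strikes.tolist(),
                            }
                        )
                    )
            for k in range(n_sts):
                jitter = int(rng.integers(0, 300))
                spec = StsTrialSpec(
                    phase_boundaries=(
                        400 + jitter,
                        1400 + jitter,
                        2500 + jitter,
                        4100 + jitter,
                        5100 + jitter,
                    ),
                    bodyweight_n=subject.bodyweight_n,
                    noise_sd=0.01 * subject.bodyweight_n,
                    noise_sd_vz=0.005,
                    seed=int(rng.integers(2**31 - 1)),
                    subject=subject,
                )
                trial, truth = generate_sts_trace(spec)
                path = sdir / f"sts_{k:02d}.tsv"
                trial.to_tsv(path)
                path.with_suffix(".meta.json").write_text(
                    json.dumps({"events": truth.events, "boundaries": list(truth.boundaries)})
                )
    return out_dir
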