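"""Signal conditioning and trial segmentation.

Conditioning is a 4th-order dual-pass (forward-backward, zero-phase)
Butterworth low-pass: 45 Hz for ground reaction forces, 10 Hz for kinematic
and moment channels in running and 6 Hz for other movements.  Segmentation
covers gait contact events (20 N vertical-force threshold), stride windows,
and the formula-defined sit-to-stand / stand-to-sit phase boundaries:

- sit-to-stand starts where |dFz/dt| first reaches 10% of its trial
  peak-to-peak value (seat unloading) and ends at quiet standing,
  Fz within (1 ± 0.01)·BW sustained for 200 ms;
- stand-to-sit starts after the quiet standing period where Fz ≤ 0.98·BW and
  ends where |dFy/dt| drops to 1% of its trial peak-to-peak value or the
  pelvis vertical velocity magnitude drops below 0.02 m/s, whichever first.

Numerical choices: derivatives are central differences; threshold crossings
resolve to the first discrete sample satisfying the condition (no sub-sample
interpolation); derivative/threshold logic runs on a 3 Hz-smoothed copy of
the relevant channel (sit-stand transitions evolve over ~1 s, so their
content lies well below 2 Hz) so that derivative noise does not swamp the
peak-to-peak thresholds; phase-end clauses carry a 100 ms sustain
requirement (instantaneous equality is measure-zero on sampled data).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .trial import (
    ANGLE_CHANNELS,
    GRF_CHANNELS,
    MOMENT_CHANNELS,
    FilterSpec,
    PhaseWindow,
    TrialTimeSeries,
)


class EventNotFoundError(RuntimeError):
    """Raised when a trial contains no event satisfying a phase definition."""


def filter_dual_pass(signal, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    """Zero-phase Butterworth filtering (forward-backward).

    The magnitude response is squared by the second pass, so a sinusoid at
    the nominal cutoff is attenuated to 0.5; no cutoff correction is applied.
    Output has the same length and units as the input.
    """
    nyquist = rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz at rate {rate_hz} Hz"
        )
    x = np.asarray(signal, dtype=float)
    b, a = butter(spec.order, spec.cutoff_hz / nyquist)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"signal too short to filter: need > {padlen} samples")
    return filtfilt(b, a, x)


def filter_trial(
    trial: TrialTimeSeries, grf_cutoff_hz: float = 45.0, kin_cutoff_hz: float = 6.0
) -> TrialTimeSeries:
    """Condition all channels of a trial with the movement-class cutoffs."""
    updates = {}
    for ch in GRF_CHANNELS:
        updates[ch] = filter_dual_pass(trial[ch], FilterSpec(grf_cutoff_hz), trial.rate_hz)
    for ch in ANGLE_CHANNELS + MOMENT_CHANNELS + ["pelvis_vz"]:
        updates[ch] = filter_dual_pass(trial[ch], FilterSpec(kin_cutoff_hz), trial.rate_hz)
    return trial.copy_with(**updates)


def _central_diff(x: np.ndarray, rate_hz: float) -> np.ndarray:
    return np.gradient(np.asarray(x, float), 1.0 / rate_hz)


def _sustained_from(mask: np.ndarray, n_sustain: int) -> np.ndarray:
    """Indices i where ``mask[i : i + n_sustain]`` is all True."""
    if n_sustain <= 1:
        return np.flatnonzero(mask)
    ok = np.convolve(mask.astype(int), np.ones(n_sustain, dtype=int), mode="valid")
    return np.flatnonzero(ok == n_sustain)


def _smooth(x: np.ndarray, rate_hz: float, cutoff_hz: float = 3.0) -> np.ndarray:
    return filter_dual_pass(x, FilterSpec(cutoff_hz), rate_hz)


def detect_heel_strikes(
    fz, rate_hz: float, threshold_n: float = 20.0, sustain_s: float = 0.010
) -> np.ndarray:
    """Upward crossings of the contact threshold sustained for >= 10 ms.

    Returns the strictly increasing indices of the first sample at or above
    ``threshold_n`` for each sustained contact onset; an empty array when the
    foot never contacts the plate.
    """
    if threshold_n <= 0:
        raise ValueError("threshold must be positive")
    fz = np.asarray(fz, dtype=float)
    above = fz >= threshold_n
    n_sustain = max(1, int(round(sustain_s * rate_hz)))
    sustained = np.zeros(len(fz), dtype=bool)
    idx = _sustained_from(above, n_sustain)
    sustained[idx] = True
    onsets = np.flatnonzero(sustained & ~np.concatenate(([True], above[:-1])))
    # first sample can itself be an onset only if the trial starts airborne
    return onsets


def extract_strides(
    events: np.ndarray, trial: TrialTimeSeries, max_strides: int = 5
) -> list[PhaseWindow]:
    """Heel-strike-to-heel-strike stride windows, cleaned and capped.

    A stride is "clean" when its force channels contain no gaps (NaNs) and
    its duration lies within 2 SD of the trial median duration.  The SD gate
    carries a 2%-of-median floor so that a set of near-identical durations
    (SD below one sample) does not reject single-sample timing jitter.  At
    most the first ``max_strides`` clean windows are retained, mirroring the
    five clean strides analysed per trial.
    """
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        raise EventNotFoundError("no stride: fewer than two heel strikes")
    durations = np.diff(events)
    med = np.median(durations)
    sd = durations.std(ddof=1) if len(durations) > 1 else 0.0
    tol = max(2 * sd, 0.02 * med)
    windows = []
    fz = trial["fz"]
    for start, end, dur in zip(events[:-1], events[1:], durations):
        if abs(dur - med) > tol:
            continue
        if np.isnan(fz[start:end]).any():
            continue
        windows.append(PhaseWindow("stride", int(start), int(end)))
        if len(windows) == max_strides:
            break
    return windows


def stance_window(
    trial: TrialTimeSeries, stride: PhaseWindow, threshold_n: float = 20.0
) -> PhaseWindow:
    """Contact portion of a stride: from the heel strike until the vertical
    force first drops below the contact threshold."""
    fz = trial["fz"][stride.slice()]
    below = np.flatnonzero(fz < threshold_n)
    end = stride.start_index + (int(below[0]) if len(below) else len(fz))
    return PhaseWindow("stance", stride.start_index, max(end, stride.start_index + 1))


def _quiet_standing_onset(
    fz_s: np.ndarray, bodyweight_n: float, rate_hz: float, band: float, sustain_s: float
) -> int:
    in_band = np.abs(fz_s - bodyweight_n) <= band * bodyweight_n
    idx = _sustained_from(in_band, max(1, int(round(sustain_s * rate_hz))))
    if len(idx) == 0:
        raise EventNotFoundError("no event: no quiet standing period found")
    return int(idx[0])


def detect_sit_to_stand(
    trial: TrialTimeSeries,
    bodyweight_n: float,
    derivative_fraction: float = 0.10,
    standing_band: float = 0.01,
    sustain_s: float = 0.200,
    smooth_cutoff_hz: float = 3.0,
) -> PhaseWindow:
    """Sit-to-stand window: seat unloading to sustained quiet standing.

    Start: first sample where |dFz/dt| >= 10% of its trial peak-to-peak
    value while the vertical force is still below the standing band (the
    seat-unloading surge).  End: first sample from which Fz stays within
    (1 ± 0.01)·BW for 200 ms.
    """
    if bodyweight_n <= 0:
        raise ValueError("bodyweight must be positive")
    fz_s = _smooth(trial["fz"], trial.rate_hz, smooth_cutoff_hz)
    dfz = _central_diff(fz_s, trial.rate_hz)
    pp = dfz.max() - dfz.min()
    if pp <= 0:
        raise EventNotFoundError("no event: vertical force has no dynamics")
    below_band = fz_s < (1.0 - standing_band) * bodyweight_n
    surge = (np.abs(dfz) >= derivative_fraction * pp) & below_band
    # a genuine unloading surge rises out of quiet sitting and stays above
    # threshold for tens of ms; requiring a quiet 100 ms lead-in and a short
    # forward sustain rejects filter edge transients and noise excursions
    n_pre = max(1, int(round(0.100 * trial.rate_hz)))
    sustained = np.zeros(len(surge), dtype=bool)
    sustained[_sustained_from(surge, max(1, int(round(0.030 * trial.rate_hz))))] = True
    quiet = (~surge).astype(int)
    lead = np.convolve(quiet, np.ones(n_pre, dtype=int), mode="valid")  # windows [j, j+n_pre)
    candidates = [
        i
        for i in np.flatnonzero(sustained)
        if i >= n_pre and lead[i - n_pre] == n_pre
    ]
    if not candidates:
        raise EventNotFoundError("no event: no seat-unloading surge found")
    start = int(candidates[0])
    in_band = np.abs(fz_s - bodyweight_n) <= standing_band * bodyweight_n
    n_sustain = max(1, int(round(sustain_s * trial.rate_hz)))
    idx = _sustained_from(in_band, n_sustain)
    idx = idx[idx > start]
    if len(idx) == 0:
        raise EventNotFoundError("no event: quiet standing never reached")
    return PhaseWindow("sit_to_stand", start, int(idx[0]))


def detect_stand_to_sit(
    trial: TrialTimeSeries,
    bodyweight_n: float,
    unload_fraction: float = 0.98,
    derivative_fraction: float = 0.01,
    vz_threshold: float = 0.02,
    standing_band: float = 0.01,
    standing_sustain_s: float = 0.200,
    end_sustain_s: float = 0.100,
    smooth_cutoff_hz: float = 3.0,
) -> PhaseWindow:
    """Stand-to-sit window: descent onset after quiet standing to quiet sitting.

    Start: first sample at or after the quiet-standing period with
    Fz <= 0.98·BW.  End: first subsequent sample where |dFy/dt| <= 1% of its
    trial peak-to-peak value OR |pelvis vz| < 0.02 m/s, whichever comes
    first; either clause must hold for 100 ms to reject instantaneous
    derivative zero-crossings mid-descent.
    """
    if bodyweight_n <= 0:
        raise ValueError("bodyweight must be positive")
    rate = trial.rate_hz
    fz_s = _smooth(trial["fz"], rate, smooth_cutoff_hz)
    stand0 = _quiet_standing_onset(fz_s, bodyweight_n, rate, standing_band, standing_sustain_s)
    below = np.flatnonzero(fz_s[stand0:] <= unload_fraction * bodyweight_n)
    if len(below) == 0:
        raise EventNotFoundError("no event: force never drops below 0.98 BW after standing")
    start = stand0 + int(below[0])

    fy_s = _smooth(trial["fy"], rate, smooth_cutoff_hz)
    dfy = _central_diff(fy_s, rate)
    pp = dfy.max() - dfy.min()
    quiet_fy = np.abs(dfy) <= derivative_fraction * pp
    vz_s = _smooth(trial["pelvis_vz"], rate, smooth_cutoff_hz)
    quiet_vz = np.abs(vz_s) < vz_threshold
    n_sustain = max(1, int(round(end_sustain_s * rate)))
    ends = np.concatenate(
        [_sustained_from(quiet_fy, n_sustain), _sustained_from(quiet_vz, n_sustain)]
    )
    ends = ends[ends > start]
    if len(ends) == 0:
        raise EventNotFoundError("no event: quiet sitting never reached")
    return PhaseWindow("stand_to_sit", start, int(ends.min()))
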