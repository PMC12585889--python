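"""Fixation detection from raw gaze traces by angular-speed thresholding.

Samples moving faster than 30 deg/s are saccadic; contiguous sub-threshold runs
become candidate fixations, which are then (a) merged when closer than 0.5 deg
and 75 ms apart, (b) dropped when shorter than 50 ms, and (c) dropped when
longer than 3 SD above a participant's mean fixation duration. Rule (c) pools
durations across all of a participant's trials, so it lives in a separate
dataset-level pass (:func:`apply_duration_outlier_rule`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ViewingGeometry


@dataclass
class Fixation:
    """One detected fixation event."""

    onset: float   # ms
    offset: float  # ms
    x: float       # centroid, px
    y: float       # centroid, px

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the speed-threshold detector and its cleaning rules."""

    speed_thresh_deg_s: float = 30.0
    merge_dist_deg: float = 0.5
    merge_gap_ms: float = 75.0
    min_duration_ms: float = 50.0
    outlier_sd: float = 3.0
    smooth_window: int = 0  # moving-average window over speeds; 0 disables


def angular_speed(trace, geometry: ViewingGeometry) -> np.ndarray:
    """Per-sample angular speed in deg/s.

    Speed at sample ``i`` is the angular displacement from the previous valid
    sample divided by the elapsed time; the first valid sample inherits the
    second's speed. Invalid samples get NaN.
    """
    valid = np.asarray(trace.valid, dtype=bool)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid samples to compute speed")
    t = np.asarray(trace.t_ms, dtype=float)[valid]
    x = np.asarray(trace.x_px, dtype=float)[valid]
    y = np.asarray(trace.y_px, dtype=float)[valid]
    disp_px = np.hypot(np.diff(x), np.diff(y))
    dt_s = np.diff(t) / 1000.0
    if np.any(dt_s <= 0):
        raise ValueError("timestamps must be strictly increasing")
    sp = geometry.px_to_deg(disp_px) / dt_s
    speeds_valid = np.concatenate([[sp[0]], sp])
    out = np.full(len(valid), np.nan)
    out[valid] = speeds_valid
    return out


def _candidate_fixations(trace, geometry, params: DetectionParams) -> list[Fixation]:
    speeds = angular_speed(trace, geometry)
    if params.smooth_window > 1:
        k = params.smooth_window
        kern = np.ones(k) / k
        finite = np.isfinite(speeds)
        sm = np.convolve(np.where(finite, speeds, 0.0), kern, mode="same")
        norm = np.convolve(finite.astype(float), kern, mode="same")
        with np.errstate(invalid="ignore"):
            speeds = np.where(finite, sm / np.maximum(norm, 1e-12), np.nan)
    is_fix = np.isfinite(speeds) & (speeds <= params.speed_thresh_deg_s)
    t = np.asarray(trace.t_ms, dtype=float)
    x = np.asarray(trace.x_px, dtype=float)
    y = np.asarray(trace.y_px, dtype=float)

    out: list[Fixation] = []
    i, n = 0, len(is_fix)
    while i < n:
        if not is_fix[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_fix[j + 1]:
            j += 1
        if j > i:  # single-sample runs have zero duration; drop them
            out.append(Fixation(onset=t[i], offset=t[j],
                                x=float(x[i:j + 1].mean()),
                                y=float(y[i:j + 1].mean())))
        i = j + 1
    return out


def _merge_pass(cands: list[Fixation], geometry, params: DetectionParams) -> list[Fixation]:
    # greedy left-to-right; a merged fixation may keep absorbing its successor
    merged: list[Fixation] = []
    for f in cands:
        if merged:
            prev = merged[-1]
            gap = f.onset - prev.offset
            dist_deg = float(geometry.px_to_deg(np.hypot(f.x - prev.x, f.y - prev.y)))
            if gap <= params.merge_gap_ms and dist_deg <= params.merge_dist_deg:
                w1, w2 = prev.duration, f.duration
                wsum = max(w1 + w2, 1e-12)
                merged[-1] = Fixation(
                    onset=prev.onset, offset=f.offset,
                    x=(prev.x * w1 + f.x * w2) / wsum,
                    y=(prev.y * w1 + f.y * w2) / wsum,
                )
                continue
        merged.append(f)
    return merged


def detect_fixations(trace, geometry: ViewingGeometry,
                     params: DetectionParams | None = None) -> list[Fixation]:
    """Detect fixations in one trace, applying cleaning rules (a) and (b).

    Returns a time-ordered, non-overlapping list. Empty traces yield an empty
    list. The per-participant duration-outlier rule (c) is applied afterwards
    across trials with :func:`apply_duration_outlier_rule`.
    """
    if geometry is None:
        raise ValueError("viewing geometry is required")
    params = params or DetectionParams()
    if len(np.asarray(trace.t_ms)) == 0:
        return []
    cands = _candidate_fixations(trace, geometry, params)
    merged = _merge_pass(cands, geometry, params)
    return [f for f in merged if f.duration >= params.min_duration_ms]


def apply_duration_outlier_rule(trials: dict, params: DetectionParams | None = None) -> dict:
    """Cleaning rule (c): drop fixations > mean + ``outlier_sd``·SD per participant.

    ``trials`` maps (participant_id, trial_id) -> list of fixations from
    :func:`detect_fixations`; duration statistics pool all trials of each
    participant. Returns a dict of the same shape.
    """
    params = params or DetectionParams()
    by_participant: dict[str, list[float]] = {}
    for (pid, _tid), fixes in trials.items():
        by_participant.setdefault(pid, []).extend(f.duration for f in fixes)
    cutoffs = {}
    for pid, durs in by_participant.items():
        d = np.asarray(durs, dtype=float)
        cutoffs[pid] = np.inf if len(d) < 2 else d.mean() + params.outlier_sd * d.std(ddof=1)
    return {key: [f for f in fixes if f.duration <= cutoffs[key[0]]]
            for key, fixes in trials.items()}
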