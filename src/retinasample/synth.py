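"""Parametric face-like stimuli, observer sampling policies, and gaze traces.

The generator emulates the statistical structure the downstream analysis
assumes, without any photographic content:

* identities are grayscale "face-like" layouts — an oval face carrying shared
  base features plus identity-specific high-frequency texture patches at 2-4
  randomly chosen feature regions, so diagnostic information is spatially
  non-uniform and identity-specific;
* each identity has a neutral and a happy stimulus differing only inside the
  designated expression regions (mouth and brow);
* observers are sampling policies that differ in how many fixations they make,
  how broadly they spread them, and how strongly they target high-diagnosticity
  locations (random / control / super);
* gaze traces alternate low-speed dwells around fixation targets with brief
  high-speed saccades, plus smooth oculomotor jitter, at eye-tracker rates.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .controls import RegionMask
from .geometry import ViewingGeometry, default_geometry

SPOTLIGHT_SIZES = (12, 24, 36, 48, 60, 100)
EXPRESSIONS = ("neutral", "happy")

# regions that may carry identity-diagnostic texture; mouth and brow are
# reserved for the expression manipulation so expressions never alter identity
# features
_IDENTITY_REGIONS = ("eye_left", "eye_right", "nose", "chin",
                     "cheek_left", "cheek_right", "forehead")
_REGION_OF_SITE = {"eye_left": "eyes", "eye_right": "eyes", "nose": "nose",
                   "chin": "chin", "cheek_left": "cheeks", "cheek_right": "cheeks",
                   "forehead": "forehead"}

_BASE_SEED = 171_717        # shared face scaffold, common to all identities
_EXPR_SEEDS = {"neutral": 271_828, "happy": 314_159}

GENDERS = ("F", "M")
ETHNICITIES = ("A", "B")
AGE_BANDS = ("young", "middle", "older")


@dataclass(frozen=True)
class SyntheticIdentity:
    identity_id: str
    feature_patches: list  # (site name, center x px, center y px, appearance seed)
    demographics: dict     # gender / ethnicity / age_band
    diagnosticity_map: np.ndarray  # per-pixel weight in [0, 1]


@dataclass(frozen=True)
class StimulusImage:
    pixels: np.ndarray     # 2-D luminance in [0, 1]
    identity_id: str
    expression: str
    face_bounds: tuple[int, int, int, int]  # x0, y0, x1, y1 (exclusive)


@dataclass(frozen=True)
class ObserverPolicy:
    """How an observer distributes fixations over a face.

    ``targeting_weight`` is the probability that a fixation target is drawn
    from the identity's diagnosticity map rather than from an isotropic
    face-centered Gaussian of scale ``spread_sigma``.
    """

    source_label: str
    n_fixations_mean: float = 10.0
    spread_sigma: float = 55.0            # px
    targeting_weight: float = 0.0
    fixation_duration_params: tuple[float, float] = (420.0, 120.0)  # mean, sd (ms)
    jitter_sd_deg: float = 0.15
    jitter_rho: float = 0.9               # AR(1) smoothness of the jitter
    seed: int | None = None


@dataclass
class GazeTrace:
    """Raw time-stamped gaze samples for one learning trial."""

    participant_id: str
    trial_id: str
    spotlight_pct: int
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    rate_hz: float


# ---------------------------------------------------------------------------
# face layout

def _face_layout(size: int):
    cx, cy = size / 2.0, size / 2.0
    a, b = 0.32 * size, 0.42 * size   # face semi-axes
    sites = {
        "eye_left": (cx - 0.42 * a, cy - 0.25 * b),
        "eye_right": (cx + 0.42 * a, cy - 0.25 * b),
        "nose": (cx, cy + 0.05 * b),
        "mouth": (cx, cy + 0.50 * b),
        "chin": (cx, cy + 0.80 * b),
        "cheek_left": (cx - 0.55 * a, cy + 0.18 * b),
        "cheek_right": (cx + 0.55 * a, cy + 0.18 * b),
        "brow_left": (cx - 0.42 * a, cy - 0.45 * b),
        "brow_right": (cx + 0.42 * a, cy - 0.45 * b),
        "forehead": (cx, cy - 0.72 * b),
    }
    return cx, cy, a, b, sites


def face_bounds(size: int) -> tuple[int, int, int, int]:
    cx, cy, a, b, _ = _face_layout(size)
    return (int(np.floor(cx - a)), int(np.floor(cy - b)),
            int(np.ceil(cx + a)), int(np.ceil(cy + b)))


def _ellipse(size, cx, cy, rx, ry):
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def build_region_mask(size: int = 448) -> RegionMask:
    """Prototype face mask with the seven named regions, background elsewhere."""
    cx, cy, a, b, s = _face_layout(size)
    face = _ellipse(size, cx, cy, a, b)
    shapes = [
        ("eyes", _ellipse(size, *s["eye_left"], 0.28 * a, 0.13 * b)
         | _ellipse(size, *s["eye_right"], 0.28 * a, 0.13 * b)),
        ("brow", _ellipse(size, *s["brow_left"], 0.30 * a, 0.08 * b)
         | _ellipse(size, *s["brow_right"], 0.30 * a, 0.08 * b)),
        ("nose", _ellipse(size, *s["nose"], 0.15 * a, 0.26 * b)),
        ("mouth", _ellipse(size, *s["mouth"], 0.32 * a, 0.11 * b)),
        ("chin", _ellipse(size, *s["chin"], 0.36 * a, 0.15 * b)),
        ("cheeks", _ellipse(size, *s["cheek_left"], 0.24 * a, 0.20 * b)
         | _ellipse(size, *s["cheek_right"], 0.24 * a, 0.20 * b)),
        ("forehead", _ellipse(size, *s["forehead"], 0.50 * a, 0.22 * b)),
    ]
    labels = np.zeros((size, size), dtype=np.uint8)
    legend = {"background": 0}
    for code, (name, mask) in enumerate(shapes, start=1):
        legend[name] = code
        labels[mask & face & (labels == 0)] = code
    return RegionMask(labels=labels, legend=legend)


# ---------------------------------------------------------------------------
# stimulus synthesis

def _bandpass_noise(size, seed, lo=1.0, hi=3.0):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((size, size))
    bp = gaussian_filter(w, lo * size / 448.0) - gaussian_filter(w, hi * size / 448.0)
    return bp / max(bp.std(), 1e-12)


def _gauss_window(size, cx, cy, sigma):
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma ** 2))


def _base_face(size: int) -> np.ndarray:
    cx, cy, a, b, s = _face_layout(size)
    face = _ellipse(size, cx, cy, a, b)
    img = np.full((size, size), 0.45)
    img[face] = 0.72
    img = gaussian_filter(img, 0.01 * size)
    # generic shared features: darker eyes/brows/mouth, brighter nose ridge
    for site, amp in (("eye_left", -0.18), ("eye_right", -0.18), ("mouth", -0.12),
                      ("brow_left", -0.10), ("brow_right", -0.10), ("nose", 0.08)):
        img += amp * _gauss_window(size, *s[site], 0.035 * size)
    img += 0.04 * gaussian_filter(_bandpass_noise(size, _BASE_SEED, 2.0, 8.0), 0.005 * size)
    return img


def _expression_overlay(size: int, expression: str, mask: RegionMask) -> np.ndarray:
    """Texture confined (exactly) to the mouth and brow label pixels."""
    region = np.isin(mask.labels, [mask.legend["mouth"], mask.legend["brow"]])
    pattern = 0.15 * _bandpass_noise(size, _EXPR_SEEDS[expression], 1.5, 5.0)
    out = np.zeros((size, size))
    out[region] = pattern[region]
    return out


def generate_identities(n_identities: int, image_size: int = 448, seed: int = 0):
    """Generate identities with neutral/happy stimuli and diagnosticity maps.

    Returns ``(identities, stimuli)`` where ``stimuli[(identity_id, expression)]``
    is a :class:`StimulusImage`. Deterministic for a fixed seed. Demographics
    are assigned in consecutive pairs so every identity has at least one peer
    sharing its gender, ethnicity and age band.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities to form non-match pairs")
    mask = build_region_mask(image_size)
    base = _base_face(image_size)
    overlays = {e: _expression_overlay(image_size, e, mask) for e in EXPRESSIONS}
    _, _, _, _, sites = _face_layout(image_size)
    bounds = face_bounds(image_size)

    identities, stimuli = [], {}
    for i in range(n_identities):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        k = int(rng.integers(2, 5))  # 2-4 diagnostic sites
        while True:  # sites must span >= 2 distinct face regions
            chosen = list(rng.choice(len(_IDENTITY_REGIONS), size=k, replace=False))
            labels = {_REGION_OF_SITE[_IDENTITY_REGIONS[c]] for c in chosen}
            if len(labels) >= 2:
                break
        idimg = np.zeros((image_size, image_size))
        diag = np.zeros((image_size, image_size))
        patches = []
        for site_idx in chosen:
            site = _IDENTITY_REGIONS[site_idx]
            cx, cy = sites[site]
            patch_seed = int(rng.integers(2 ** 31))
            window = _gauss_window(image_size, cx, cy, 0.06 * image_size)
            idimg += 0.45 * window * _bandpass_noise(image_size, patch_seed)
            diag += window
            patches.append((site, float(cx), float(cy), patch_seed))
        diag /= max(diag.max(), 1e-12)

        pair = i - 1 if (i == n_identities - 1 and n_identities % 2 == 1) else i
        cell = (pair // 2) % (len(GENDERS) * len(ETHNICITIES) * len(AGE_BANDS))
        demo = {"gender": GENDERS[cell % 2],
                "ethnicity": ETHNICITIES[(cell // 2) % 2],
                "age_band": AGE_BANDS[(cell // 4) % 3]}
        ident = SyntheticIdentity(identity_id=f"id{i:03d}", feature_patches=patches,
                                  demographics=demo, diagnosticity_map=diag)
        identities.append(ident)
        for expr in EXPRESSIONS:
            px = np.clip(base + idimg + overlays[expr], 0.0, 1.0)
            stimuli[(ident.identity_id, expr)] = StimulusImage(
                pixels=px, identity_id=ident.identity_id, expression=expr,
                face_bounds=bounds)
    return identities, stimuli


# ---------------------------------------------------------------------------
# observer policies and gaze traces

def default_policies(image_size: int = 448,
                     targeting=(0.0, 0.3, 0.7)) -> dict[str, ObserverPolicy]:
    """Random / control / super sampling policies at the study's conditions.

    Targeting weights order random < control < super; the super policy also
    spreads fixations at least as broadly as controls.
    """
    scale = image_size / 448.0
    tw_random, tw_control, tw_super = targeting
    # the isotropic spread is matched across sources so that group differences
    # arise from diagnosticity targeting alone; the super group's empirically
    # broader fixation distribution emerges from targeting dispersed
    # identity-specific patches
    pols = {
        "random": ObserverPolicy("random", spread_sigma=55.0 * scale,
                                 targeting_weight=tw_random),
        "control": ObserverPolicy("control", spread_sigma=55.0 * scale,
                                  targeting_weight=tw_control),
        "super": ObserverPolicy("super", spread_sigma=55.0 * scale,
                                targeting_weight=tw_super),
    }
    assert pols["random"].targeting_weight == 0.0
    assert pols["super"].targeting_weight > pols["control"].targeting_weight
    assert pols["super"].spread_sigma >= pols["control"].spread_sigma
    return pols


def _sample_targets(policy, stimulus, diagnosticity_map, n, rng):
    size = stimulus.pixels.shape[0]
    x0, y0, x1, y1 = stimulus.face_bounds
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    targets = np.empty((n, 2))
    use_map = rng.random(n) < policy.targeting_weight
    if use_map.any():
        if diagnosticity_map is None:
            raise ValueError("targeting_weight > 0 requires a diagnosticity map")
        p = diagnosticity_map.ravel() / diagnosticity_map.sum()
        idx = rng.choice(diagnosticity_map.size, size=int(use_map.sum()), p=p)
        yy, xx = np.unravel_index(idx, diagnosticity_map.shape)
        targets[use_map, 0] = xx
        targets[use_map, 1] = yy
    n_iso = int((~use_map).sum())
    if n_iso:
        targets[~use_map] = rng.normal([cx, cy], policy.spread_sigma, size=(n_iso, 2))
    targets[:, 0] = np.clip(targets[:, 0], x0 + 2, x1 - 2)
    targets[:, 1] = np.clip(targets[:, 1], y0 + 2, y1 - 2)
    return targets


def generate_gaze_trace(policy: ObserverPolicy, stimulus: StimulusImage,
                        geometry: ViewingGeometry | None = None,
                        duration_ms: float = 5000.0, rate_hz: float = 120.0,
                        seed: int = 0, diagnosticity_map: np.ndarray | None = None,
                        participant_id: str = "p000", trial_id: str = "t000",
                        spotlight_pct: int = 100,
                        saccade_ms: float = 30.0) -> GazeTrace:
    """Simulate one learning-trial gaze trace under a sampling policy.

    The trace dwells at each fixation target (low angular speed: only smooth
    AR(1) jitter) and jumps between targets with short linear saccades whose
    speed far exceeds the saccade threshold.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if rate_hz < 60:
        raise ValueError("sampling rate below 60 Hz cannot represent saccades")
    geometry = geometry or default_geometry(stimulus.pixels.shape[0])
    rng = np.random.default_rng(seed)

    mean_n = policy.n_fixations_mean
    n = 1 if mean_n <= 1 else max(1, int(rng.poisson(mean_n)))
    mu, sd = policy.fixation_duration_params
    durs = np.clip(rng.normal(mu, sd, size=n), 120.0, None)
    total_dwell = duration_ms - (n - 1) * saccade_ms
    while total_dwell <= n * 120.0 and n > 1:  # too many fixations to fit
        n -= 1
        durs = durs[:n]
        total_dwell = duration_ms - (n - 1) * saccade_ms
    durs = durs * (total_dwell / durs.sum())

    targets = _sample_targets(policy, stimulus, diagnosticity_map, n, rng)
    key_t, key_x, key_y = [], [], []
    t = 0.0
    for i in range(n):
        key_t += [t, t + durs[i]]
        key_x += [targets[i, 0]] * 2
        key_y += [targets[i, 1]] * 2
        t += durs[i] + saccade_ms

    t_ms = np.arange(0.0, duration_ms, 1000.0 / rate_hz)
    x = np.interp(t_ms, key_t, key_x)
    y = np.interp(t_ms, key_t, key_y)

    if policy.jitter_sd_deg > 0:
        sd_px = float(geometry.deg_to_px(policy.jitter_sd_deg))
        rho = policy.jitter_rho
        innov_sd = sd_px * np.sqrt(1.0 - rho ** 2)
        eps = rng.normal(0.0, innov_sd, size=(len(t_ms), 2))
        jit = np.empty_like(eps)
        jit[0] = rng.normal(0.0, sd_px, size=2)
        for i in range(1, len(t_ms)):
            jit[i] = rho * jit[i - 1] + eps[i]
        x = x + jit[:, 0]
        y = y + jit[:, 1]

    w, h = geometry.screen_resolution
    size = stimulus.pixels.shape[0]
    x = np.clip(x, 0, max(w, size) - 1)
    y = np.clip(y, 0, max(h, size) - 1)
    return GazeTrace(participant_id=participant_id, trial_id=trial_id,
                     spotlight_pct=spotlight_pct, t_ms=t_ms, x_px=x, y_px=y,
                     valid=np.ones(len(t_ms), dtype=bool), rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# plain-text IO

TRACE_COLUMNS = ("participant_id", "trial_id", "spotlight_pct",
                 "t_ms", "x_px", "y_px", "valid")


def write_traces_csv(traces: list[GazeTrace], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(TRACE_COLUMNS)
        for tr in traces:
            for i in range(len(tr.t_ms)):
                wr.writerow([tr.participant_id, tr.trial_id, tr.spotlight_pct,
                             f"{tr.t_ms[i]:.3f}", f"{tr.x_px[i]:.3f}",
                             f"{tr.y_px[i]:.3f}", int(tr.valid[i])])


def read_traces_csv(path) -> list[GazeTrace]:
    import pandas as pd

    df = pd.read_csv(path)
    traces = []
    for (pid, tid, pct), g in df.groupby(["participant_id", "trial_id", "spotlight_pct"],
                                         sort=False):
        t = g["t_ms"].to_numpy(float)
        rate = 1000.0 / np.median(np.diff(t)) if len(t) > 1 else 0.0
        traces.append(GazeTrace(participant_id=str(pid), trial_id=str(tid),
                                spotlight_pct=int(pct), t_ms=t,
                                x_px=g["x_px"].to_numpy(float),
                                y_px=g["y_px"].to_numpy(float),
                                valid=g["valid"].to_numpy(bool), rate_hz=rate))
    return traces


def write_stimulus_png(stimulus: StimulusImage, path) -> None:
    from PIL import Image

    arr = np.clip(stimulus.pixels * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_identity_metadata(identities: list[SyntheticIdentity], path) -> None:
    meta = []
    for ident in identities:
        d = ident.diagnosticity_map
        meta.append({
            "identity_id": ident.identity_id,
            "demographics": ident.demographics,
            "feature_patches": [{"site": s, "x": x, "y": y, "seed": sd}
                                for s, x, y, sd in ident.feature_patches],
            "diagnosticity": {"max": float(d.max()), "mean": float(d.mean()),
                              "nonzero_frac": float((d > 0.05).mean())},
        })
    Path(path).write_text(json.dumps(meta, indent=1))
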