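"""Foveated retinal reconstruction of the information revealed per trial.

Each fixation yields a foveated view: full resolution at the fixation point,
decaying with eccentricity following an acuity model r(e) = e2/(e2 + e), where
e2 = 28.75/Δ degrees is the half-resolution eccentricity (the default lossy
parameter Δ = 25 gives e2 = 1.15°, at the conservative end of the human E2
range reported for acuity-like tasks; Δ → 0 disables the acuity loss
entirely). The view is realized by blending levels of a Gaussian
pyramid: per-pixel level = −log2 r(e). A circular "spotlight" aperture whose
area is a fixed percentage of the face area masks each view, and per-trial
views combine into a composite by keeping, at every pixel, the value from the
fixation that achieves the highest resolution there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import Fixation
from .geometry import ViewingGeometry

E2_DELTA_SCALE = 28.75  # deg; e2 = E2_DELTA_SCALE / delta: delta=25 -> e2=1.15 deg
BACKGROUND_VALUE = 0.5


@dataclass(frozen=True)
class ApertureSpec:
    """Circular gaze-contingent aperture revealing a % of the face area."""

    spotlight_pct: int

    def radius_px(self, face_bounds) -> float:
        x0, y0, x1, y1 = face_bounds
        face_area = (x1 - x0) * (y1 - y0)
        return float(np.sqrt(self.spotlight_pct / 100.0 * face_area / np.pi))


@dataclass
class FoveatedView:
    pixels: np.ndarray
    resolution_map: np.ndarray  # effective resolution in [0, 1]; 1 at the fovea
    fixation: Fixation


@dataclass
class CompositeRetinalImage:
    pixels: np.ndarray
    resolution_map: np.ndarray
    trial_id: str = ""
    source_label: str = ""
    spotlight_pct: int = 100
    n_fixations: int = 0


class FoveationModel:
    """Precomputed Gaussian pyramid of one stimulus, reusable across fixations.

    Levels are kept at full resolution (level k blurred with sigma 2**(k-1)),
    so per-pixel blending is a simple gather along the level axis.
    """

    def __init__(self, stimulus, geometry: ViewingGeometry, delta: float = 25.0,
                 n_levels: int = 6):
        if delta <= 0:
            raise ValueError("delta must be positive")
        self.stimulus = stimulus
        self.geometry = geometry
        self.delta = delta
        img = np.asarray(stimulus.pixels, dtype=float)
        levels = [img]
        for k in range(1, n_levels):
            levels.append(gaussian_filter(img, sigma=2.0 ** (k - 1)))
        self.levels = np.stack(levels)           # (L, H, W)
        self.n_levels = n_levels
        h, w = img.shape
        self._yy, self._xx = np.mgrid[0:h, 0:w]
        self.e2_deg = E2_DELTA_SCALE / delta

    def resolution_at(self, fixation: Fixation) -> np.ndarray:
        ecc_px = np.hypot(self._xx - fixation.x, self._yy - fixation.y)
        ecc_deg = self.geometry.px_to_deg(ecc_px)
        return self.e2_deg / (self.e2_deg + ecc_deg)

    def view(self, fixation: Fixation) -> FoveatedView:
        h, w = self.levels.shape[1:]
        if not (0 <= fixation.x < w and 0 <= fixation.y < h):
            raise ValueError("fixation centroid outside the image")
        res = self.resolution_at(fixation)
        level = np.clip(-np.log2(res), 0.0, self.n_levels - 1.0)
        lo = np.floor(level).astype(int)
        hi = np.minimum(lo + 1, self.n_levels - 1)
        frac = level - lo
        px_lo = np.take_along_axis(self.levels, lo[None], axis=0)[0]
        px_hi = np.take_along_axis(self.levels, hi[None], axis=0)[0]
        return FoveatedView(pixels=(1 - frac) * px_lo + frac * px_hi,
                            resolution_map=res, fixation=fixation)


def foveate(stimulus, fixation: Fixation, geometry: ViewingGeometry,
            delta: float = 25.0, n_levels: int = 6) -> FoveatedView:
    """One-shot foveation (builds the pyramid; use FoveationModel for many)."""
    return FoveationModel(stimulus, geometry, delta, n_levels).view(fixation)


def apply_aperture(view: FoveatedView, spec: ApertureSpec, face_bounds,
                   background: float = BACKGROUND_VALUE,
                   edge_ramp_px: float = 0.0) -> FoveatedView:
    """Mask a view outside the circular spotlight centered on its fixation.

    At 100% the view passes through unchanged. ``edge_ramp_px`` > 0 applies a
    cosine ramp of that width instead of a hard edge (default hard).
    """
    if spec.spotlight_pct >= 100:
        return view
    h, w = view.pixels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - view.fixation.x, yy - view.fixation.y)
    r = spec.radius_px(face_bounds)
    if edge_ramp_px > 0:
        t = np.clip((dist - (r - edge_ramp_px)) / edge_ramp_px, 0.0, 1.0)
        keep = 0.5 * (1.0 + np.cos(np.pi * t))
    else:
        keep = (dist <= r).astype(float)
    return FoveatedView(pixels=keep * view.pixels + (1 - keep) * background,
                        resolution_map=keep * view.resolution_map,
                        fixation=view.fixation)


def composite(views: list[FoveatedView], trial_id: str = "",
              source_label: str = "", spotlight_pct: int = 100,
              background: float = BACKGROUND_VALUE) -> CompositeRetinalImage:
    """Combine per-fixation views: at each pixel keep the highest-resolution one.

    Ties break toward the earlier fixation. Pixels no fixation reveals stay at
    the background value with resolution 0.
    """
    if not views:
        raise ValueError("need at least one view to composite")
    shape = views[0].pixels.shape
    if any(v.pixels.shape != shape for v in views):
        raise ValueError("all views must share the stimulus shape")
    res = np.stack([v.resolution_map for v in views])
    px = np.stack([v.pixels for v in views])
    best = np.argmax(res, axis=0)  # first max wins -> earlier fixation
    best_res = np.take_along_axis(res, best[None], axis=0)[0]
    best_px = np.take_along_axis(px, best[None], axis=0)[0]
    out_px = np.where(best_res > 0, best_px, background)
    return CompositeRetinalImage(pixels=out_px, resolution_map=best_res,
                                 trial_id=trial_id, source_label=source_label,
                                 spotlight_pct=spotlight_pct, n_fixations=len(views))


def write_composite_png(comp: CompositeRetinalImage, path, tau: float = 0.05) -> None:
    """Write a composite as 8-bit PNG with a JSON sidecar of its provenance."""
    import json
    from pathlib import Path

    from PIL import Image

    arr = np.clip(comp.pixels * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    Path(path).with_suffix(".json").write_text(json.dumps({
        "trial_id": comp.trial_id, "source_label": comp.source_label,
        "spotlight_pct": comp.spotlight_pct, "n_fixations": comp.n_fixations,
        "revealed_fraction": float((comp.resolution_map > tau).mean()),
    }))


def reconstruct_trial(model: FoveationModel, fixations: list[Fixation],
                      spec: ApertureSpec, trial_id: str = "",
                      source_label: str = "",
                      background: float = BACKGROUND_VALUE,
                      edge_ramp_px: float = 0.0) -> CompositeRetinalImage:
    """Foveate + aperture every fixation of a trial and composite the views."""
    fb = model.stimulus.face_bounds
    views = [apply_aperture(model.view(f), spec, fb, background, edge_ramp_px)
             for f in fixations]
    return composite(views, trial_id=trial_id, source_label=source_label,
                     spotlight_pct=spec.spotlight_pct, background=background)
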