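"""Proportion of the original face's information preserved in a composite.

Two bounded components are combined:

* a structural-similarity term — the local SSIM map between composite and
  original (canonical 11x11 Gaussian-windowed formulation, rescaled from
  [-1, 1] to [0, 1]) averaged over the face bounds, weighted by the revealed
  indicator so that unrevealed face pixels contribute zero;
* a pixel-test term — the fraction of face pixels revealed at usable
  resolution (resolution map above a small threshold).

Both lie in [0, 1], equal 1 for a full-fidelity composite, 0 for an
all-background composite, and grow monotonically as more of the face is
revealed. The default information proportion is their equal-weight mean; the
components are always reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

REVEALED_TAU = 0.05


@dataclass(frozen=True)
class InfoProportion:
    value: float
    ssim_term: float
    pixel_term: float
    trial_id: str = ""


def _face_crop(arr: np.ndarray, face_bounds) -> np.ndarray:
    x0, y0, x1, y1 = face_bounds
    return arr[y0:y1, x0:x1]


def structural_similarity_term(composite, original: np.ndarray, face_bounds,
                               tau: float = REVEALED_TAU) -> float:
    """Revealed-weighted mean local SSIM over the face bounds, in [0, 1]."""
    comp = _face_crop(np.asarray(composite.pixels, float), face_bounds)
    orig = _face_crop(np.asarray(original, float), face_bounds)
    if comp.shape != orig.shape:
        raise ValueError("composite and original must share shape")
    revealed = _face_crop(composite.resolution_map, face_bounds) > tau
    if not revealed.any():
        return 0.0
    _, ssim_map = structural_similarity(
        orig, comp, data_range=1.0, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, full=True)
    ssim01 = np.clip((ssim_map + 1.0) / 2.0, 0.0, 1.0)
    return float((ssim01 * revealed).sum() / revealed.size)


def pixel_test_term(composite, face_bounds, tau: float = REVEALED_TAU) -> float:
    """Fraction of face-bounds pixels revealed at usable resolution."""
    revealed = _face_crop(composite.resolution_map, face_bounds) > tau
    return float(revealed.mean())


def info_proportion(composite, original: np.ndarray, face_bounds,
                    weights=(0.5, 0.5), tau: float = REVEALED_TAU,
                    trial_id: str = "") -> InfoProportion:
    """Weighted mean of the SSIM and pixel-test terms (weights must sum to 1)."""
    if not np.isclose(sum(weights), 1.0):
        raise ValueError("weights must sum to 1")
    s = structural_similarity_term(composite, original, face_bounds, tau)
    p = pixel_test_term(composite, face_bounds, tau)
    return InfoProportion(value=float(weights[0] * s + weights[1] * p),
                          ssim_term=s, pixel_term=p, trial_id=trial_id)
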