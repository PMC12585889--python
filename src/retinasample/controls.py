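"""Face-region masks and the yoked random-fixation control condition.

The null condition for human gaze sampling is a set of random fixations yoked
to each human trial: the same number of fixations, with per-region counts
(eyes, nose, mouth, chin, cheeks, brow, forehead) matched exactly, and
locations drawn uniformly within each region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import Fixation

FACE_REGIONS = ("eyes", "nose", "mouth", "chin", "cheeks", "brow", "forehead")
BACKGROUND = "background"


@dataclass(frozen=True)
class RegionMask:
    """Label image partitioning the stimulus into face regions plus background.

    ``labels`` holds integer codes; ``legend`` maps region name -> code.
    Every one of the seven face regions must be non-empty.
    """

    labels: np.ndarray
    legend: dict[str, int]

    def __post_init__(self) -> None:
        codes = set(self.legend.values())
        if len(codes) != len(self.legend):
            raise ValueError("legend codes must be unique")
        missing = [r for r in FACE_REGIONS if r not in self.legend]
        if missing:
            raise ValueError(f"legend missing regions: {missing}")
        for region in FACE_REGIONS:
            if not (self.labels == self.legend[region]).any():
                raise ValueError(f"region {region!r} has no pixels")

    def label_at(self, x: float, y: float) -> str:
        """Region name at pixel (x, y); outside the image counts as background."""
        h, w = self.labels.shape
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            return BACKGROUND
        code = self.labels[yi, xi]
        for name, c in self.legend.items():
            if c == code:
                return name
        return BACKGROUND

    def pixels_of(self, region: str) -> np.ndarray:
        """(N, 2) array of (y, x) pixel coordinates carrying ``region``."""
        if region == "face":
            mask = np.isin(self.labels, [self.legend[r] for r in FACE_REGIONS])
        else:
            mask = self.labels == self.legend[region]
        return np.argwhere(mask)


def region_counts(fixations: list[Fixation], mask: RegionMask) -> dict[str, int]:
    """Number of fixations whose centroid falls in each region.

    Counts (including background) always sum to ``len(fixations)``.
    """
    counts = {r: 0 for r in (*FACE_REGIONS, BACKGROUND)}
    for f in fixations:
        counts[mask.label_at(f.x, f.y)] += 1
    return counts


def yoked_random_fixations(human: list[Fixation], mask: RegionMask,
                           seed: int) -> list[Fixation]:
    """Random fixations yoked to a human trial.

    Returns exactly ``len(human)`` fixations with per-region counts equal to the
    human counts (stratified sampling, so the match is exact by construction).
    Locations are uniform over each region's pixels; onsets, offsets and hence
    durations are copied from the corresponding human fixation. Human fixations
    landing on background are yoked to uniform draws over the whole face (the
    union of the seven regions).
    """
    if not human:
        raise ValueError("need at least one human fixation to yoke")
    rng = np.random.default_rng(seed)
    out: list[Fixation] = []
    for f in human:
        region = mask.label_at(f.x, f.y)
        target = "face" if region == BACKGROUND else region
        pix = mask.pixels_of(target)
        if len(pix) == 0:
            raise ValueError(f"mask has no pixels for region {target!r}")
        yy, xx = pix[rng.integers(len(pix))]
        out.append(replace(f, x=float(xx), y=float(yy)))
    return out
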