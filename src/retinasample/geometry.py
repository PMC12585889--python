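"""Viewing geometry: conversions between screen pixels and degrees of visual angle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ViewingGeometry:
    """Physical viewing setup linking screen pixels to visual angle.

    Parameters
    ----------
    eye_to_screen_mm : viewing distance from the eye to the screen plane.
    pixel_pitch_mm : physical size of one screen pixel (mm per px).
    screen_resolution : (width_px, height_px) of the display.
    """

    eye_to_screen_mm: float
    pixel_pitch_mm: float
    screen_resolution: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if self.eye_to_screen_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("eye_to_screen_mm and pixel_pitch_mm must be positive")
        if any(r <= 0 for r in self.screen_resolution):
            raise ValueError("screen_resolution must be positive")

    def px_to_deg(self, px):
        """Visual angle (deg) subtended by a distance of ``px`` pixels on screen.

        Uses the exact relation deg = 2*atan(px*pitch / (2*distance)).
        """
        px = np.asarray(px, dtype=float)
        return np.degrees(2.0 * np.arctan2(px * self.pixel_pitch_mm, 2.0 * self.eye_to_screen_mm))

    def deg_to_px(self, deg):
        """Inverse of :meth:`px_to_deg`."""
        deg = np.asarray(deg, dtype=float)
        return 2.0 * self.eye_to_screen_mm * np.tan(np.radians(deg) / 2.0) / self.pixel_pitch_mm


def default_geometry(image_size: int = 448, face_width_deg: float = 8.6,
                     face_width_frac: float = 0.64,
                     eye_to_screen_mm: float = 600.0) -> ViewingGeometry:
    """Geometry whose pixel pitch makes the face span ``face_width_deg``.

    Scaling the pitch with ``image_size`` keeps the angular size of the face
    constant across stimulus resolutions, so fixation-detection thresholds and
    foveation behave identically at 224 and 448 px.
    """
    face_px = face_width_frac * image_size
    face_mm = 2.0 * eye_to_screen_mm * np.tan(np.radians(face_width_deg) / 2.0)
    pitch = face_mm / face_px
    return ViewingGeometry(eye_to_screen_mm=eye_to_screen_mm, pixel_pitch_mm=float(pitch),
                           screen_resolution=(image_size, image_size))
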