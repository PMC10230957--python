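"""Photogrammetric scale model for nadir UAV imagery.

The ground sampling distance (GSD) of a nadir image taken at flight height
``H`` with a camera of focal length ``f`` and sensor pixel pitch ``a`` is

    GSD = H * a / f        [length on the ground per pixel]

All public functions work in meters internally; constructors accept the
mixed field units (m for flight height, micrometers for pixel pitch,
millimeters for focal length) and convert once on entry, which avoids
silent factor-of-1000 mistakes when the three constants are combined.

Physical extents derived from super-resolution-enhanced masks must divide
pixel counts by the upscale factor; :class:`GroundScale` carries that
factor alongside the native GSD so callers cannot forget it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "CameraModel",
    "GroundScale",
    "Footprint",
    "compute_gsd",
    "image_footprint",
    "px_to_length",
]


@dataclass(frozen=True)
class CameraModel:
    """Flight and optics constants of the imaging platform.

    Defaults describe a lightweight multispectral quadcopter platform:
    10 m flight height, 3 um pixel pitch, 5.74 mm focal length and a
    1600 x 1300 px sensor.
    """

    flight_height_m: float = 10.0
    pixel_pitch_um: float = 3.0
    focal_length_mm: float = 5.74
    image_width_px: int = 1600
    image_height_px: int = 1300

    def __post_init__(self) -> None:
        for name in (
            "flight_height_m",
            "pixel_pitch_um",
            "focal_length_mm",
            "image_width_px",
            "image_height_px",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"CameraModel.{name} must be strictly positive, got {value!r}")

    @classmethod
    def from_config(cls, block: Mapping[str, float]) -> "CameraModel":
        """Build from a ``camera:`` config block (keys as in the dataclass)."""
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown camera config keys: {sorted(unknown)}")
        return cls(**dict(block))


@dataclass(frozen=True)
class GroundScale:
    """Native GSD plus the resolution-enhancement multiplier.

    ``sr_factor`` > 1 means pixel counts were measured on an image whose
    resolution was enhanced by that factor; the effective ground scale is
    ``gsd_m / sr_factor``.
    """

    gsd_m: float
    sr_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.gsd_m > 0:
            raise ValueError(f"GroundScale.gsd_m must be strictly positive, got {self.gsd_m!r}")
        if not self.sr_factor >= 1:
            raise ValueError(f"GroundScale.sr_factor must be >= 1, got {self.sr_factor!r}")


@dataclass(frozen=True)
class Footprint:
    """Physical ground extent of one full camera frame."""

    length_m: float
    width_m: float
    area_m2: float


def compute_gsd(camera: CameraModel) -> float:
    """Ground sampling distance in meters per pixel: H * a / f."""
    a_m = camera.pixel_pitch_um * 1e-6
    f_m = camera.focal_length_mm * 1e-3
    return camera.flight_height_m * a_m / f_m


def image_footprint(camera: CameraModel) -> Footprint:
    """Ground footprint of one frame.

    The longer (width_px) sensor dimension maps to the footprint *length*,
    the shorter one to its *width*, matching the aerial-survey convention
    for landscape-oriented frames.
    """
    gsd = compute_gsd(camera)
    length = camera.image_width_px * gsd
    width = camera.image_height_px * gsd
    return Footprint(length_m=length, width_m=width, area_m2=length * width)


def px_to_length(n_px: float, scale: GroundScale) -> float:
    """Convert a pixel count to ground meters: n_px * gsd / sr_factor."""
    if n_px < 0:
        raise ValueError(f"pixel count must be non-negative, got {n_px!r}")
    return n_px * scale.gsd_m / scale.sr_factor
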