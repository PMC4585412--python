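"""Optical and feeding geometry of the line-scan inspection unit.

A tri-linear line-scan camera images leaves carried past it on a conveyor.
The optics map a square sensor pixel of pitch ``p`` (µm) onto the object
plane with a magnification ``M`` (object extent / sensor extent), giving a
linear resolution of ``p/1000 × M`` mm per pixel and an areal resolution of
its square.  The transverse field of view is the sensor line length times
``M``; the scan-direction field of view is the (three-line) sensor height
times ``M``.  The feeding cylinders that flatten the leaves must be spaced
at least one cylinder diameter plus the scan-direction field of view apart
so that the gap between the second and third cylinder leaves the imaging
line unobstructed.

Values are stored unrounded; reported values are rounded to a configurable
number of decimals (2 for lengths in mm, 3 for areas in mm²) so that the
default profile reproduces the conventional printed figures (0.22 mm,
0.048 mm²/pixel, 281.84 mm × 3.77 mm) without cascading rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CalibrationProfile",
    "DEFAULT_PROFILE",
    "linear_resolution",
    "area_per_pixel",
    "field_of_view",
    "min_cylinder_spacing",
    "pixels_to_area",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def linear_resolution(
    pixel_pitch_um: float, magnification: float, ndigits: int | None = 2
) -> float:
    """Object-plane size of one pixel in mm.

    Parameters
    ----------
    pixel_pitch_um:
        Sensor pixel pitch in micrometres (square pixels).
    magnification:
        Object-to-sensor scale factor (dimensionless, > 1 means the object
        plane is larger than the sensor).
    ndigits:
        Decimals for the reported value; ``None`` returns the raw product.
    """
    _require_positive(pixel_pitch_um=pixel_pitch_um, magnification=magnification)
    value = pixel_pitch_um / 1000.0 * magnification
    return value if ndigits is None else round(value, ndigits)


def area_per_pixel(mm_per_pixel: float, ndigits: int | None = 3) -> float:
    """Object-plane area of one pixel in mm² (the square of the resolution)."""
    _require_positive(mm_per_pixel=mm_per_pixel)
    value = mm_per_pixel**2
    return value if ndigits is None else round(value, ndigits)


def field_of_view(
    sensor_extent_mm: float, magnification: float, ndigits: int | None = 2
) -> float:
    """Field of view in mm for a sensor extent imaged at ``magnification``."""
    _require_positive(sensor_extent_mm=sensor_extent_mm, magnification=magnification)
    value = sensor_extent_mm * magnification
    return value if ndigits is None else round(value, ndigits)


def min_cylinder_spacing(cylinder_diameter_mm: float, scan_fov_mm: float) -> float:
    """Lower bound on the centre-line spacing of the feeding cylinders (mm).

    The spacing must exceed one cylinder diameter plus the scan-direction
    field of view so the imaging line falls in the gap between cylinders.
    """
    _require_positive(
        cylinder_diameter_mm=cylinder_diameter_mm, scan_fov_mm=scan_fov_mm
    )
    return cylinder_diameter_mm + scan_fov_mm


@dataclass(frozen=True)
class CalibrationProfile:
    """Geometric calibration of the scanner.

    Attributes
    ----------
    pixel_pitch_um:
        Sensor pixel pitch (µm, square pixels).
    magnification:
        Object-to-sensor scale factor.
    channel_offset_green, channel_offset_blue:
        Row shifts (pixels, along the scan direction) of the green and blue
        sensor lines relative to the red line.  Whole lines only.
    frame_height_px, frame_width_px:
        Rows and columns of one acquired frame.
    """

    pixel_pitch_um: float = 14.0
    magnification: float = 15.71
    channel_offset_green: int = 2
    channel_offset_blue: int = 4
    frame_height_px: int = 3000
    frame_width_px: int = 1280

    def __post_init__(self) -> None:
        _require_positive(
            pixel_pitch_um=self.pixel_pitch_um,
            magnification=self.magnification,
            frame_height_px=self.frame_height_px,
            frame_width_px=self.frame_width_px,
        )
        for name in ("channel_offset_green", "channel_offset_blue"):
            off = getattr(self, name)
            if int(off) != off or off < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {off!r}")
        if self.frame_height_px <= max(self.channel_offset_green, self.channel_offset_blue):
            raise ValueError("frame_height_px must exceed the largest channel offset")

    @property
    def mm_per_pixel(self) -> float:
        """Unrounded linear resolution (mm/pixel)."""
        return linear_resolution(self.pixel_pitch_um, self.magnification, ndigits=None)

    @property
    def area_per_pixel_mm2(self) -> float:
        """Unrounded areal resolution (mm²/pixel)."""
        return self.mm_per_pixel**2

    @property
    def channel_offsets(self) -> tuple[int, int]:
        """(green, blue) row offsets relative to the red line."""
        return (int(self.channel_offset_green), int(self.channel_offset_blue))

    def rounded_resolution(self) -> float:
        return linear_resolution(self.pixel_pitch_um, self.magnification)

    def rounded_area_per_pixel(self) -> float:
        return area_per_pixel(self.rounded_resolution())


def pixels_to_area(pixel_count: float, profile: CalibrationProfile) -> float:
    """Convert a foreground pixel count to an object-plane area in mm²."""
    if pixel_count < 0:
        raise ValueError(f"pixel_count must be non-negative, got {pixel_count!r}")
    return pixel_count * profile.area_per_pixel_mm2


#: Profile of the reference instrument: 14 µm pitch at ×15.71 → 0.22 mm/pixel.
DEFAULT_PROFILE = CalibrationProfile()
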