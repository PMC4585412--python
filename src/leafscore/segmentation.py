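"""HSL colour-space thresholding of leaf imagery.

Leaves are separated from the conveyor background by fixed, inclusive
threshold bands in hue–saturation–lightness space, with every channel
quantised to 8 bits (hue 0–360° mapped onto 0–255).  The default bands are
the desktop-scanner reference values for green (H 39–131, S 34–255,
L 30–233) and yellow (H 0–38, S 34–255, L 30–233) rice leaves; three
sub-bands of the green band split its lightness range to grade leaf
greenness into the light/moderate/dark classes of the IRRI leaf colour
chart (green-2/3/4).  Because the sub-bands partition the green band's
lightness range exactly, every green pixel belongs to exactly one class.

Small connected components ("impurities": dust, lint, edge artefacts) are
removed from binary masks by size; class masks are then obtained by
intersecting the raw class band masks with the cleaned total-leaf mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

__all__ = [
    "Band",
    "BandSet",
    "DEFAULT_BANDS",
    "rgb_to_hsl8",
    "hsl8_to_rgb",
    "band_mask",
    "remove_impurities",
    "class_areas",
    "GREEN_CLASSES",
    "LEAF_CLASSES",
]

#: Green colour classes, light to dark (IRRI leaf colour chart levels).
GREEN_CLASSES = ("green-2", "green-3", "green-4")
#: All leaf colour classes handled by the pipeline.
LEAF_CLASSES = GREEN_CLASSES + ("yellow",)


@dataclass(frozen=True)
class Band:
    """One inclusive HSL threshold box with 8-bit bounds per channel."""

    name: str
    h_min: int
    h_max: int
    s_min: int
    s_max: int
    l_min: int
    l_max: int

    def __post_init__(self) -> None:
        for channel in "hsl":
            lo = getattr(self, f"{channel}_min")
            hi = getattr(self, f"{channel}_max")
            if not (0 <= lo <= hi <= 255):
                raise ValueError(
                    f"band {self.name!r}: need 0 <= {channel}_min <= {channel}_max <= 255"
                )

    def contains(self, h: int, s: int, l: int) -> bool:
        return (
            self.h_min <= h <= self.h_max
            and self.s_min <= s <= self.s_max
            and self.l_min <= l <= self.l_max
        )


def _default_green() -> Band:
    return Band("green", 39, 131, 34, 255, 30, 233)


def _default_yellow() -> Band:
    return Band("yellow", 0, 38, 34, 255, 30, 233)


def _default_green2() -> Band:
    return Band("green-2", 39, 131, 34, 255, 156, 233)


def _default_green3() -> Band:
    return Band("green-3", 39, 131, 34, 255, 106, 155)


def _default_green4() -> Band:
    return Band("green-4", 39, 131, 34, 255, 30, 105)


@dataclass(frozen=True)
class BandSet:
    """Named bands used by the pipeline.

    ``green`` and ``yellow`` define the total-leaf foreground;
    ``green2/3/4`` grade greenness.  The class sub-bands must be pairwise
    disjoint and contained in ``green``; the defaults partition the green
    band's lightness range (156–233 / 106–155 / 30–105).
    """

    green: Band = field(default_factory=_default_green)
    yellow: Band = field(default_factory=_default_yellow)
    green2: Band = field(default_factory=_default_green2)
    green3: Band = field(default_factory=_default_green3)
    green4: Band = field(default_factory=_default_green4)

    def __post_init__(self) -> None:
        subs = [self.green2, self.green3, self.green4]
        for sub in subs:
            for channel in "hsl":
                if getattr(sub, f"{channel}_min") < getattr(self.green, f"{channel}_min") or getattr(
                    sub, f"{channel}_max"
                ) > getattr(self.green, f"{channel}_max"):
                    raise ValueError(f"class band {sub.name!r} not contained in green band")
        for i, a in enumerate(subs):
            for b in subs[i + 1 :]:
                if not (
                    a.h_max < b.h_min or b.h_max < a.h_min
                    or a.s_max < b.s_min or b.s_max < a.s_min
                    or a.l_max < b.l_min or b.l_max < a.l_min
                ):
                    raise ValueError(f"class bands {a.name!r} and {b.name!r} overlap")

    @property
    def class_bands(self) -> dict[str, Band]:
        """Colour-class bands keyed by class label (greens + yellow)."""
        return {
            "green-2": self.green2,
            "green-3": self.green3,
            "green-4": self.green4,
            "yellow": self.yellow,
        }

    def band_for(self, name: str) -> Band:
        mapping = {
            "green": self.green,
            "yellow": self.yellow,
            "green-2": self.green2,
            "green-3": self.green3,
            "green-4": self.green4,
        }
        try:
            return mapping[name]
        except KeyError:
            raise KeyError(f"unknown band {name!r}") from None


DEFAULT_BANDS = BandSet()


def rgb_to_hsl8(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to 8-bit HSL.

    Hue (0–360°), saturation and lightness are each scaled to 0–255 and
    rounded.  The hue of achromatic pixels (max = min) is defined as 0.
    Accepts any array whose last axis has length 3.
    """
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError("expected an array with a trailing axis of length 3 (RGB)")
    rgbf = rgb.astype(np.float64) / 255.0
    r, g, b = rgbf[..., 0], rgbf[..., 1], rgbf[..., 2]
    maxc = np.max(rgbf, axis=-1)
    minc = np.min(rgbf, axis=-1)
    l = (maxc + minc) / 2.0
    d = maxc - minc
    chromatic = d > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - np.abs(2.0 * l - 1.0)
        s = np.where(chromatic & (denom > 0), d / np.where(denom > 0, denom, 1.0), 0.0)

        h = np.zeros_like(l)
        dd = np.where(chromatic, d, 1.0)
        h_r = np.mod((g - b) / dd, 6.0)
        h_g = (b - r) / dd + 2.0
        h_b = (r - g) / dd + 4.0
        h = np.where(maxc == r, h_r, h)
        h = np.where((maxc == g) & (maxc != r), h_g, h)
        h = np.where((maxc == b) & (maxc != r) & (maxc != g), h_b, h)
        h = np.where(chromatic, h / 6.0, 0.0)  # fraction of a turn

    out = np.stack(
        [np.round(h * 255.0), np.round(s * 255.0), np.round(l * 255.0)], axis=-1
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def hsl8_to_rgb(hsl: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsl8` (up to 8-bit rounding)."""
    hsl = np.asarray(hsl)
    if hsl.shape[-1] != 3:
        raise ValueError("expected an array with a trailing axis of length 3 (HSL)")
    h = hsl[..., 0].astype(np.float64) / 255.0 * 6.0  # sextants
    s = hsl[..., 1].astype(np.float64) / 255.0
    l = hsl[..., 2].astype(np.float64) / 255.0

    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    x = c * (1.0 - np.abs(np.mod(h, 2.0) - 1.0))
    m = l - c / 2.0

    sext = np.floor(h).astype(int) % 6
    r = np.choose(sext, [c, x, np.zeros_like(c), np.zeros_like(c), x, c])
    g = np.choose(sext, [x, c, c, x, np.zeros_like(c), np.zeros_like(c)])
    b = np.choose(sext, [np.zeros_like(c), np.zeros_like(c), x, c, c, x])

    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def band_mask(hsl: np.ndarray, band: Band) -> np.ndarray:
    """Boolean mask of pixels whose H, S and L all lie inside ``band``."""
    hsl = np.asarray(hsl)
    h, s, l = hsl[..., 0], hsl[..., 1], hsl[..., 2]
    return (
        (h >= band.h_min) & (h <= band.h_max)
        & (s >= band.s_min) & (s <= band.s_max)
        & (l >= band.l_min) & (l <= band.l_max)
    )


def remove_impurities(
    mask: np.ndarray, min_area_px: int = 50, connectivity: int = 2
) -> np.ndarray:
    """Drop connected components smaller than ``min_area_px`` pixels.

    ``connectivity`` follows scikit-image convention (2 = 8-connectivity,
    the default so thin diagonal leaf tips do not fragment).  Components
    with exactly ``min_area_px`` pixels are kept.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_area_px == 1:
        return mask.copy()
    labels = skmeasure.label(mask, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area_px
    keep[0] = False  # background
    return keep[labels]


def class_areas(
    total_mask: np.ndarray, hsl: np.ndarray, bands: BandSet
) -> dict[str, np.ndarray]:
    """Class masks: each colour-class band mask intersected with ``total_mask``.

    ``total_mask`` is expected to be impurity-cleaned; off-leaf specks that
    happen to fall inside a class band are thereby excluded.
    """
    total_mask = np.asarray(total_mask, dtype=bool)
    return {
        name: band_mask(hsl, band) & total_mask
        for name, band in bands.class_bands.items()
    }
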