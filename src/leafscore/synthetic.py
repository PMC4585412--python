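"""Synthetic line-scan generator with analytic ground truth.

Renders plants of parameterised leaves (rectangles, tapered ellipses and
curved blades in three green classes plus yellow) onto a long scan canvas,
then emulates the instrument's acquisition artefacts: the tri-linear
sensor's green/blue row misalignment (:func:`distort_channels`),
fixed-height frame splitting with leaves crossing frame boundaries
(:func:`split_frames`), and dust/impurity speckle.

Each leaf is drawn in a single HSL colour sampled strictly inside its
class band, so the band masks of a clean render equal the label raster
exactly and every measured quantity can be compared against an analytic
truth computed from the leaf specifications:

=================  ==============  ===============  =====================
shape              area            perimeter        length definition
=================  ==============  ===============  =====================
rectangle          L·W             2(L+W)           long side L
tapered-ellipse    πLW/4           Ramanujan        major axis L
curved-blade       L·W             2(L+W)           centre-line arc L
=================  ==============  ===============  =====================

(The curved blade is an annulus sector of centre-line radius L/θ and
width W, whose area and perimeter coincide with the rectangle it would
unroll into.)  Canvas axes: rows = scan direction (time), columns =
transverse; frames follow each other down the rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import DEFAULT_PROFILE, CalibrationProfile
from .channels import ScanFrame
from .errors import CapacityError
from .morphometrics import LeafRecord, classify_leaf, compactness
from .segmentation import (
    DEFAULT_BANDS,
    Band,
    BandSet,
    LEAF_CLASSES,
    hsl8_to_rgb,
    rgb_to_hsl8,
)
from .traits import PlantTraits, aggregate

__all__ = [
    "LeafSpec",
    "SyntheticTask",
    "RenderedScan",
    "CLASS_CODES",
    "DEFAULT_CLASS_MIX",
    "sample_plant",
    "render_scan",
    "distort_channels",
    "split_frames",
    "match_leaves_to_truth",
]

#: Integer codes used in the class label raster (0 = background).
CLASS_CODES = {"green-2": 2, "green-3": 3, "green-4": 4, "yellow": 5}

#: Default colour-class mixture of a plant: mostly moderate green with
#: lighter/darker leaves and a small senescent (yellow) fraction.
DEFAULT_CLASS_MIX = {
    "green-2": 0.25,
    "green-3": 0.40,
    "green-4": 0.25,
    "yellow": 0.10,
}

_SHAPES = ("rectangle", "tapered-ellipse", "curved-blade")


@dataclass(frozen=True)
class LeafSpec:
    """One leaf: geometry (mm), colour class and canvas placement."""

    length_mm: float
    max_width_mm: float
    shape: str
    curvature: float  # arc angle in radians for curved blades, else 0
    colour_class: str
    hsl_centre: tuple[int, int, int]
    anchor: tuple[int, int]  # (row, col) of the local bounding box origin

    def __post_init__(self) -> None:
        if not self.length_mm > self.max_width_mm > 0:
            raise ValueError("need length > max_width > 0")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.colour_class not in LEAF_CLASSES:
            raise ValueError(f"unknown colour class {self.colour_class!r}")

    # ---- analytic truth -------------------------------------------------
    @property
    def area_mm2(self) -> float:
        if self.shape == "tapered-ellipse":
            return math.pi * self.length_mm * self.max_width_mm / 4.0
        return self.length_mm * self.max_width_mm

    @property
    def perimeter_mm(self) -> float:
        if self.shape == "tapered-ellipse":
            a, b = self.length_mm / 2.0, self.max_width_mm / 2.0
            h = (a - b) ** 2 / (a + b) ** 2
            return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))
        return 2.0 * (self.length_mm + self.max_width_mm)

    def truth_record(self, leaf_id: int = 0) -> LeafRecord:
        areas = {c: 0.0 for c in LEAF_CLASSES}
        areas[self.colour_class] = self.area_mm2
        return LeafRecord(
            leaf_id=leaf_id,
            length_mm=self.length_mm,
            width_mm=self.max_width_mm,
            perimeter_mm=self.perimeter_mm,
            area_mm2=self.area_mm2,
            compactness=compactness(self.area_mm2, self.perimeter_mm),
            class_areas_mm2=areas,
            dominant_class=classify_leaf(areas),
        )


@dataclass
class SyntheticTask:
    """A plant rendered as one scan task, with its analytic ground truth."""

    plant_id: str
    leaves: list[LeafSpec]
    seed: int
    dust_density: float  # specks per megapixel
    canvas_shape: tuple[int, int]  # (rows, cols)
    frame_height_px: int

    @property
    def truth(self) -> PlantTraits:
        return aggregate(self.truth_records())

    def truth_records(self) -> list[LeafRecord]:
        return [leaf.truth_record(i + 1) for i, leaf in enumerate(self.leaves)]


@dataclass
class RenderedScan:
    """Clean render of a task: RGB raster plus truth label rasters."""

    rgb: np.ndarray  # (rows, cols, 3) uint8
    leaf_labels: np.ndarray  # (rows, cols) int32, 0 = background/dust
    class_labels: np.ndarray  # (rows, cols) uint8, CLASS_CODES


# ---------------------------------------------------------------------------
# leaf rasterisation


def leaf_local_mask(spec: LeafSpec, mm_per_pixel: float) -> np.ndarray:
    """Deterministic boolean raster of one leaf in its local bounding box.

    The blade's long axis runs along rows (the scan direction).
    """
    lpx = spec.length_mm / mm_per_pixel
    wpx = spec.max_width_mm / mm_per_pixel
    if spec.shape == "rectangle":
        return np.ones((max(round(lpx), 1), max(round(wpx), 1)), dtype=bool)
    if spec.shape == "tapered-ellipse":
        h, w = max(round(lpx), 1), max(round(wpx), 1)
        r = (np.arange(h) + 0.5 - h / 2.0) / (lpx / 2.0)
        c = (np.arange(w) + 0.5 - w / 2.0) / (wpx / 2.0)
        return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0
    # curved blade: annulus sector, centre-line radius r_c = L/θ
    theta = spec.curvature
    if not 0 < theta < math.pi:
        raise ValueError("curved-blade curvature must be an arc angle in (0, π)")
    r_c = lpx / theta
    half = theta / 2.0
    rows_ext = 2.0 * (r_c + wpx / 2.0) * math.sin(half) + wpx
    cols_ext = r_c * (1.0 - math.cos(half)) + wpx
    h = int(math.ceil(rows_ext)) + 2
    w = int(math.ceil(cols_ext)) + 2
    cr = h / 2.0
    cc = r_c + wpx / 2.0 + 1.0  # centre of curvature, right of the blade
    rr = np.arange(h) + 0.5
    cols = np.arange(w) + 0.5
    dr = rr[:, None] - cr
    dc = cols[None, :] - cc
    rho = np.hypot(dr, dc)
    ang = np.arctan2(dr, -dc)  # 0 at the apex, ± along the blade
    mask = (np.abs(rho - r_c) <= wpx / 2.0) & (np.abs(ang) <= half)
    rows_any = mask.any(axis=1)
    cols_any = mask.any(axis=0)
    return mask[rows_any][:, cols_any]


def _sample_in_band(rng: np.random.Generator, band: Band, margin: int = 4) -> tuple[int, int, int]:
    """Sample an HSL triple strictly inside ``band`` that survives the
    HSL→RGB→HSL 8-bit round trip still inside the band."""
    for _ in range(200):
        h = int(rng.integers(band.h_min + margin, band.h_max - margin + 1))
        s = int(rng.integers(max(band.s_min + margin, 60), min(band.s_max - margin, 245) + 1))
        l = int(rng.integers(max(band.l_min + margin, 50), min(band.l_max - margin, 220) + 1))
        rgb = hsl8_to_rgb(np.array([[h, s, l]], dtype=np.uint8))
        h2, s2, l2 = (int(v) for v in rgb_to_hsl8(rgb)[0])
        if band.contains(h2, s2, l2):
            return h, s, l
    raise RuntimeError(f"could not sample a stable colour inside band {band.name!r}")


# ---------------------------------------------------------------------------
# plant sampling


def sample_plant(
    n_leaves: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    *,
    profile: CalibrationProfile = DEFAULT_PROFILE,
    bands: BandSet = DEFAULT_BANDS,
    length_range_mm: tuple[float, float] = (150.0, 350.0),
    width_range_mm: tuple[float, float] = (8.0, 18.0),
    shapes: tuple[str, ...] = _SHAPES,
    dust_density: float = 5.0,
    canvas_cols: int | None = None,
    frame_height_px: int | None = None,
    col_margin_px: int = 20,
    row_margin_px: int = 30,
    plant_id: str | None = None,
) -> SyntheticTask:
    """Sample a plant of non-overlapping leaves packed onto the scan canvas.

    Deterministic given ``seed``.  Leaves are shelf-packed with their long
    axis along the scan direction; when the canvas spans more than one
    frame, the packing is shifted so that at least one leaf straddles a
    frame boundary (boundary crossing is the condition the mosaic stage
    must handle).  Raises :class:`CapacityError` if a leaf cannot fit the
    canvas width.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class mix proportions must sum to 1")
    unknown = set(mix) - set(LEAF_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    mpp = profile.mm_per_pixel
    cols = canvas_cols or profile.frame_width_px
    fh = frame_height_px or profile.frame_height_px
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])

    specs: list[dict] = []
    for _ in range(n_leaves):
        length = float(rng.uniform(*length_range_mm))
        width = float(rng.uniform(*width_range_mm))
        width = min(width, 0.8 * length)  # keep the blade elongated
        shape = shapes[int(rng.integers(len(shapes)))]
        curvature = float(rng.uniform(0.3, 0.9)) if shape == "curved-blade" else 0.0
        cls = classes[int(rng.choice(len(classes), p=probs))]
        colour = _sample_in_band(rng, bands.band_for(cls))
        probe = LeafSpec(length, width, shape, curvature, cls, colour, (0, 0))
        box = leaf_local_mask(probe, mpp).shape
        specs.append(
            dict(length=length, width=width, shape=shape, curvature=curvature,
                 cls=cls, colour=colour, box=box)
        )

    # shelf packing: rows grow downward, one shelf at a time
    top = row_margin_px + max(profile.channel_offsets) + 1
    shelf_row, cur_col, shelf_h = top, col_margin_px, 0
    anchors: list[tuple[int, int]] = []
    for s in specs:
        h, w = s["box"]
        if w + 2 * col_margin_px > cols:
            raise CapacityError(
                f"leaf of {w} px width cannot fit a {cols} px canvas"
            )
        if cur_col + w + col_margin_px > cols:
            shelf_row += shelf_h + row_margin_px
            cur_col, shelf_h = col_margin_px, 0
        jr = int(rng.integers(0, row_margin_px // 2 + 1))
        anchors.append((shelf_row + jr, cur_col))
        cur_col += w + col_margin_px
        shelf_h = max(shelf_h, h + row_margin_px // 2)
    canvas_rows = shelf_row + shelf_h + row_margin_px

    # guarantee at least one frame-boundary crossing when frames split
    if canvas_rows > fh:
        crossing = any(
            (a[0] // fh) != ((a[0] + s["box"][0] - 1) // fh)
            for a, s in zip(anchors, specs)
        )
        if not crossing:
            i = int(np.argmax([s["box"][0] for s in specs]))
            centre = anchors[i][0] + specs[i]["box"][0] // 2
            delta = int(math.ceil(centre / fh)) * fh - centre
            anchors = [(r + delta, c) for r, c in anchors]
            canvas_rows += delta

    leaves = [
        LeafSpec(
            s["length"], s["width"], s["shape"], s["curvature"], s["cls"],
            s["colour"], anchor,
        )
        for s, anchor in zip(specs, anchors)
    ]
    return SyntheticTask(
        plant_id=plant_id or f"plant-{seed}",
        leaves=leaves,
        seed=seed,
        dust_density=dust_density,
        canvas_shape=(int(canvas_rows), int(cols)),
        frame_height_px=fh,
    )


# ---------------------------------------------------------------------------
# rendering


def render_scan(
    task: SyntheticTask, profile: CalibrationProfile = DEFAULT_PROFILE
) -> RenderedScan:
    """Render the clean (undistorted) scan raster and its truth labels.

    Background is black (outside every threshold band).  Dust specks of
    1–20 pixels are strewn over the background — never touching a leaf,
    so the analytic truth stays exact — in colours half of which lie
    inside a leaf band to exercise impurity removal.
    """
    rows, cols = task.canvas_shape
    rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
    leaf_labels = np.zeros((rows, cols), dtype=np.int32)
    class_labels = np.zeros((rows, cols), dtype=np.uint8)
    mpp = profile.mm_per_pixel

    for i, leaf in enumerate(task.leaves, start=1):
        mask = leaf_local_mask(leaf, mpp)
        r0, c0 = leaf.anchor
        r1, c1 = r0 + mask.shape[0], c0 + mask.shape[1]
        if r1 > rows or c1 > cols or r0 < 0 or c0 < 0:
            raise CapacityError(f"leaf {i} exceeds the canvas")
        region = leaf_labels[r0:r1, c0:c1]
        if (region[mask] != 0).any():
            raise CapacityError(f"leaf {i} overlaps a previously placed leaf")
        colour = hsl8_to_rgb(np.array([leaf.hsl_centre], dtype=np.uint8))[0]
        rgb[r0:r1, c0:c1][mask] = colour
        region[mask] = i
        class_labels[r0:r1, c0:c1][mask] = CLASS_CODES[leaf.colour_class]

    _strew_dust(task, rgb, leaf_labels)
    return RenderedScan(rgb=rgb, leaf_labels=leaf_labels, class_labels=class_labels)


def _strew_dust(task: SyntheticTask, rgb: np.ndarray, leaf_labels: np.ndarray) -> None:
    """Draw random specks in place on background pixels only."""
    if task.dust_density <= 0:
        return
    from scipy import ndimage

    rng = np.random.default_rng([task.seed, 0xD05])
    rows, cols = leaf_labels.shape
    n = int(rng.poisson(task.dust_density * rows * cols / 1e6))
    if n == 0:
        return
    # keep specks off the leaves (and not 8-adjacent to them)
    forbidden = ndimage.binary_dilation(leaf_labels > 0, np.ones((5, 5), dtype=bool))
    bands = DEFAULT_BANDS
    band_list = list(bands.class_bands.values())
    for _ in range(n):
        size = int(rng.integers(1, 21))
        r = int(rng.integers(0, rows))
        c = int(rng.integers(0, cols))
        if rng.random() < 0.5:
            colour = rng.integers(0, 256, size=3).astype(np.uint8)
        else:
            band = band_list[int(rng.integers(len(band_list)))]
            colour = hsl8_to_rgb(
                np.array([_sample_in_band(rng, band)], dtype=np.uint8)
            )[0]
        # random-walk blob of `size` pixels
        pts = [(r, c)]
        for _ in range(size - 1):
            dr, dc = (int(rng.integers(-1, 2)), int(rng.integers(-1, 2)))
            nr = min(max(pts[-1][0] + dr, 0), rows - 1)
            nc = min(max(pts[-1][1] + dc, 0), cols - 1)
            pts.append((nr, nc))
        if any(forbidden[p] for p in pts):
            continue
        for p in pts:
            rgb[p] = colour
            forbidden[p] = True  # keep specks from piling into big blobs


# ---------------------------------------------------------------------------
# acquisition artefacts


def distort_channels(
    rgb: np.ndarray, offsets: tuple[int, int], fill: tuple[int, int, int] = (0, 0, 0)
) -> np.ndarray:
    """Displace the green and blue planes *down* the scan axis.

    This is the inverse of :func:`leafscore.channels.correct_channels`:
    ``correct(distort(x))`` equals ``x`` on all rows except the last
    ``max(offsets)`` rows of the raster (and of each frame, once split),
    where the round trip is lossy by construction.
    """
    rgb = np.asarray(rgb)
    g_off, b_off = (int(o) for o in offsets)
    rows = rgb.shape[0]
    for name, off in (("green", g_off), ("blue", b_off)):
        if not 0 <= off < rows:
            raise ValueError(f"{name} offset {off} out of range [0, {rows})")
    out = rgb.copy()
    for plane, off in ((1, g_off), (2, b_off)):
        if off:
            out[off:, :, plane] = rgb[:-off, :, plane]
            out[:off, :, plane] = fill[plane]
    return out


def split_frames(
    raster: np.ndarray, frame_height: int, task_id: str = ""
) -> list[ScanFrame]:
    """Cut a long raster into adjoining frames of ``frame_height`` rows.

    Concatenating the frames in order reproduces the raster exactly; the
    last frame may be shorter.
    """
    if frame_height < 1:
        raise ValueError("frame_height must be >= 1")
    raster = np.asarray(raster)
    return [
        ScanFrame(raster[start : start + frame_height].copy(), frame_index=i, task_id=task_id)
        for i, start in enumerate(range(0, raster.shape[0], frame_height))
    ]


def match_leaves_to_truth(
    leaf_masks: list[np.ndarray] | list, leaf_labels: np.ndarray
) -> list[int]:
    """Map extracted leaf objects to truth leaf ids by majority overlap.

    ``leaf_masks`` may be full-canvas boolean masks or objects with
    ``mask``/``bbox`` attributes (see :class:`leafscore.mosaic.LeafObject`).
    Returns the truth id (0 if the object overlaps no truth leaf).
    """
    out = []
    for obj in leaf_masks:
        if hasattr(obj, "bbox"):
            r0, c0, r1, c1 = obj.bbox
            labels = leaf_labels[r0:r1, c0:c1][obj.mask]
        else:
            labels = leaf_labels[np.asarray(obj, dtype=bool)]
        labels = labels[labels > 0]
        out.append(int(np.bincount(labels).argmax()) if labels.size else 0)
    return out
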