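"""Still-image quantification at the cell division site.

Implements the intensity measurements used to compare protein
localization at the cytokinesis site:

* ROI intensity with local cytoplasmic background subtraction — an
  inner ROI1 captures the division-site signal; a surrounding ROI2 of
  roughly twice the area estimates the per-pixel cytoplasmic background
  from the annulus ROI2 minus ROI1.
* 3-pixel-wide line scans across the division plane along the cell
  short axis (the width averages out single-plane signal variation).
* Alignment of line scans to a common center by one of four
  conventions: the peak of a reference channel (e.g. a contractile-ring
  marker), the brightest pixel of the scanned channel itself, the
  midpoint between the two rim peaks, or an externally supplied center
  (e.g. the septum middle from a DIC image).
* The long-axis colocalization profile: a 1.5 x 3.5 um ROI spanning the
  division plane, averaged over its short dimension to give one
  intensity-vs-long-axis curve per channel at the identical position.

Coordinates are 0-based (row, col) pixel indices internally; reported
positions are in um relative to the alignment center.  Perpendicular
line-scan sampling uses nearest-pixel lookup (1 sample per pixel along
the line); an interpolated mode is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "IntensityImage",
    "Roi",
    "RoiMeasurement",
    "LineProfile",
    "ProfileError",
    "AlignmentError",
    "sum_projection",
    "roi_corrected_intensity",
    "line_scan",
    "align_profiles",
    "long_axis_profile",
    "load_image",
]


class ProfileError(ValueError):
    pass


class AlignmentError(ProfileError):
    pass


@dataclass
class IntensityImage:
    """A 2-D intensity image (single plane or z-projection)."""

    pixels: np.ndarray
    pixel_size: float  # um / pixel
    projection: str = "single-plane"  # {sum, max, single-plane}

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ProfileError("image must be 2-D")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ProfileError("image must be finite and non-negative")
        if self.pixel_size <= 0:
            raise ProfileError("pixel_size must be > 0")


def sum_projection(stack: np.ndarray, pixel_size: float) -> IntensityImage:
    """Sum all z-sections into one plane (total fluorescence per pixel)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ProfileError("expected a z-stack with shape (z, rows, cols)")
    return IntensityImage(stack.sum(axis=0), pixel_size, projection="sum")


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle: rows [row, row+height), cols [col, col+width)."""

    row: int
    col: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width

    def contains(self, other: "Roi") -> bool:
        return (
            self.row <= other.row
            and self.col <= other.col
            and self.row + self.height >= other.row + other.height
            and self.col + self.width >= other.col + other.width
        )

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            0 <= self.row
            and 0 <= self.col
            and self.row + self.height <= shape[0]
            and self.col + self.width <= shape[1]
        )

    def pixel_sum(self, pixels: np.ndarray) -> float:
        return float(
            pixels[self.row : self.row + self.height, self.col : self.col + self.width].sum()
        )


@dataclass
class RoiMeasurement:
    roi1_sum: float
    roi1_area: int
    roi2_sum: float
    roi2_area: int
    corrected: float

    def to_dict(self) -> dict:
        return {
            "roi1_sum": self.roi1_sum,
            "roi1_area_px": self.roi1_area,
            "roi2_sum": self.roi2_sum,
            "roi2_area_px": self.roi2_area,
            "corrected_intensity": self.corrected,
        }


@dataclass
class LineProfile:
    positions: np.ndarray  # um (or px when pixel_size=1), monotone
    values: np.ndarray
    channel: str = ""
    width_px: int = 3
    alignment_offset: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ProfileError("positions and values differ in length")

    def shifted(self, offset: float) -> "LineProfile":
        return LineProfile(
            self.positions - offset,
            self.values.copy(),
            self.channel,
            self.width_px,
            self.alignment_offset + offset,
        )


# ---------------------------------------------------------------------------
# ROI intensity with cytoplasmic background subtraction
# ---------------------------------------------------------------------------


def roi_corrected_intensity(
    image: IntensityImage, roi1: Roi, roi2: Roi
) -> RoiMeasurement:
    """Division-site intensity corrected for cytoplasmic background.

    The per-pixel background b is estimated from the annulus between
    ROI2 (which must strictly contain ROI1, and should be roughly twice
    its area) and ROI1: b = (sum2 - sum1)/(area2 - area1); the
    corrected intensity is sum1 - b * area1.
    """
    if not roi2.within(image.pixels.shape) or not roi1.within(image.pixels.shape):
        raise ProfileError("ROI exceeds image bounds")
    if not (roi2.contains(roi1) and roi2.area > roi1.area):
        raise ProfileError("ROI2 must strictly contain ROI1")
    ratio = roi2.area / roi1.area
    if not (1.5 <= ratio <= 2.5):
        warnings.warn(
            f"ROI2/ROI1 area ratio {ratio:.2f} outside [1.5, 2.5]; the "
            "background estimate expects ROI2 ~ twice ROI1",
            stacklevel=2,
        )
    s1 = roi1.pixel_sum(image.pixels)
    s2 = roi2.pixel_sum(image.pixels)
    b = (s2 - s1) / (roi2.area - roi1.area)
    return RoiMeasurement(
        roi1_sum=s1,
        roi1_area=roi1.area,
        roi2_sum=s2,
        roi2_area=roi2.area,
        corrected=s1 - b * roi1.area,
    )


# ---------------------------------------------------------------------------
# Line scans
# ---------------------------------------------------------------------------


def line_scan(
    image: IntensityImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 3,
    channel: str = "",
    interpolate: bool = False,
) -> LineProfile:
    """Mean intensity along a line, averaged over ``width_px`` pixels
    perpendicular to it.

    ``start`` and ``end`` are (row, col) pixel coordinates.  Sampling is
    one sample per pixel of line length; each sample averages
    ``width_px`` points perpendicular to the line (nearest-pixel lookup
    by default, bilinear when ``interpolate``).  The width must be odd
    so a center pixel exists.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ProfileError("line width must be odd (a center pixel is needed)")
    r0, c0 = start
    r1, c1 = end
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ProfileError("zero-length scan line")
    n = int(round(length)) + 1
    ts = np.linspace(0.0, 1.0, n)
    rows = r0 + ts * (r1 - r0)
    cols = c0 + ts * (c1 - c0)
    # unit normal to the line
    nr, nc = -(c1 - c0) / length, (r1 - r0) / length
    offsets = np.arange(width_px) - (width_px - 1) / 2

    h, w = image.pixels.shape
    samples = np.empty((width_px, n))
    for k, off in enumerate(offsets):
        rr = rows + off * nr
        cc = cols + off * nc
        if np.any(rr < -0.5) or np.any(rr > h - 0.5) or np.any(cc < -0.5) or np.any(cc > w - 0.5):
            raise ProfileError("scan line (with width) exceeds image bounds")
        if interpolate:
            samples[k] = map_coordinates(image.pixels, [rr, cc], order=1, mode="nearest")
        else:
            ri = np.clip(np.rint(rr).astype(int), 0, h - 1)
            ci = np.clip(np.rint(cc).astype(int), 0, w - 1)
            samples[k] = image.pixels[ri, ci]
    values = samples.mean(axis=0)
    positions = ts * length * image.pixel_size
    return LineProfile(positions, values, channel=channel, width_px=width_px)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

ALIGN_MODES = ("reference_peak", "brightest_pixel", "two_peak_midpoint", "external_center")


def _global_peak(profile: LineProfile) -> float:
    """Position of the global maximum; ties go to the lowest index."""
    i = int(np.argmax(profile.values))
    return float(profile.positions[i])


def _two_peak_center(profile: LineProfile, min_separation: int = 3) -> float:
    """Midpoint of the two highest strict local maxima separated by at
    least ``min_separation`` samples."""
    v = profile.values
    maxima = [
        i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]
    ]
    maxima.sort(key=lambda i: (-v[i], i))
    for a in range(len(maxima)):
        for b in range(a + 1, len(maxima)):
            if abs(maxima[a] - maxima[b]) >= min_separation:
                pa, pb = profile.positions[maxima[a]], profile.positions[maxima[b]]
                return float((pa + pb) / 2)
    raise AlignmentError(
        "two_peak_midpoint needs two separated local maxima; profile "
        "appears unimodal"
    )


def align_profiles(
    profiles: Sequence[LineProfile],
    mode: str,
    reference: LineProfile | None = None,
    center: float | None = None,
) -> list[LineProfile]:
    """Shift profiles so the computed center sits at position 0.

    Modes: ``reference_peak`` centers every profile on the global peak
    of the reference channel; ``brightest_pixel`` centers each profile
    on its own global maximum; ``two_peak_midpoint`` on the midpoint of
    its two rim peaks; ``external_center`` on a supplied coordinate
    (same units as the positions).
    """
    if mode not in ALIGN_MODES:
        raise ProfileError(f"unknown alignment mode {mode!r}; choose from {ALIGN_MODES}")
    if mode == "reference_peak":
        if reference is None:
            raise ProfileError("reference_peak mode needs a reference profile")
        c = _global_peak(reference)
        return [p.shifted(c) for p in profiles]
    if mode == "external_center":
        if center is None:
            raise ProfileError("external_center mode needs a center coordinate")
        return [p.shifted(float(center)) for p in profiles]
    out = []
    for p in profiles:
        c = _global_peak(p) if mode == "brightest_pixel" else _two_peak_center(p)
        out.append(p.shifted(c))
    return out


# ---------------------------------------------------------------------------
# Long-axis colocalization profile
# ---------------------------------------------------------------------------


def long_axis_profile(
    image_a: IntensityImage,
    image_b: IntensityImage,
    center: tuple[float, float],
    roi_length_um: float = 3.5,
    roi_height_um: float = 1.5,
    channels: tuple[str, str] = ("A", "B"),
) -> tuple[LineProfile, LineProfile]:
    """Two-channel intensity along the cell long axis at the division
    plane.

    A single rectangular ROI of ``roi_height_um`` x ``roi_length_um``
    (short x long axis), centered at ``center`` (row, col), is applied
    at the identical position to both channels; at each long-axis pixel
    the value is the mean over the ROI's short-axis extent.  The long
    axis is the image column direction.
    """
    if image_a.pixels.shape != image_b.pixels.shape or image_a.pixel_size != image_b.pixel_size:
        raise ProfileError("the two channels must share geometry")
    px = image_a.pixel_size
    half_len = int(round(roi_length_um / px / 2))
    half_h = int(round(roi_height_um / px / 2))
    r, c = int(round(center[0])), int(round(center[1]))
    r0, r1 = r - half_h, r + half_h + 1
    c0, c1 = c - half_len, c + half_len + 1
    h, w = image_a.pixels.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ProfileError("long-axis ROI exceeds image bounds")
    positions = (np.arange(c0, c1) - c) * px
    out = []
    for img, ch in ((image_a, channels[0]), (image_b, channels[1])):
        values = img.pixels[r0:r1, c0:c1].mean(axis=0)
        out.append(LineProfile(positions, values, channel=ch, width_px=r1 - r0))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Image loading (TIFF or delimited numeric matrix)
# ---------------------------------------------------------------------------


def load_image(path, pixel_size: float, projection: str = "single-plane") -> IntensityImage:
    """Load a grayscale TIFF or a delimited numeric matrix as an image."""
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(str(path))
    else:
        data = np.loadtxt(str(path), delimiter="\t" if path.suffix == ".tsv" else None)
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        return sum_projection(data, pixel_size)
    return IntensityImage(data, pixel_size, projection=projection)
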