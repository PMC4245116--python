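"""Foreground segmentation of scanned leaves/sheaths and dpi calibration.

Scans are acquired on a flatbed scanner whose lid gives a near-white
background, so the default foreground test is simply ``min(R,G,B) < 235``
(plant tissue is never near-white except the N-stressed sheath base, which
sits inside the organ and survives hole filling).  Otsu thresholding on the
min-channel is available as a fallback for less controlled backgrounds.

All geometry is computed on the 0-based, row-major pixel grid at pixel
centers; physical quantities are obtained afterwards through the dpi
calibration (2.54 cm per inch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu


class SegmentationError(ValueError):
    """Base class for segmentation failures."""


class EmptyForeground(SegmentationError):
    """No foreground component of at least ``min_pixels`` pixels."""


#: minimum pixels for a valid object
MIN_FOREGROUND_PIXELS = 10

#: default near-white background threshold on the min channel
DEFAULT_THRESHOLD = 235


@dataclass
class LeafScan:
    """A single scanned organ: 8-bit RGB raster plus acquisition metadata."""

    pixels: np.ndarray  # H x W x 3 uint8
    dpi: int
    kind: str  # "leaf" | "sheath"
    position: int  # 1 (youngest) .. 3 (oldest fully expanded)
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.kind not in ("leaf", "sheath"):
            raise ValueError(f"kind must be 'leaf' or 'sheath', got {self.kind!r}")
        self.pixels = px.astype(np.uint8, copy=False)

    @classmethod
    def from_file(cls, path, dpi: int, kind: str, position: int, sample_id: str = ""):
        px = np.asarray(Image.open(path).convert("RGB"))
        return cls(px, dpi=dpi, kind=kind, position=position, sample_id=sample_id)

    def save(self, path) -> None:
        Image.fromarray(self.pixels).save(Path(path))


@dataclass
class SegmentedObject:
    """Foreground mask of one organ with its principal-axis frame.

    ``axis`` is the unit eigenvector of the largest second-moment
    eigenvalue; ``tip_end``/``base_end`` are foreground pixels at the
    extreme projections onto the axis, the tip being the end whose local
    width is smaller (rice leaves taper to the tip).  When the two end
    widths differ by less than 5 % the assignment is ambiguous: it is then
    made deterministically (lexicographically smaller pixel becomes the
    tip) and flagged via ``ambiguous_tip``.
    """

    mask: np.ndarray  # H x W bool
    source: LeafScan
    centroid: tuple[float, float]
    axis: np.ndarray  # unit vector (d_row, d_col)
    tip_end: tuple[int, int]
    base_end: tuple[int, int]
    ambiguous_tip: bool = False
    cache: dict = field(default_factory=dict, repr=False)

    @property
    def dpi(self) -> int:
        return self.source.dpi

    @property
    def kind(self) -> str:
        return self.source.kind

    def foreground_pixels(self) -> np.ndarray:
        """(N, 3) array of RGB values under the mask."""
        return self.source.pixels[self.mask]

    def save_mask(self, path) -> None:
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(Path(path))


def px_to_cm(n_pixels: float, dpi: int) -> float:
    """Linear calibration: pixel count along a line to centimetres."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return n_pixels * 2.54 / dpi


def px2_to_cm2(n_pixels: float, dpi: int) -> float:
    """Area calibration: pixel count to square centimetres."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return n_pixels * (2.54 / dpi) ** 2


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of the coordinate covariance."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    # deterministic sign: positive first non-zero component
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def _end_width(s: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Mean perpendicular run over unit bins of axis position in [lo, hi]."""
    sel = (s >= lo) & (s <= hi)
    if not np.any(sel):
        return 0.0
    b = np.floor(s[sel] - lo).astype(int)
    pv = p[sel]
    nb = b.max() + 1
    pmax = ndimage.maximum(pv, labels=b + 1, index=np.arange(1, nb + 1))
    pmin = ndimage.minimum(pv, labels=b + 1, index=np.arange(1, nb + 1))
    widths = np.atleast_1d(pmax) - np.atleast_1d(pmin) + 1.0
    return float(np.mean(widths[np.isfinite(widths)]))


def _extreme_pixel(coords: np.ndarray, s: np.ndarray, end: str) -> tuple[int, int]:
    """Pixel at the min/max axis projection; ties resolved lexicographically."""
    key = s if end == "min" else -s
    target = key.min()
    cand = coords[key <= target + 1e-9]
    order = np.lexsort((cand[:, 1], cand[:, 0]))
    return tuple(int(v) for v in cand[order[0]])


def segment_object(
    scan: LeafScan,
    threshold: int = DEFAULT_THRESHOLD,
    method: str = "minwhite",
    min_pixels: int = MIN_FOREGROUND_PIXELS,
    tip_band: float = 0.05,
) -> SegmentedObject:
    """Segment the single organ in ``scan`` against the near-white background.

    Foreground = pixels whose min channel falls below ``threshold``
    (or below an Otsu threshold on the min channel when ``method='otsu'``),
    with holes filled and only the largest 8-connected component kept.

    Raises
    ------
    EmptyForeground
        if no component reaches ``min_pixels`` pixels.
    """
    minchan = scan.pixels.min(axis=2)
    if method == "otsu":
        # dark organ on a bright background: foreground lies at or below
        # the Otsu split
        fg = minchan <= threshold_otsu(minchan)
    elif method == "minwhite":
        fg = minchan < threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    if not fg.any():
        raise EmptyForeground("no pixel below the background threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    if n == 0:
        raise EmptyForeground("no foreground component")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_pixels:
        raise EmptyForeground(
            f"largest component has {sizes[best - 1]} px < {min_pixels}"
        )
    mask = labels == best

    coords = np.argwhere(mask).astype(float)
    centroid = tuple(coords.mean(axis=0))
    axis = _principal_axis(coords)
    perp = np.array([-axis[1], axis[0]])
    s = coords @ axis
    p = coords @ perp
    s0, s1 = float(s.min()), float(s.max())
    band = max(tip_band * (s1 - s0), 1.0)

    w_lo = _end_width(s, p, s0, s0 + band)
    w_hi = _end_width(s, p, s1 - band, s1)
    end_lo = _extreme_pixel(coords, s, "min")
    end_hi = _extreme_pixel(coords, s, "max")

    wmax = max(w_lo, w_hi, 1e-9)
    ambiguous = abs(w_lo - w_hi) < 0.05 * wmax
    if ambiguous:
        tip, base = (end_lo, end_hi) if end_lo <= end_hi else (end_hi, end_lo)
    elif w_lo < w_hi:
        tip, base = end_lo, end_hi
    else:
        tip, base = end_hi, end_lo

    return SegmentedObject(
        mask=mask,
        source=scan,
        centroid=centroid,
        axis=axis,
        tip_end=tip,
        base_end=base,
        ambiguous_tip=bool(ambiguous),
    )
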