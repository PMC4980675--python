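"""IR-channel segmentation into single and merged (collision) blobs.

FTIR-style recordings are high-contrast with a near-black background, so a
fixed intensity threshold (optionally Otsu's between-class-variance method)
followed by 8-connected component labelling is sufficient.  Components much
larger than a single animal are *not* rejected: they are kept and marked
``MERGED`` so the collision-resolution stage can identify the participating
animals and split the contour along the GFP channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

SINGLE = "SINGLE"
MERGED = "MERGED"


@dataclass
class FramePair:
    """One time point of a two-channel recording (red = IR, green = GFP)."""
    ir: np.ndarray
    gfp: np.ndarray
    frame_index: int
    time: float

    def __post_init__(self) -> None:
        if self.ir.shape != self.gfp.shape:
            raise ValueError("IR and GFP images must have identical dimensions")


@dataclass
class Blob:
    """A segmented connected component of the thresholded IR image."""
    pixels: np.ndarray                 # (n, 2) int, (row, col)
    contour: np.ndarray                # (m, 2) float, ordered boundary (row, col)
    area: int
    centroid: np.ndarray               # (row, col), px
    kind: str = SINGLE                 # SINGLE | MERGED
    gfp_fraction: float | None = None
    b_gfp: bool | None = None
    label: int = -1
    gfp_values: np.ndarray | None = None   # per-pixel GFP intensities (optional)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        r, c = self.pixels[:, 0], self.pixels[:, 1]
        return int(r.min()), int(c.min()), int(r.max()) + 1, int(c.max()) + 1

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.pixels))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


def _outer_contour(mask: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Longest closed iso-contour of a component mask (outer boundary only)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        # single-pixel degenerate component
        r0, c0 = origin
        return np.array([[r0, c0]], dtype=float)
    longest = max(contours, key=len)
    return longest - 1.0 + np.asarray(origin, dtype=float)


@dataclass
class SegmentationParams:
    ir_threshold: float = 0.3
    auto_threshold: bool = False
    min_area: int = 20
    merged_area_factor: float = 1.5
    gfp_threshold: float = 0.3
    gfp_fraction_min: float = 0.5


class ReferenceArea:
    """Running median of SINGLE-blob areas, the single-animal size reference.

    Seeded from the first segmented frame (where every blob is assumed to be
    a single animal); afterwards only blobs classified SINGLE contribute.
    """

    def __init__(self, maxlen: int = 500):
        self._areas: list[int] = []
        self._maxlen = maxlen

    @property
    def value(self) -> float | None:
        if not self._areas:
            return None
        return float(np.median(self._areas))

    def update(self, areas) -> None:
        self._areas.extend(int(a) for a in areas)
        if len(self._areas) > self._maxlen:
            self._areas = self._areas[-self._maxlen:]


def segment_frame(frame: FramePair, params: SegmentationParams,
                  reference_area: float | None = None) -> list[Blob]:
    """Threshold the IR channel and extract connected-component blobs.

    Components with area below ``min_area`` are dropped.  Components larger
    than ``merged_area_factor`` times the single-animal reference area are
    kept and marked ``MERGED`` (collision candidates), never discarded.
    An all-background frame yields an empty list.
    """
    ir = np.asarray(frame.ir)
    if ir.size == 0:
        raise ValueError("empty image")
    if params.auto_threshold and ir.max() > ir.min():
        thr = float(threshold_otsu(ir))
    else:
        thr = params.ir_threshold
    fg = ir >= thr
    if not fg.any():
        return []
    labels = measure.label(fg, connectivity=2)
    blobs: list[Blob] = []
    for region in measure.regionprops(labels):
        if region.area < params.min_area:
            continue
        r0, c0, _, _ = region.bbox
        contour = _outer_contour(region.image, (r0, c0))
        blobs.append(Blob(
            pixels=region.coords.astype(np.int32),
            contour=contour,
            area=int(region.area),
            centroid=np.asarray(region.centroid, dtype=float),
            label=int(region.label),
        ))
    ref = reference_area
    if ref is None and blobs:
        ref = float(np.median([b.area for b in blobs]))
    for b in blobs:
        b.kind = MERGED if (ref is not None and
                            b.area > params.merged_area_factor * ref) else SINGLE
    return blobs


def measure_gfp(blob: Blob, gfp_image: np.ndarray,
                gfp_threshold: float, gfp_fraction_min: float = 0.5,
                ) -> tuple[float, bool]:
    """Fraction of blob pixels suprathreshold in the GFP channel, and the
    per-blob GFP call b_gfp (fraction >= ``gfp_fraction_min``)."""
    if blob.pixels.size == 0:
        raise ValueError("empty pixel set")
    vals = gfp_image[blob.pixels[:, 0], blob.pixels[:, 1]]
    frac = float(np.mean(vals >= gfp_threshold))
    blob.gfp_fraction = frac
    blob.b_gfp = frac >= gfp_fraction_min
    return frac, blob.b_gfp
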