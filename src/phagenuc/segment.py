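"""Cell detection, long-axis extraction and infected-cell flagging.

The measurement stages downstream (axial profiles, nucleus quantification)
need, per cell: a pixel mask, the long axis with a defined "initial
measured end", and an infected/uninfected call.  Infection is scored the
way it is recognised by eye in DAPI-stained micrographs: a bright,
circular focus near the centre of the cell (the phage nucleus).

Conventions fixed here so results are exactly reproducible:

* Otsu threshold — class 0 holds the bins at or below the threshold; the
  reported threshold is the upper edge of the argmax bin, with ties broken
  by the floor of the mean argmax index.
* The "initial measured end" ``axis_p0`` is the lexicographically smaller
  (row, col) endpoint.
* Coordinates are 0-based (row, col) with pixel-centre semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import measure

from .errors import (
    AxisAmbiguousError,
    DegenerateHistogramError,
    NoCellsError,
)

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class OtsuResult:
    """Otsu threshold plus the evidence it was chosen on."""

    threshold: float
    between_class_variance: float
    histogram: np.ndarray
    bin_edges: np.ndarray


@dataclass
class CellROI:
    """One detected (or externally supplied) cell region.

    ``axis_p0`` is the initial measured end; ``length_px`` the Euclidean
    p0-p1 distance.  ``mask`` is a full-frame boolean array.
    """

    cell_id: int
    mask: np.ndarray
    centroid: tuple[float, float]
    axis_p0: tuple[float, float] | None = None
    axis_p1: tuple[float, float] | None = None
    length_px: float | None = None
    infected: bool | None = None
    meta: dict = field(default_factory=dict)
    bbox: tuple[slice, slice] | None = None  # tight crop, a speed aid only

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def crop(self, pad: int = 2) -> tuple[slice, slice]:
        """Bounding-box slices around the mask (cached), padded by ``pad``."""
        if self.bbox is None:
            rows, cols = np.nonzero(self.mask)
            self.bbox = (
                slice(max(int(rows.min()) - pad, 0),
                      min(int(rows.max()) + pad + 1, self.mask.shape[0])),
                slice(max(int(cols.min()) - pad, 0),
                      min(int(cols.max()) + pad + 1, self.mask.shape[1])),
            )
        return self.bbox

    def width_estimate(self) -> float:
        """Mean cell width in px, from area / axis length (rod geometry)."""
        if not self.length_px:
            raise ValueError("axis not set")
        return self.area / self.length_px


def otsu_threshold(pixels: np.ndarray, n_bins: int = 256) -> OtsuResult:
    """Otsu's method: maximize between-class variance over a binned histogram.

    Pixels are binned into ``n_bins`` equal-width bins over [min, max].
    For every candidate split ``t`` (class 0 = bins 0..t), the between-class
    variance is sigma_b^2(t) = w0 w1 (mu0 - mu1)^2.  The returned threshold
    is the upper edge of bin ``t*``; among tied maxima, ``t*`` is the floor
    of the mean argmax index.

    Raises
    ------
    DegenerateHistogramError
        if the input has fewer than two distinct values.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size == 0 or np.min(pixels) == np.max(pixels):
        raise DegenerateHistogramError("constant or empty intensity collection")
    hist, edges = np.histogram(pixels, bins=n_bins, range=(pixels.min(), pixels.max()))
    sigma_b = between_class_variance(hist)
    top = float(sigma_b.max())
    ties = np.flatnonzero(sigma_b >= top * (1.0 - 1e-12))
    t_star = int(np.floor(ties.mean()))
    return OtsuResult(
        threshold=float(edges[t_star + 1]),
        between_class_variance=float(sigma_b[t_star]),
        histogram=hist,
        bin_edges=edges,
    )


def between_class_variance(hist: np.ndarray) -> np.ndarray:
    """sigma_b^2(t) for every split t in 0..n_bins-2 (vectorized cumsums)."""
    hist = np.asarray(hist, dtype=float)
    idx = np.arange(hist.size)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m0 = np.cumsum(hist * idx)[:-1]
    m1 = (hist * idx).sum() - m0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2 / hist.sum() ** 2
    return sigma_b


def segment_cells(
    image: np.ndarray,
    min_area: float = 200.0,
    max_area: float = 6000.0,
    smooth_sigma: float = 1.0,
    log_transform: bool = True,
) -> list[CellROI]:
    """Detect cells in a membrane/composite image by global Otsu + labeling.

    ``image`` may be a single channel (e.g. a membrane stain) or a
    ``(channels, rows, cols)`` stack, in which case the interior channels
    (GFP + DAPI) are summed — the blurred membrane ridge straddles the true
    cell boundary and would bias an intensity threshold outward by most of
    a pixel.  The composite is Gaussian-smoothed,
    log-compressed (``log1p``; infected cells make the composite histogram
    trimodal — background / cytoplasm / bright nucleus — and without
    compression Otsu can split cytoplasm from nucleus instead of cells from
    background), thresholded with :func:`otsu_threshold`, hole-filled and
    labeled with 8-connectivity; components outside [min_area, max_area] or
    touching the image border are discarded (border cells are logged).
    Cell ids are assigned in raster order of the centroid.

    Raises
    ------
    NoCellsError
        if no component survives.
    """
    image = np.asarray(image, dtype=float)
    composite = image[:2].sum(axis=0) if image.ndim == 3 else image
    if smooth_sigma > 0:
        composite = ndi.gaussian_filter(composite, sigma=smooth_sigma)
    work = np.log1p(np.maximum(composite, 0.0)) if log_transform else composite
    try:
        thr = otsu_threshold(work).threshold
    except DegenerateHistogramError as exc:
        raise NoCellsError(f"blank image: {exc}") from exc
    # refine to the midpoint of the two class medians (linear intensity):
    # this pins the mask contour to the half-intensity edge of the blurred
    # cell boundary instead of wherever the histogram weights put the Otsu
    # split, and medians keep bright nuclei from dragging the level up
    fg = work > thr
    if fg.any() and (~fg).any():
        mid = (np.median(composite[fg]) + np.median(composite[~fg])) / 2.0
        binary = composite > mid
    else:
        binary = fg
    binary = ndi.binary_fill_holes(binary)
    labeled, n = ndi.label(binary, structure=_EIGHT)
    shape = binary.shape
    rois: list[CellROI] = []
    for lab, sl in enumerate(ndi.find_objects(labeled), start=1):
        if sl is None:
            continue
        mask_loc = labeled[sl] == lab
        area = int(mask_loc.sum())
        if not (min_area <= area <= max_area):
            continue
        touches = (
            sl[0].start == 0
            or sl[1].start == 0
            or sl[0].stop == shape[0]
            or sl[1].stop == shape[1]
        )
        if touches:
            log.info("discarding component %d: touches the image border", lab)
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[sl] = mask_loc
        rows, cols = np.nonzero(mask_loc)
        pad = (
            slice(max(sl[0].start - 2, 0), min(sl[0].stop + 2, shape[0])),
            slice(max(sl[1].start - 2, 0), min(sl[1].stop + 2, shape[1])),
        )
        rois.append(
            CellROI(
                cell_id=0,
                mask=mask,
                centroid=(
                    float(rows.mean() + sl[0].start),
                    float(cols.mean() + sl[1].start),
                ),
                bbox=pad,
            )
        )
    if not rois:
        raise NoCellsError("no component within the area limits")
    rois.sort(key=lambda r: r.centroid)
    for i, roi in enumerate(rois, start=1):
        roi.cell_id = i
    return rois


def long_axis(
    roi: CellROI, min_anisotropy: float = 1.05, step: float = 0.25
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Long axis of a mask from its second central moments.

    The direction is the principal eigenvector of the covariance matrix of
    the mask pixel coordinates; the endpoints are found by marching along
    that direction from the centroid until the line leaves the mask
    (subpixel, nearest-pixel membership).  ``axis_p0`` is the
    lexicographically smaller endpoint.  Updates ``roi`` in place and
    returns ``(p0, p1, length_px)``.

    Raises
    ------
    AxisAmbiguousError
        if the eigenvalue ratio is below ``min_anisotropy`` (isotropic mask).
    """
    sl = roi.crop()
    off = np.array([sl[0].start, sl[1].start], dtype=float)
    rows, cols = np.nonzero(roi.mask[sl])
    if rows.size < 4:
        raise AxisAmbiguousError("mask smaller than 4 px")
    coords = np.stack([rows, cols]).astype(float) + off[:, None]
    cov = np.cov(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0 or evals[1] / evals[0] < min_anisotropy:
        raise AxisAmbiguousError(
            f"eigenvalue ratio {evals[1] / max(evals[0], 1e-12):.3f} < {min_anisotropy}"
        )
    direction = evecs[:, 1]
    centroid = coords.mean(axis=1)

    def _march(sign: float) -> np.ndarray:
        p = centroid.copy()
        t = 0.0
        while True:
            t += step
            q = centroid + sign * t * direction
            r, c = int(round(q[0])), int(round(q[1]))
            if (
                r < 0
                or c < 0
                or r >= roi.mask.shape[0]
                or c >= roi.mask.shape[1]
                or not roi.mask[r, c]
            ):
                return p
            p = q

    p0 = _march(-1.0)
    p1 = _march(+1.0)
    if tuple(p1) < tuple(p0):
        p0, p1 = p1, p0
    length = float(np.hypot(*(p1 - p0)))
    roi.axis_p0 = (float(p0[0]), float(p0[1]))
    roi.axis_p1 = (float(p1[0]), float(p1[1]))
    roi.length_px = length
    return roi.axis_p0, roi.axis_p1, length


def flag_infected(
    roi: CellROI,
    dapi: np.ndarray,
    brightness_min: float = 2.0,
    circularity_min: float = 0.7,
    center_band: float = 1 / 3,
    max_area_frac: float = 0.6,
) -> CellROI:
    """Flag a cell as infected from its DAPI signal.

    Within the ROI the DAPI pixels are Otsu-thresholded and the largest
    bright component is taken as the candidate phage nucleus.  The cell is
    infected iff the candidate is (a) bright — mean intensity at least
    ``brightness_min`` times the complementary in-ROI mean, (b) compact — it
    covers at most ``max_area_frac`` of the ROI (in an uninfected cell the
    "bright" class degenerates to the whole cell interior), (c) circular —
    4 pi area / perimeter^2 >= ``circularity_min`` — and (d) central — its
    centroid projects into the central ``center_band`` fraction of the cell
    axis.  Any failed criterion (including a degenerate histogram) yields
    ``infected=False``.
    """
    roi.infected = False
    sl = roi.crop()
    dapi_loc = np.asarray(dapi[sl], dtype=float)
    mask_loc = roi.mask[sl]
    try:
        thr = otsu_threshold(dapi_loc[mask_loc]).threshold
    except DegenerateHistogramError:
        return roi
    bright = (dapi_loc > thr) & mask_loc
    labeled, n = ndi.label(bright, structure=_EIGHT)
    if n == 0:
        return roi
    sizes = ndi.sum_labels(bright, labeled, index=np.arange(1, n + 1))
    blob = labeled == (int(np.argmax(sizes)) + 1)
    complement = mask_loc & ~blob
    if not complement.any():
        return roi
    if dapi_loc[blob].mean() < brightness_min * dapi_loc[complement].mean():
        return roi
    if blob.sum() > max_area_frac * mask_loc.sum():
        return roi
    perimeter = measure.perimeter(blob)
    if perimeter <= 0 or 4.0 * np.pi * blob.sum() / perimeter**2 < circularity_min:
        return roi
    if roi.axis_p0 is None:
        return roi
    p0 = np.array(roi.axis_p0)
    p1 = np.array(roi.axis_p1)
    rows, cols = np.nonzero(blob)
    blob_centroid = np.array([rows.mean() + sl[0].start, cols.mean() + sl[1].start])
    axis = p1 - p0
    t = float((blob_centroid - p0) @ axis / (axis @ axis))
    if abs(t - 0.5) > center_band / 2.0:
        return roi
    roi.infected = True
    roi.meta["nucleus_candidate_area"] = int(blob.sum())
    return roi


# ---------------------------------------------------------------------------
# I/O: label images and ROI tables


def rois_to_label_image(rois: list[CellROI], shape: tuple[int, int]) -> np.ndarray:
    label = np.zeros(shape, dtype=np.int32)
    for roi in rois:
        label[roi.mask] = roi.cell_id
    return label


def rois_from_label_image(label: np.ndarray) -> list[CellROI]:
    """Escape hatch: build ROIs from an externally drawn label image."""
    label = np.asarray(label)
    rois = []
    for lab in np.unique(label):
        if lab == 0:
            continue
        mask = label == lab
        rows, cols = np.nonzero(mask)
        rois.append(
            CellROI(
                cell_id=int(lab),
                mask=mask,
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    return rois


def write_label_image(path: str | Path, rois: list[CellROI], shape: tuple[int, int]) -> None:
    tifffile.imwrite(Path(path), rois_to_label_image(rois, shape).astype(np.int32))


def read_label_image(path: str | Path) -> list[CellROI]:
    return rois_from_label_image(tifffile.imread(Path(path)))


def roi_table(rois: list[CellROI]) -> pd.DataFrame:
    rows = []
    for r in rois:
        rows.append(
            {
                "cell_id": r.cell_id,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area,
                "axis_p0_row": r.axis_p0[0] if r.axis_p0 else np.nan,
                "axis_p0_col": r.axis_p0[1] if r.axis_p0 else np.nan,
                "axis_p1_row": r.axis_p1[0] if r.axis_p1 else np.nan,
                "axis_p1_col": r.axis_p1[1] if r.axis_p1 else np.nan,
                "length_px": r.length_px if r.length_px else np.nan,
                "infected": r.infected,
            }
        )
    return pd.DataFrame(rows)
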