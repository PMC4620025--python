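"""Frame preprocessing: binarization, seeded watershed, ROI extraction.

Conventions: 0-based row-major pixel indices; bounding boxes are
half-open ``(min_row, min_col, max_row, max_col)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential, watershed
from skimage.transform import resize

__all__ = ["RoiPatch", "binarize", "segment_nuclei", "extract_rois"]


@dataclass(frozen=True)
class RoiPatch:
    """Fixed-size intensity patch around one segmented nucleus."""

    cell_id: int
    patch: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # half-open (min_row, min_col, max_row, max_col)


def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    manual_threshold: float | None = None,
    opening_radius: int = 1,
) -> np.ndarray:
    """Foreground mask: pixel true iff intensity >= threshold.

    ``method`` is "otsu" (threshold derived from the intensity histogram)
    or "manual" (requires ``manual_threshold``). A morphological opening
    with a disc footprint of ``opening_radius`` removes speckle; radius 0
    disables it. A constant frame with Otsu thresholding yields an
    all-false mask with a warning rather than an error.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a nonempty 2-D array")
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual thresholding requires manual_threshold")
        mask = frame >= manual_threshold
    elif method == "otsu":
        if manual_threshold is not None:
            raise ValueError("manual_threshold is only valid with method='manual'")
        if np.ptp(frame) == 0:
            warnings.warn(
                "constant frame: Otsu threshold is degenerate; returning empty mask",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.zeros(frame.shape, dtype=bool)
        # threshold_otsu returns the last intensity of the background
        # class, so foreground is strictly above it
        mask = frame > threshold_otsu(frame)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    if opening_radius > 0:
        mask = ndi.binary_opening(mask, structure=disk(opening_radius))
    return mask


def segment_nuclei(
    frame: np.ndarray,
    mask: np.ndarray,
    min_seed_distance: int = 5,
    min_area: int = 10,
) -> np.ndarray:
    """Split the foreground into nuclei with a seeded watershed.

    Seeds are local maxima of the Euclidean distance transform of the
    mask, at least ``min_seed_distance`` pixels apart within each
    connected component; the watershed floods the inverted distance
    transform from those seeds, so touching nuclei split along the ridge
    between their distance peaks. Regions smaller than ``min_area``
    pixels are removed and labels recompacted to 1..n.
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    components, _ = ndi.label(mask)
    coords = peak_local_max(
        distance,
        min_distance=max(1, int(min_seed_distance)),
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = components
    labels = watershed(-distance, markers, mask=mask)
    if min_area > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def extract_rois(
    frame: np.ndarray,
    labels: np.ndarray,
    roi_shape: tuple[int, int] = (48, 48),
    background_level: float | None = None,
) -> list[RoiPatch]:
    """Cut one fixed-size patch per labeled region.

    A square window the size of the region's larger bbox side, centered
    on the bbox center, is cropped (padded with ``background_level``,
    default the frame median, where it leaves the frame) and resampled to
    ``roi_shape``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape != frame.shape:
        raise ValueError("labels shape must match frame shape")
    n = int(labels.max())
    if n == 0:
        return []
    if background_level is None:
        background_level = float(np.median(frame))
    h, w = frame.shape
    objects = ndi.find_objects(labels)
    patches: list[RoiPatch] = []
    for cell_id in range(1, n + 1):
        sl = objects[cell_id - 1]
        if sl is None:
            continue
        min_r, max_r = sl[0].start, sl[0].stop
        min_c, max_c = sl[1].start, sl[1].stop
        rows, cols = np.nonzero(labels == cell_id)
        centroid = (float(rows.mean()), float(cols.mean()))
        side = max(max_r - min_r, max_c - min_c)
        cr = (min_r + max_r) / 2.0
        cc = (min_c + max_c) / 2.0
        half = side / 2.0
        r0, r1 = int(np.floor(cr - half)), int(np.ceil(cr + half))
        c0, c1 = int(np.floor(cc - half)), int(np.ceil(cc + half))
        window = np.full((r1 - r0, c1 - c0), background_level, dtype=np.float64)
        fr0, fr1 = max(r0, 0), min(r1, h)
        fc0, fc1 = max(c0, 0), min(c1, w)
        window[fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0] = frame[fr0:fr1, fc0:fc1]
        patch = resize(
            window, roi_shape, preserve_range=True, anti_aliasing=True
        ).astype(np.float64)
        patches.append(
            RoiPatch(
                cell_id=cell_id,
                patch=patch,
                centroid=centroid,
                bbox=(min_r, min_c, max_r, max_c),
            )
        )
    return patches
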