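"""Per-ROI feature extractors: RAW, HoG, GIST, SIFT.

Every extractor is a pure function of the patch and its configuration
and returns a fixed-length :class:`FeatureVector`; vectors of one kind
column-stack into the d x N sample matrix consumed by sparse coding.

RAW is a resampled pixel-intensity vector (default 9 x 6 = 54 entries);
HoG is block-normalized gradient-orientation histograms; GIST pools a
Gabor filter bank over a spatial grid; SIFT is a dense, aggregated
gradient-orientation descriptor (4 x 4 spatial bins x 8 orientations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import hog as _skimage_hog
from skimage.filters import gabor_kernel
from scipy.signal import fftconvolve

from .preprocess import RoiPatch

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "Standardizer",
    "raw_feature",
    "hog_feature",
    "gist_feature",
    "sift_feature",
    "hog_length",
    "assemble_feature_matrix",
    "extract_features",
]

FEATURE_NAMES = ("RAW", "HoG", "GIST", "SIFT")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    feature_name: str

    def __post_init__(self) -> None:
        if self.feature_name not in FEATURE_NAMES:
            raise ValueError(f"feature_name must be one of {FEATURE_NAMES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureMatrix:
    """d x N matrix whose columns are per-nucleus feature vectors."""

    values: np.ndarray
    feature_name: str
    standardized: bool = False

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]


def _patch_array(patch: RoiPatch | np.ndarray) -> np.ndarray:
    arr = patch.patch if isinstance(patch, RoiPatch) else patch
    return np.asarray(arr, dtype=np.float64)


def raw_feature(
    patch: RoiPatch | np.ndarray, out_shape: tuple[int, int] = (9, 6)
) -> FeatureVector:
    """Pixel-wise intensity feature: resample, flatten row-major, min-max
    rescale to [0, 1] (a constant patch maps to all zeros)."""
    from skimage.transform import resize

    arr = _patch_array(patch)
    small = resize(arr, out_shape, preserve_range=True, anti_aliasing=True)
    flat = small.ravel()
    span = flat.max() - flat.min()
    if span == 0:
        return FeatureVector(np.zeros(flat.shape), "RAW")
    return FeatureVector((flat - flat.min()) / span, "RAW")


def hog_length(cells: tuple[int, int], orientations: int, block: int = 2) -> int:
    br = cells[0] - block + 1
    bc = cells[1] - block + 1
    return br * bc * block * block * orientations


def hog_feature(
    patch: RoiPatch | np.ndarray,
    cells: tuple[int, int] = (3, 3),
    orientations: int = 9,
    block: int = 2,
    cell_pixels: int = 8,
) -> FeatureVector:
    """Histogram of oriented gradients over a ``cells`` grid.

    The patch is resampled so every cell is ``cell_pixels`` square, then
    per-cell orientation histograms are L2-Hys block-normalized and
    concatenated; the output length depends only on the configuration.
    """
    from skimage.transform import resize

    arr = _patch_array(patch)
    if min(cells) < 1 or min(cells) < block:
        raise ValueError("cells grid must be at least block x block")
    work = resize(
        arr,
        (cells[0] * cell_pixels, cells[1] * cell_pixels),
        preserve_range=True,
        anti_aliasing=True,
    )
    vec = _skimage_hog(
        work,
        orientations=orientations,
        pixels_per_cell=(cell_pixels, cell_pixels),
        cells_per_block=(block, block),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    return FeatureVector(np.asarray(vec, dtype=np.float64), "HoG")


def gist_feature(
    patch: RoiPatch | np.ndarray,
    scales: int = 4,
    orientations: int = 8,
    grid: tuple[int, int] = (4, 4),
) -> FeatureVector:
    """Gabor filter-bank energies averaged over a spatial grid.

    ``scales`` logarithmically spaced spatial frequencies x
    ``orientations`` filter angles; each magnitude response is averaged
    in every grid cell. Length = scales * orientations * grid_r * grid_c.
    The patch mean is removed first, so a constant patch gives zeros.
    """
    arr = _patch_array(patch)
    arr = arr - arr.mean()
    gr, gc = grid
    h, w = arr.shape
    row_edges = np.linspace(0, h, gr + 1).astype(int)
    col_edges = np.linspace(0, w, gc + 1).astype(int)
    out = np.empty(scales * orientations * gr * gc)
    i = 0
    for si in range(scales):
        frequency = 0.05 * (2.0**si)
        for oi in range(orientations):
            theta = np.pi * oi / orientations
            kernel = gabor_kernel(frequency, theta=theta)
            resp = fftconvolve(arr, kernel, mode="same")
            mag = np.abs(resp)
            for r in range(gr):
                for c in range(gc):
                    cell = mag[row_edges[r] : row_edges[r + 1], col_edges[c] : col_edges[c + 1]]
                    out[i] = cell.mean() if cell.size else 0.0
                    i += 1
    return FeatureVector(out, "GIST")


def _sift_descriptor(window: np.ndarray, n_spatial: int = 4, n_orient: int = 8) -> np.ndarray:
    """One 4x4x8 gradient-orientation descriptor with SIFT-style
    contrast normalization (L2, clip at 0.2, renormalize)."""
    gy, gx = np.gradient(window)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    h, w = window.shape
    row_bin = np.minimum((np.arange(h) * n_spatial) // max(h, 1), n_spatial - 1)
    col_bin = np.minimum((np.arange(w) * n_spatial) // max(w, 1), n_spatial - 1)
    ori_bin = np.minimum((ang / (2 * np.pi) * n_orient).astype(int), n_orient - 1)
    desc = np.zeros((n_spatial, n_spatial, n_orient))
    np.add.at(
        desc,
        (row_bin[:, None] * np.ones(w, int), np.ones(h, int)[:, None] * col_bin, ori_bin),
        mag,
    )
    vec = desc.ravel()
    norm = np.linalg.norm(vec)
    if norm == 0:
        return vec
    vec = np.minimum(vec / norm, 0.2)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def sift_feature(
    patch: RoiPatch | np.ndarray, grid: tuple[int, int] = (2, 2)
) -> FeatureVector:
    """Dense aggregated SIFT: one 128-entry descriptor per grid window,
    averaged into a single 128-entry vector (no keypoint detection)."""
    arr = _patch_array(patch)
    gr, gc = grid
    h, w = arr.shape
    row_edges = np.linspace(0, h, gr + 1).astype(int)
    col_edges = np.linspace(0, w, gc + 1).astype(int)
    descs = []
    for r in range(gr):
        for c in range(gc):
            window = arr[row_edges[r] : row_edges[r + 1], col_edges[c] : col_edges[c + 1]]
            if window.size == 0:
                descs.append(np.zeros(128))
            else:
                descs.append(_sift_descriptor(window))
    return FeatureVector(np.mean(descs, axis=0), "SIFT")


_EXTRACTORS = {
    "RAW": raw_feature,
    "HoG": hog_feature,
    "GIST": gist_feature,
    "SIFT": sift_feature,
}


def extract_features(
    patches: list[RoiPatch], feature_name: str, **kwargs
) -> list[FeatureVector]:
    if feature_name not in _EXTRACTORS:
        raise ValueError(f"unknown feature {feature_name!r}; choose from {FEATURE_NAMES}")
    fn = _EXTRACTORS[feature_name]
    return [fn(p, **kwargs) for p in patches]


def assemble_feature_matrix(
    vectors: list[FeatureVector], standardize: bool = False
) -> FeatureMatrix:
    """Column-stack feature vectors of one kind into a d x N matrix.

    With ``standardize`` each row is centered and scaled to unit variance
    (constant rows are left at zero). Mixed feature names or lengths are
    an error, as is an empty sequence.
    """
    if not vectors:
        raise ValueError("cannot assemble an empty sequence of feature vectors")
    name = vectors[0].feature_name
    d = len(vectors[0])
    for v in vectors:
        if v.feature_name != name:
            raise ValueError(f"mixed feature names: {name} vs {v.feature_name}")
        if len(v) != d:
            raise ValueError(f"mixed feature lengths: {d} vs {len(v)}")
    M = np.column_stack([v.values for v in vectors]).astype(np.float64)
    if standardize:
        M = Standardizer().fit(M).transform(M)
        return FeatureMatrix(M, name, standardized=True)
    return FeatureMatrix(M, name)


@dataclass
class Standardizer:
    """Per-row (per-feature) centering and unit-variance scaling.

    Fit on the training matrix and applied to train and test alike so no
    test statistics leak into the representation.
    """

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, M: np.ndarray) -> "Standardizer":
        self.mean_ = M.mean(axis=1, keepdims=True)
        std = M.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        self.std_ = std
        return self

    def transform(self, M: np.ndarray) -> np.ndarray:
        if self.mean_ is None or self.std_ is None:
            raise RuntimeError("Standardizer used before fit")
        return (M - self.mean_) / self.std_
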