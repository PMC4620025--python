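"""Synthetic data: labeled nucleus scenes and sparse-coding instances.

Two generators make the whole pipeline testable without real microscopy:

* :func:`generate_cell_frames` renders grayscale frames containing nuclei
  of the four cell-cycle phases (interphase, prophase, metaphase,
  anaphase) as Gaussian-shaded ellipses on a noisy background, together
  with ground-truth label masks, phases, and centroids. The phases differ
  in area, eccentricity, and internal texture so that intensity, shape,
  and local-structure features can all separate them: interphase nuclei
  are large and smooth, prophase nuclei carry speckled chromatin texture,
  metaphase nuclei are elongated bright bands, and anaphase nuclei are
  two adjacent sub-blobs of separating chromatids.

* :func:`generate_tsc_instance` draws a ground-truth dictionary A with
  unit-norm atoms and sparse codes s, and returns noisy samples
  x = A s + r — the generative model that topographic sparse coding
  inverts — so dictionary recovery can be measured against known atoms.

Both are deterministic functions of their config (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PHASES",
    "PhaseShapeParams",
    "SynthImageConfig",
    "SynthTscConfig",
    "GroundTruthScene",
    "PlacementError",
    "default_class_shape_params",
    "generate_cell_frames",
    "generate_tsc_instance",
]

PHASES: tuple[str, str, str, str] = ("interphase", "prophase", "metaphase", "anaphase")

_MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """Cannot place the requested number of nuclei at the given separation."""


@dataclass(frozen=True)
class PhaseShapeParams:
    """Ellipse axis ranges (pixels) and texture parameters for one phase.

    ``texture`` is the relative amplitude of multiplicative speckle
    inside the nucleus; ``split`` renders two offset sub-blobs
    (anaphase); ``brightness`` scales the peak amplitude.
    """

    major_axis: tuple[float, float]
    minor_axis: tuple[float, float]
    texture: float = 0.0
    split: bool = False
    brightness: float = 1.0


def default_class_shape_params() -> dict[str, PhaseShapeParams]:
    return {
        "interphase": PhaseShapeParams((9.0, 12.0), (8.0, 11.0), texture=0.0),
        "prophase": PhaseShapeParams((8.0, 10.0), (7.0, 9.0), texture=0.6),
        "metaphase": PhaseShapeParams((12.0, 15.0), (3.0, 4.5), texture=0.0, brightness=1.4),
        "anaphase": PhaseShapeParams((5.0, 6.5), (4.0, 5.5), texture=0.0, split=True),
    }


@dataclass(frozen=True)
class SynthImageConfig:
    frame_height: int = 256
    frame_width: int = 256
    n_cells_per_frame: int = 12
    n_frames: int = 8
    class_shape_params: Mapping[str, PhaseShapeParams] = field(
        default_factory=default_class_shape_params
    )
    noise_sd: float = 300.0
    background_level: float = 2000.0
    amplitude: float = 20000.0
    min_separation: float = 36.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.n_cells_per_frame < 0 or self.n_frames <= 0:
            raise ValueError("n_frames must be positive, n_cells_per_frame nonnegative")
        if set(self.class_shape_params) != set(PHASES):
            raise ValueError(f"class_shape_params must define exactly the phases {PHASES}")
        if self.min_separation < 0 or self.noise_sd < 0:
            raise ValueError("min_separation and noise_sd must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class SynthTscConfig:
    d: int = 16
    k: int = 16
    N: int = 1000
    atoms_active_per_sample: int = 3
    code_scale: float = 1.0
    noise_sd: float = 0.01
    topographic: bool = False
    group_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.k <= 0 or self.N <= 0:
            raise ValueError("d, k, N must be positive")
        if not (0 < self.atoms_active_per_sample <= self.k):
            raise ValueError("atoms_active_per_sample must be in (0, k]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruthScene:
    """One synthetic frame with its ground-truth segmentation and phases."""

    frame: np.ndarray
    label_mask: np.ndarray
    phases: tuple[str, ...]
    centroids: np.ndarray  # (n_cells, 2) float (row, col)

    def __post_init__(self) -> None:
        labels = np.unique(self.label_mask)
        labels = labels[labels > 0]
        if len(labels) != len(self.phases) or len(self.phases) != len(self.centroids):
            raise ValueError("label/phase/centroid counts disagree")


def _place_centroids(
    rng: np.random.Generator, cfg: SynthImageConfig, margin: float
) -> np.ndarray:
    """Rejection-sample centroids pairwise >= min_separation apart."""
    placed: list[tuple[float, float]] = []
    attempts = 0
    lo_r, hi_r = margin, cfg.frame_height - margin
    lo_c, hi_c = margin, cfg.frame_width - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError("frame too small for the nucleus margin")
    while len(placed) < cfg.n_cells_per_frame:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {cfg.n_cells_per_frame} nuclei with "
                f"min_separation={cfg.min_separation} after {attempts} attempts"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        attempts += 1
        if all(
            (r - pr) ** 2 + (c - pc) ** 2 >= cfg.min_separation**2 for pr, pc in placed
        ):
            placed.append((r, c))
    return np.array(placed, dtype=np.float64).reshape(-1, 2)


def _render_blob(
    canvas: np.ndarray,
    mask: np.ndarray,
    label: int,
    center: tuple[float, float],
    major: float,
    minor: float,
    theta: float,
    amplitude: float,
    texture: float,
    rng: np.random.Generator,
) -> None:
    """Add one Gaussian-shaded ellipse to the canvas and its label footprint."""
    h, w = canvas.shape
    r0, c0 = center
    half = int(np.ceil(2.2 * max(major, minor))) + 1
    rr = np.arange(max(0, int(r0) - half), min(h, int(r0) + half + 1))
    cc = np.arange(max(0, int(c0) - half), min(w, int(c0) + half + 1))
    if rr.size == 0 or cc.size == 0:
        return
    R, C = np.meshgrid(rr - r0, cc - c0, indexing="ij")
    u = R * np.cos(theta) + C * np.sin(theta)
    v = -R * np.sin(theta) + C * np.cos(theta)
    # quadratic form: 1 on the ellipse boundary
    q = (u / major) ** 2 + (v / minor) ** 2
    shading = np.exp(-1.5 * q)
    inside = q <= 1.0
    profile = amplitude * shading * inside
    if texture > 0:
        speckle = 1.0 + texture * rng.standard_normal(profile.shape)
        profile = profile * np.clip(speckle, 0.0, 2.0)
    canvas[np.ix_(rr, cc)] += profile
    sub = mask[np.ix_(rr, cc)]
    sub[inside] = label
    mask[np.ix_(rr, cc)] = sub


def generate_cell_frames(config: SynthImageConfig) -> list[GroundTruthScene]:
    """Render ``n_frames`` scenes, each with ``n_cells_per_frame`` nuclei.

    Phase classes are drawn uniformly; centroids are rejection-sampled to
    be pairwise at least ``min_separation`` apart. Intensities are
    clipped to the configured bit depth.
    """
    rng = np.random.default_rng(config.seed)
    max_val = 2**config.bit_depth - 1
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    margin = max(
        (max(p.major_axis[1], p.minor_axis[1]) for p in config.class_shape_params.values()),
        default=0.0,
    ) * (2.0 if any(p.split for p in config.class_shape_params.values()) else 1.5)
    scenes: list[GroundTruthScene] = []
    for _ in range(config.n_frames):
        canvas = np.full(
            (config.frame_height, config.frame_width),
            config.background_level,
            dtype=np.float64,
        )
        mask = np.zeros(canvas.shape, dtype=np.int32)
        centroids = (
            _place_centroids(rng, config, margin)
            if config.n_cells_per_frame > 0
            else np.zeros((0, 2))
        )
        phases = tuple(
            PHASES[i]
            for i in rng.integers(0, len(PHASES), size=config.n_cells_per_frame)
        )
        for label, ((r, c), phase) in enumerate(zip(centroids, phases), start=1):
            p = config.class_shape_params[phase]
            major = rng.uniform(*p.major_axis)
            minor = rng.uniform(*p.minor_axis)
            theta = rng.uniform(0, np.pi)
            amp = config.amplitude * p.brightness
            if p.split:
                # two adjacent chromatid blobs along the major axis; the
                # footprints overlap so the nucleus stays one component
                off = 0.8 * major
                for sign in (-1.0, 1.0):
                    cr = r + sign * off * np.cos(theta)
                    cc_ = c + sign * off * np.sin(theta)
                    _render_blob(
                        canvas, mask, label, (cr, cc_), major, minor, theta,
                        amp, p.texture, rng,
                    )
            else:
                _render_blob(
                    canvas, mask, label, (r, c), major, minor, theta,
                    amp, p.texture, rng,
                )
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
        frame = np.clip(np.rint(canvas), 0, max_val).astype(dtype)
        scenes.append(GroundTruthScene(frame, mask, phases, centroids))
    return scenes


def generate_tsc_instance(
    config: SynthTscConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (true_dictionary, true_codes, samples) with samples = A s + noise.

    The dictionary has unit-norm Gaussian atoms. Each code column has
    exactly ``atoms_active_per_sample`` nonzeros; when ``topographic`` the
    active atoms are drawn from one ``group_size x group_size``
    neighborhood of a square atom grid (so co-active atoms are grid
    neighbors), otherwise uniformly at random.
    """
    rng = np.random.default_rng(config.seed)
    A = rng.standard_normal((config.d, config.k))
    A /= np.linalg.norm(A, axis=0)
    s = np.zeros((config.k, config.N))
    if config.topographic:
        grid = int(np.sqrt(config.k))
        if grid * grid != config.k:
            raise ValueError("topographic instances require k to be a perfect square")
        gsz = min(config.group_size, grid)
        if config.atoms_active_per_sample > gsz * gsz:
            raise ValueError("more active atoms than one grid neighborhood holds")
    for n in range(config.N):
        if config.topographic:
            r0 = rng.integers(0, grid)
            c0 = rng.integers(0, grid)
            neigh = [
                ((r0 + dr) % grid) * grid + (c0 + dc) % grid
                for dr in range(gsz)
                for dc in range(gsz)
            ]
            active = rng.choice(neigh, size=config.atoms_active_per_sample, replace=False)
        else:
            active = rng.choice(config.k, size=config.atoms_active_per_sample, replace=False)
        mags = config.code_scale * (0.5 + rng.random(config.atoms_active_per_sample))
        signs = rng.choice([-1.0, 1.0], size=config.atoms_active_per_sample)
        s[active, n] = mags * signs
    x = A @ s
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
    return A, s, x
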