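"""Synthetic thorax phantoms with ground truth.

No public CT dataset accompanies the method this package implements, so
all testing runs on a parametric phantom: two dark elliptical lung fields
inside a brighter thorax ellipse on a black background, with bright
nodule blobs, a configurable junction gap between the lungs, and a
degradation model (linear-motion blur + additive Gaussian noise) that the
restoration stage is expected to invert.

4-D acquisition is emulated by rendering the lungs at a cranio-caudal
displacement driven by a sinusoidal breathing signal; each frame carries
its signal value as a tag and frames are sorted retrospectively into
respiratory phase bins.  Frames are rendered at the representative
displacement of their phase bin (stepwise motion), which gives every bin
an exact ground-truth lung position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .preprocess import BlurSpec

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "Frame",
    "PhantomError",
    "generate_slice",
    "generate_4d",
    "sort_by_phase",
    "apply_degradation",
]


class PhantomError(RuntimeError):
    """Raised when a phantom cannot be constructed (e.g. nodule placement)."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and acquisition parameters of the phantom.

    Intensities live on [0, 1].  Defaults put the lung level (0.03) well
    below the pipeline's lung-extraction thresholds even after min–max
    normalization against the thorax level.
    """

    image_size: int = 128
    thorax_intensity: float = 0.8
    lung_intensity: float = 0.03
    nodule_intensity: float = 0.6
    n_nodules: int = 0
    nodule_radius_range: tuple[float, float] = (2.0, 4.0)
    malignant: bool = False
    junction_gap: int = 8
    noise_sigma: float = 0.0
    blur_length: int = 1
    blur_angle: float = 0.0
    n_phases: int = 1
    n_frames: int | None = None
    motion_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lung_intensity < self.thorax_intensity <= 1.0):
            raise ValueError("require 0 <= lung_intensity < thorax_intensity <= 1")
        if self.nodule_intensity <= self.lung_intensity:
            raise ValueError("nodule_intensity must exceed lung_intensity")
        if self.junction_gap < 0:
            raise ValueError("junction_gap must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")


@dataclass
class GroundTruth:
    """Reference segmentation and nodule list for a generated phantom.

    ``lung_mask`` labels: 0 background, 1 left lung, 2 right lung (viewer
    orientation).  ``nodule_centers`` holds (row, col, radius, is_malignant)
    tuples; every centre lies inside the lung mask.  ``junction_column`` is
    the column of the midline between the lung fields.  For 4-D phantoms
    ``phase_of_frame`` gives each frame's breathing bin and
    ``frame_truths`` the per-frame ground truth.
    """

    lung_mask: np.ndarray
    nodule_centers: list[tuple[int, int, float, bool]]
    junction_column: int
    phase_of_frame: np.ndarray | None = None
    frame_truths: list["GroundTruth"] | None = None


@dataclass
class Frame:
    """A rendered slice tagged with its breathing-signal value."""

    image: np.ndarray
    phase: float


def _ellipse_mask(size: int, center: tuple[float, float],
                  semi_axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    r0, c0 = center
    a, b = semi_axes  # row, col semi-axes
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _lung_geometry(cfg: PhantomConfig, row_offset: float = 0.0):
    """Thorax and lung ellipse masks at a given cranio-caudal offset."""
    s = cfg.image_size
    mid = s / 2.0
    thorax = _ellipse_mask(s, (mid, mid), (0.42 * s, 0.45 * s))
    lung_a = 0.28 * s           # row semi-axis
    lung_b = 0.16 * s           # col semi-axis
    if cfg.junction_gap > 0:
        dc = cfg.junction_gap / 2.0 + lung_b
    else:
        # merged-lung case: fields overlap across the midline; a thin
        # bright junction column is painted there at render time
        dc = lung_b - 2.0
    lr = mid + row_offset
    left = _ellipse_mask(s, (lr, mid - dc), (lung_a, lung_b))
    right = _ellipse_mask(s, (lr, mid + dc), (lung_a, lung_b))
    # lungs clipped to the thorax interior
    left &= thorax
    right &= thorax
    return thorax, left, right


def _render_nodule(canvas: np.ndarray, center: tuple[int, int], radius: float,
                   malignant: bool, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of one nodule; malignant blobs are larger and lumpy."""
    size = canvas.shape[0]
    rr, cc = np.mgrid[0:size, 0:size]
    r0, c0 = center
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    if malignant:
        # satellite lobes give an irregular, elongated outline
        for _ in range(3):
            ang = rng.uniform(0, 2 * np.pi)
            sr = r0 + 0.9 * radius * np.sin(ang)
            sc = c0 + 0.9 * radius * np.cos(ang)
            sat = (rr - sr) ** 2 + (cc - sc) ** 2 <= (0.6 * radius) ** 2
            mask |= sat
    return mask


def _place_nodules(cfg: PhantomConfig, lung_mask: np.ndarray,
                   rng: np.random.Generator):
    """Sample non-overlapping nodule centres strictly inside the lungs."""
    lo, hi = cfg.nodule_radius_range
    inside = lung_mask > 0
    dist = ndimage.distance_transform_edt(inside)
    centers: list[tuple[int, int, float, bool]] = []
    for _ in range(cfg.n_nodules):
        radius = float(rng.uniform(lo, hi))
        # keep nodules clear of the pleural boundary: the full blob extent
        # (satellite lobes reach 1.5r) plus the motion-blur smear, so the
        # rendered nodule stays an interior hole of the lung field even
        # after degradation
        margin = radius * (1.6 if cfg.malignant else 1.0) + cfg.blur_length + 2.0
        ok = np.argwhere(dist >= margin)
        placed = False
        for _attempt in range(100):
            if len(ok) == 0:
                break
            r, c = ok[rng.integers(len(ok))]
            if all((r - r2) ** 2 + (c - c2) ** 2 > (1.6 * (radius + rad2) + 2) ** 2
                   for r2, c2, rad2, _m in centers):
                centers.append((int(r), int(c), radius, cfg.malignant))
                placed = True
                break
        if not placed:
            raise PhantomError(
                f"could not place nodule of radius {radius:.1f}: lung fields too "
                f"small for {cfg.n_nodules} nodules at this size")
    return centers


def _render(cfg: PhantomConfig, rng: np.random.Generator,
            row_offset: float = 0.0,
            centers: list[tuple[int, int, float, bool]] | None = None):
    """Render one clean slice (no blur, no noise) and its ground truth."""
    thorax, left, right = _lung_geometry(cfg, row_offset)
    image = np.zeros((cfg.image_size, cfg.image_size))
    image[thorax] = cfg.thorax_intensity
    image[left | right] = cfg.lung_intensity

    lung_mask = np.zeros_like(image, dtype=np.int64)
    lung_mask[left] = 1
    lung_mask[right] = 2
    mid_col = cfg.image_size // 2
    if cfg.junction_gap == 0:
        # 1-px junction tissue column splits the ground-truth labels
        union_mid = (left | right)[:, mid_col]
        image[union_mid, mid_col] = cfg.thorax_intensity
        lung_mask[union_mid, mid_col] = 0
        lung_mask[:, :mid_col][lung_mask[:, :mid_col] > 0] = 1
        lung_mask[:, mid_col + 1:][lung_mask[:, mid_col + 1:] > 0] = 2

    if centers is None:
        centers = _place_nodules(cfg, lung_mask, rng) if cfg.n_nodules else []
    for r, c, radius, malignant in centers:
        blob = _render_nodule(image, (r, c), radius, malignant, rng)
        blob &= lung_mask > 0
        image[blob] = cfg.nodule_intensity

    gt = GroundTruth(lung_mask=lung_mask, nodule_centers=list(centers),
                     junction_column=cfg.image_size // 2)
    return image, gt


def generate_slice(config: PhantomConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate one clean 2-D phantom slice with ground truth.

    The output is the piecewise-constant reference image F: blur and noise
    are *not* applied here (see :func:`apply_degradation`).  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    return _render(config, rng)


def _breathing_signal(n_frames: int) -> np.ndarray:
    """One cycle of a normalized sinusoidal breathing signal in [0, 1]."""
    t = np.arange(n_frames) / n_frames
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def generate_4d(config: PhantomConfig) -> tuple[list[Frame], GroundTruth]:
    """Generate a breathing sequence of tagged frames plus ground truth.

    Each frame is tagged with its breathing-signal value; the lungs are
    displaced cranio-caudally by ``motion_amplitude · p/(n_phases−1)``
    where p is the frame's phase bin, so every bin has an exact reference
    position.  The returned GroundTruth carries ``phase_of_frame`` and
    per-frame ``frame_truths``.
    """
    if config.n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    n_frames = config.n_frames or 4 * config.n_phases
    rng = np.random.default_rng(config.seed)
    signal = _breathing_signal(n_frames)
    if config.n_phases == 1:
        bins = np.zeros(n_frames, dtype=int)
    else:
        edges = np.linspace(0.0, 1.0, config.n_phases + 1)
        bins = np.clip(np.digitize(signal, edges[1:-1]), 0, config.n_phases - 1)

    # nodules placed once, in the reference (zero-displacement) frame
    _, ref_gt = _render(config, np.random.default_rng(config.seed))

    frames: list[Frame] = []
    truths: list[GroundTruth] = []
    for k in range(n_frames):
        if config.n_phases == 1:
            offset = 0.0
        else:
            offset = config.motion_amplitude * bins[k] / (config.n_phases - 1)
        shifted = [(int(round(r + offset)), c, rad, m)
                   for r, c, rad, m in ref_gt.nodule_centers]
        image, gt = _render(config, rng, row_offset=offset, centers=shifted)
        frames.append(Frame(image=image, phase=float(signal[k])))
        truths.append(gt)

    gt4 = GroundTruth(lung_mask=ref_gt.lung_mask,
                      nodule_centers=ref_gt.nodule_centers,
                      junction_column=ref_gt.junction_column,
                      phase_of_frame=bins, frame_truths=truths)
    return frames, gt4


def sort_by_phase(frames: Sequence[Frame], n_bins: int) -> dict[int, list[Frame]]:
    """Retrospectively sort tagged frames into breathing-phase bins.

    The signal range observed across the input is split into ``n_bins``
    equal-width bins; each frame goes to exactly one bin (the partition is
    lossless).  A degenerate signal (all tags equal) puts every frame in
    bin 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    for f in frames:
        if f.phase is None:
            raise ValueError("every frame must carry a breathing-signal tag")
    tags = np.array([f.phase for f in frames], dtype=float)
    out: dict[int, list[Frame]] = {b: [] for b in range(n_bins)}
    if len(frames) == 0:
        return out
    lo, hi = tags.min(), tags.max()
    if hi == lo:
        out[0] = list(frames)
        return out
    idx = np.minimum(((tags - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    for f, b in zip(frames, idx):
        out[int(b)].append(f)
    return out


def apply_degradation(image: np.ndarray, blur: BlurSpec, noise_sigma: float = 0.0,
                      seed: int | None = None, clip: bool = True) -> np.ndarray:
    """Degrade a clean slice: circular blur, then additive Gaussian noise.

    Clipping to [0, 1] is applied last; pass ``clip=False`` to inspect the
    raw noise statistics.
    """
    from .preprocess import blur_forward

    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    out = blur_forward(image, blur)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out
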