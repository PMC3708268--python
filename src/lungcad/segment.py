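"""Lung-field extraction from normalized CT slices.

Lungs are radiolucent: on a [0,1]-normalized slice they are *dark*
regions inside the brighter thorax, so all thresholding here takes
foreground = pixels BELOW the threshold.  The stock global thresholds
are 0.05555 for 2-D slices and 0.0678 for 4-D frames, interpreted on
min–max-normalized intensity.

:func:`lung_mask` composes the standard cleanup: threshold, discard
components touching the image border (the air surrounding the body is as
dark as lung), fill holes (vessels/nodules are bright islands inside the
lung field), and keep at most the two largest components.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage

__all__ = [
    "THRESHOLD_2D",
    "THRESHOLD_4D",
    "global_threshold",
    "adaptive_threshold",
    "region_grow",
    "connected_components",
    "lung_mask",
]

THRESHOLD_2D = 0.05555
THRESHOLD_4D = 0.0678

_STRUCT8 = np.ones((3, 3), dtype=bool)


def global_threshold(image: np.ndarray, t: float = THRESHOLD_2D) -> np.ndarray:
    """Binary mask of pixels strictly below the global threshold ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    image = np.asarray(image, dtype=float)
    return (image < t).astype(np.int64)


def adaptive_threshold(image: np.ndarray, window: int = 15,
                       offset: float = 0.0) -> np.ndarray:
    """Locally adaptive threshold: foreground iff below (local mean − offset).

    ``window`` is the odd side length of the square mean filter (reflective
    boundary).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    image = np.asarray(image, dtype=float)
    local_mean = ndimage.uniform_filter(image, size=window, mode="reflect")
    return (image < local_mean - offset).astype(np.int64)


def region_grow(image: np.ndarray, seeds, tolerance: float) -> np.ndarray:
    """Seeded region growing with a running-mean homogeneity criterion.

    Each seed grows a 4-connected region, absorbing neighbours whose
    intensity differs from the region's running mean by at most
    ``tolerance``.  Seeds are processed in order; a pixel claimed by an
    earlier seed's region is never reassigned (first-seed priority).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    image = np.asarray(image, dtype=float)
    labels = np.zeros(image.shape, dtype=np.int64)
    h, w = image.shape
    for idx, (sr, sc) in enumerate(seeds, start=1):
        if not (0 <= sr < h and 0 <= sc < w):
            raise ValueError(f"seed ({sr}, {sc}) out of bounds for shape {image.shape}")
        if labels[sr, sc] != 0:
            continue
        labels[sr, sc] = idx
        total = image[sr, sc]
        count = 1
        queue = deque([(sr, sc)])
        while queue:
            r, c = queue.popleft()
            mean = total / count
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < h and 0 <= nc < w and labels[nr, nc] == 0:
                    # 1e-12 slack absorbs round-off in the running mean so
                    # tolerance 0 still floods exactly-constant regions
                    if abs(image[nr, nc] - mean) <= tolerance + 1e-12:
                        labels[nr, nc] = idx
                        total += image[nr, nc]
                        count += 1
                        queue.append((nr, nc))
    return labels


def connected_components(mask: np.ndarray) -> np.ndarray:
    """8-connected labeling with labels ordered by decreasing component size.

    Ties in size keep the scan order of scipy's labeling, so the result is
    deterministic.
    """
    mask = np.asarray(mask) > 0
    raw, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int64)
    sizes = np.bincount(raw.ravel())[1:]
    order = np.argsort(-sizes, kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[order] = np.arange(1, n + 1)
    return remap[raw]


def lung_mask(image: np.ndarray, t: float = THRESHOLD_2D) -> np.ndarray:
    """Cleaned binary lung mask from a normalized slice.

    Pipeline: global threshold → remove border-touching components →
    fill holes → keep the (up to) two largest components.  Returns an
    empty mask if nothing survives.
    """
    binary = global_threshold(image, t) > 0
    labeled, n = ndimage.label(binary, structure=_STRUCT8)
    if n == 0:
        return np.zeros(binary.shape, dtype=np.int64)
    border_labels = np.unique(np.concatenate([
        labeled[0, :], labeled[-1, :], labeled[:, 0], labeled[:, -1]]))
    keep = np.ones(n + 1, dtype=bool)
    keep[border_labels] = False
    keep[0] = False
    binary = keep[labeled]
    binary = ndimage.binary_fill_holes(binary)
    comps = connected_components(binary)
    return ((comps == 1) | (comps == 2)).astype(np.int64)
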