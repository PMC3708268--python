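"""Left/right lung separation via a maximum-cost junction path.

On some slices the two lung fields merge across the anterior junction
into one connected component.  The junction tissue is brighter than
lung parenchyma, so the junction line is recovered as the top-to-bottom
3-connected path maximizing the sum of traversed gray levels (dynamic
programming), restricted to a per-row column search region.  Because the
junction position drifts slowly through a volume, each slice's search
region can be centred on the previous slice's path (±``half_width``
columns); without a previous path the middle third of the mask bounding
box is used.

After cutting the mask along the path, a conditional dilation restores
the approximate original boundary without ever reconnecting the two
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segment import connected_components

__all__ = [
    "JunctionPath",
    "SeparationResult",
    "LungSeparationError",
    "max_cost_path",
    "needs_separation",
    "separate_lungs",
    "conditional_dilate",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class LungSeparationError(RuntimeError):
    """Raised when the junction cut fails to produce two components."""


@dataclass
class JunctionPath:
    """A 3-connected top-to-bottom column path with its accumulated cost.

    ``cols[k]`` is the column at row ``row_start + k``; successive columns
    differ by at most 1.
    """

    cols: np.ndarray
    total_cost: float
    row_start: int = 0

    @property
    def rows(self) -> np.ndarray:
        return self.row_start + np.arange(len(self.cols))


def _full_region(weights: np.ndarray) -> np.ndarray:
    n_rows, n_cols = weights.shape
    return np.tile([0, n_cols - 1], (n_rows, 1))


def max_cost_path(weights: np.ndarray, region: np.ndarray | None = None) -> JunctionPath:
    """Maximum-cost 3-connected top-to-bottom path through a weight grid.

    ``region`` is an (n_rows, 2) array of inclusive [c_lo, c_hi] column
    bounds per row (None = full width).  DP recurrence
    S(r,c) = w(r,c) + max{S(r−1,c−1), S(r−1,c), S(r−1,c+1)} over admissible
    parents; ties break toward the smaller column in both the recurrence
    and the backtrace, so the result is deterministic.
    """
    weights = np.asarray(weights, dtype=float)
    n_rows, n_cols = weights.shape
    region = _full_region(weights) if region is None else np.asarray(region, dtype=int)
    if region.shape != (n_rows, 2):
        raise ValueError("region must give [c_lo, c_hi] for every row")
    for r, (lo, hi) in enumerate(region):
        if lo > hi or lo < 0 or hi >= n_cols:
            raise ValueError(f"empty or out-of-range search region at row {r}")

    NEG = -np.inf
    score = np.full((n_rows, n_cols), NEG)
    parent = np.full((n_rows, n_cols), -1, dtype=int)
    lo, hi = region[0]
    score[0, lo:hi + 1] = weights[0, lo:hi + 1]
    for r in range(1, n_rows):
        lo, hi = region[r]
        plo, phi = region[r - 1]
        for c in range(lo, hi + 1):
            best, barg = NEG, -1
            for pc in (c - 1, c, c + 1):  # smaller column first -> tie rule
                if plo <= pc <= phi and score[r - 1, pc] > best:
                    best, barg = score[r - 1, pc], pc
            if barg >= 0:
                score[r, c] = best + weights[r, c]
                parent[r, c] = barg
    lo, hi = region[-1]
    last_scores = score[-1, lo:hi + 1]
    if np.all(np.isneginf(last_scores)):
        raise ValueError("no admissible path through the search region")
    end = lo + int(np.argmax(last_scores))  # argmax takes first max -> smaller col
    cols = np.empty(n_rows, dtype=int)
    cols[-1] = end
    for r in range(n_rows - 1, 0, -1):
        cols[r - 1] = parent[r, cols[r]]
    return JunctionPath(cols=cols, total_cost=float(score[-1, end]))


def needs_separation(mask: np.ndarray, min_fraction: float = 0.1) -> bool:
    """True iff the mask is one single component covering ≥ min_fraction of the image."""
    comps = connected_components(mask)
    n = comps.max()
    if n != 1:
        return False
    area = int((comps == 1).sum())
    return area >= min_fraction * mask.size


@dataclass
class SeparationResult:
    """Labeled lungs (0 background, 1 left, 2 right) plus the junction path used."""

    labels: np.ndarray
    path: JunctionPath | None = None


def _label_left_right(binary: np.ndarray) -> np.ndarray:
    """Assign the (up to two) largest components labels 1/2 by centroid column."""
    comps = connected_components(binary)
    n = int(comps.max())
    out = np.zeros_like(comps)
    if n == 0:
        return out
    ids = list(range(1, min(n, 2) + 1))
    cents = {i: ndimage.center_of_mass(comps == i)[1] for i in ids}
    if len(ids) == 1:
        # single lung: pick the side its centroid falls on (viewer's left = 1)
        side = 1 if cents[1] < binary.shape[1] / 2 else 2
        out[comps == 1] = side
        return out
    left_id = min(ids, key=lambda i: cents[i])
    right_id = max(ids, key=lambda i: cents[i])
    out[comps == left_id] = 1
    out[comps == right_id] = 2
    return out


def _search_region(mask: np.ndarray, rows: np.ndarray,
                   prev_path: JunctionPath | None, half_width: int) -> np.ndarray:
    n_cols = mask.shape[1]
    cols_any = np.where(mask.any(axis=0))[0]
    c0, c1 = cols_any[0], cols_any[-1]
    region = np.empty((len(rows), 2), dtype=int)
    if prev_path is not None:
        prev = dict(zip(prev_path.rows, prev_path.cols))
        mid_default = (c0 + c1) // 2
        for k, r in enumerate(rows):
            c = prev.get(int(r), mid_default)
            region[k] = (max(0, c - half_width), min(n_cols - 1, c + half_width))
    else:
        third = (c1 - c0 + 1) // 3
        lo, hi = c0 + third, c1 - third
        region[:] = (max(0, lo), min(n_cols - 1, max(lo, hi)))
    return region


def _cut_along(work: np.ndarray, path: JunctionPath) -> None:
    """Zero the mask along the path, widened at diagonal steps.

    Under 8-connectivity a 1-px path leaks across its own diagonal steps,
    so at each column change the next row's previous column is cleared too.
    """
    rows, cols = path.rows, path.cols
    work[rows, cols] = False
    steps = np.where(np.diff(cols) != 0)[0]
    work[rows[steps + 1], cols[steps]] = False


def separate_lungs(mask: np.ndarray, image: np.ndarray,
                   prev_path: JunctionPath | None = None,
                   min_fraction: float = 0.1, half_width: int = 10,
                   max_erosions: int = 5) -> SeparationResult:
    """Split a merged lung mask into left/right labels.

    When the mask is a single large component, the junction line is found
    by :func:`max_cost_path` on the image gray levels (junction tissue is
    brighter than lung) and the mask is cut along it; if the cut alone
    does not disconnect the lungs, up to ``max_erosions`` binary erosions
    are applied as a fallback.  Already-separate masks are labeled
    directly by centroid column.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty lung mask")
    if not needs_separation(mask, min_fraction):
        return SeparationResult(labels=_label_left_right(mask))

    rows_any = np.where(mask.any(axis=1))[0]
    r0, r1 = rows_any[0], rows_any[-1]
    rows = np.arange(r0, r1 + 1)
    region = _search_region(mask, rows, prev_path, half_width)
    sub = np.asarray(image, dtype=float)[r0:r1 + 1]
    path = max_cost_path(sub, region)
    path = JunctionPath(cols=path.cols, total_cost=path.total_cost, row_start=int(r0))

    # a genuine junction line is tissue, distinctly brighter than the lung
    # parenchyma; a maximum-cost path through dark pixels means the single
    # component is one lung, not two merged ones — label it directly
    image_f = np.asarray(image, dtype=float)
    med_path = float(np.median(image_f[path.rows, path.cols]))
    med_mask = float(np.median(image_f[mask]))
    if med_path < med_mask + 0.1:
        return SeparationResult(labels=_label_left_right(mask))

    work = mask.copy()
    _cut_along(work, path)
    eroded = 0
    while int(connected_components(work).max()) < 2 and eroded < max_erosions:
        work = ndimage.binary_erosion(work)
        _cut_along(work, path)
        eroded += 1
    n = int(connected_components(work).max())
    if n < 2:
        raise LungSeparationError(
            f"junction cut failed: {n} component(s) after path cut and "
            f"{eroded} erosion(s); path cost {path.total_cost:.3f}")
    return SeparationResult(labels=_label_left_right(work), path=path)


def conditional_dilate(separated: np.ndarray, original: np.ndarray,
                       iterations: int) -> np.ndarray:
    """Dilate each lung label inside the original mask without reconnecting.

    Per iteration, a pixel joins a label only if it belongs to the
    original mask and adding it creates no 8-adjacency between labels 1
    and 2.  Label 1 is grown before label 2 within an iteration (a fixed,
    documented priority that keeps the result deterministic).
    """
    labels = np.asarray(separated).copy()
    original = np.asarray(original) > 0
    if np.any((labels > 0) & ~original):
        raise ValueError("separated mask must be a subset of the original mask")
    for _ in range(iterations):
        changed = False
        for lab, other in ((1, 2), (2, 1)):
            grow = ndimage.binary_dilation(labels == lab, structure=_STRUCT8)
            near_other = ndimage.binary_dilation(labels == other, structure=_STRUCT8)
            add = grow & original & (labels == 0) & ~near_other
            if add.any():
                labels[add] = lab
                changed = True
        if not changed:
            break
    return labels
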