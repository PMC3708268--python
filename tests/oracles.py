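"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive enumeration, flood
fill, union-find — and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_path_max(weights: np.ndarray, region: np.ndarray | None = None):
    """Exhaustive maximum over all 3-connected top-to-bottom column paths.

    Returns (best_cost, best_cols) with ties resolved to the
    lexicographically smallest column sequence.
    """
    weights = np.asarray(weights, dtype=float)
    n_rows, n_cols = weights.shape
    if region is None:
        region = np.tile([0, n_cols - 1], (n_rows, 1))
    best_cost, best_cols = -np.inf, None

    def admissible(r, c):
        return region[r][0] <= c <= region[r][1]

    def recurse(r, c, cost, cols):
        nonlocal best_cost, best_cols
        if r == n_rows - 1:
            if cost > best_cost or (cost == best_cost and cols < best_cols):
                best_cost, best_cols = cost, list(cols)
            return
        for nc in (c - 1, c, c + 1):
            if 0 <= nc < n_cols and admissible(r + 1, nc):
                recurse(r + 1, nc, cost + weights[r + 1, nc], cols + [nc])

    for c in range(n_cols):
        if admissible(0, c):
            recurse(0, c, weights[0, c], [c])
    return best_cost, best_cols


def hmm_likelihood_enumeration(pi, A, B, obs) -> float:
    """P(O) as an explicit sum over every hidden state path."""
    pi, A, B = map(np.asarray, (pi, A, B))
    N, T = len(pi), len(obs)
    total = 0.0
    for path in itertools.product(range(N), repeat=T):
        p = pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        total += p
    return total


def hmm_state_posterior_enumeration(pi, A, B, obs) -> np.ndarray:
    """P(q_t = i | O) for all t, i, by path enumeration."""
    pi, A, B = map(np.asarray, (pi, A, B))
    N, T = len(pi), len(obs)
    post = np.zeros((T, N))
    total = 0.0
    for path in itertools.product(range(N), repeat=T):
        p = pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        total += p
        for t, i in enumerate(path):
            post[t, i] += p
    return post / total


def hmm_transition_posterior_enumeration(pi, A, B, obs) -> np.ndarray:
    """Sum_t P(q_t = i, q_{t+1} = j | O) by path enumeration."""
    pi, A, B = map(np.asarray, (pi, A, B))
    N, T = len(pi), len(obs)
    xi = np.zeros((N, N))
    total = 0.0
    for path in itertools.product(range(N), repeat=T):
        p = pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        total += p
        for t in range(T - 1):
            xi[path[t], path[t + 1]] += p
    return xi / total


def flood_fill(image: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """4-connected flood fill of the exact-equal-value region at seed."""
    image = np.asarray(image)
    target = image[seed]
    mask = np.zeros(image.shape, dtype=bool)
    stack = [seed]
    mask[seed] = True
    h, w = image.shape
    while stack:
        r, c = stack.pop()
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc] \
                    and image[nr, nc] == target:
                mask[nr, nc] = True
                stack.append((nr, nc))
    return mask


def count_components_union_find(mask: np.ndarray) -> int:
    """8-connected component count via a plain union-find."""
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                parent[(r, c)] = (r, c)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                    union((r, c), (nr, nc))
    return len({find(x) for x in parent})


def local_mean_brute(image: np.ndarray, window: int) -> np.ndarray:
    """Windowed mean with reflective boundary, computed pixel by pixel."""
    image = np.asarray(image, dtype=float)
    pad = window // 2
    padded = np.pad(image, pad, mode="reflect")
    out = np.zeros_like(image)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = padded[r:r + window, c:c + window].mean()
    return out


def perimeter_edges_brute(mask: np.ndarray) -> int:
    """Count exposed pixel edges by checking each pixel's 4 sides."""
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= nr < h and 0 <= nc < w) or not mask[nr, nc]:
                    count += 1
    return count


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
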