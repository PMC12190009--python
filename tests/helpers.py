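"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations (and vectorised
shortcuts): plain loops over candidate thresholds, breadth-first flood
fill, direct numerical integration.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_force_renyi_threshold(hist: np.ndarray, alpha: float) -> int:
    """Exhaustive 256-candidate maximisation of summed class Renyi entropies."""
    p = np.asarray(hist, dtype=float)
    p = p / p.sum()
    best_t, best_val = None, -math.inf
    for t in range(256):
        pb = p[: t + 1]
        pf = p[t + 1 :]
        Pb, Pf = pb.sum(), pf.sum()
        if Pb <= 1e-12 or Pf <= 1e-12:
            continue
        def renyi(q, P):
            q = q[q > 0] / P
            if abs(alpha - 1.0) < 1e-12:
                return -float(np.sum(q * np.log(q)))
            return float(np.log(np.sum(q**alpha)) / (1.0 - alpha))
        val = renyi(pb, Pb) + renyi(pf, Pf)
        if val > best_val + 1e-12:  # strict: ties keep the lower level
            best_val, best_t = val, t
    return best_t


def shannon_threshold(hist: np.ndarray) -> int:
    """Kapur maximum-entropy threshold, written out long-hand."""
    return brute_force_renyi_threshold(hist, 1.0)


def flood_fill_component_count(
    binary: np.ndarray, connectivity: int
) -> int:
    """Count connected components of a 3D boolean volume by BFS."""
    assert binary.ndim == 3 and connectivity in (6, 26)
    if connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    visited = np.zeros_like(binary, dtype=bool)
    shape = binary.shape
    count = 0
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        count += 1
        queue = deque([start])
        visited[start] = True
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and binary[nz, ny, nx]
                    and not visited[nz, ny, nx]
                ):
                    visited[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return count


def numeric_profile_extent(
    gap_fn, span: float, cutoff: float, step: float = 0.01
) -> float:
    """Fine-grid measure of {x in [0, span]: gap(x) <= cutoff}."""
    x = np.arange(0.0, span, step)
    return float(np.count_nonzero(gap_fn(x) <= cutoff) * step)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.count_nonzero(a & b) / denom if denom else 1.0
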