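"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain nested loops over matrix cells or runs,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

# Neighbor walk shared with the package contract: start at the preceding-time
# corner (i-1, j-1) and circle the center; bit n-1 has weight 2^(n-1).
OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def naive_distance_matrix(points: np.ndarray) -> np.ndarray:
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.sqrt(sum((a - b) ** 2 for a, b in zip(points[i], points[j])))
    return out


def naive_lbp(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    out = np.zeros((n - 2, n - 2), dtype=int)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            g0 = matrix[i, j]
            code = 0
            for bit, (di, dj) in enumerate(OFFSETS):
                if matrix[i + di, j + dj] >= g0:
                    code += 2**bit
            out[i - 1, j - 1] = code
    return out


def naive_recurrence_rate(binary: np.ndarray) -> float:
    count = 0
    for row in binary:
        for cell in row:
            count += int(cell)
    return count / binary.size


def naive_diagonal_runs(binary: np.ndarray, include_loi: bool) -> list[int]:
    """Lengths of all maximal diagonal runs of 1s, both triangles."""
    n_rows, n_cols = binary.shape
    runs = []
    for k in range(-(n_rows - 1), n_cols):
        if k == 0 and not include_loi:
            continue
        cells = []
        for i in range(n_rows):
            j = i + k
            if 0 <= j < n_cols:
                cells.append(int(binary[i, j]))
        runs.extend(_runs_in(cells))
    return runs


def naive_vertical_runs(binary: np.ndarray) -> list[int]:
    runs = []
    for j in range(binary.shape[1]):
        runs.extend(_runs_in([int(v) for v in binary[:, j]]))
    return runs


def _runs_in(cells: list[int]) -> list[int]:
    runs, current = [], 0
    for c in cells:
        if c:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def naive_rqa(binary: np.ndarray, l_min: int = 2, v_min: int = 2) -> dict[str, float]:
    """All nine recurrence statistics from explicit run scans."""
    diag = naive_diagonal_runs(binary, include_loi=False)
    vert = naive_vertical_runs(binary)
    long_d = [l for l in diag if l >= l_min]
    long_v = [v for v in vert if v >= v_min]
    total_d = sum(diag)
    total_v = sum(vert)
    n_l = len(long_d)
    probs = [long_d.count(l) / n_l for l in sorted(set(long_d))]
    ent = -sum(p * math.log(p) for p in probs) if n_l else 0.0
    max_d = max(long_d) if long_d else 0.0
    return {
        "rr": naive_recurrence_rate(binary),
        "det": sum(long_d) / total_d if total_d else 0.0,
        "mean_diag_l": sum(long_d) / n_l if n_l else 0.0,
        "max_diag_l": max_d,
        "div": 1.0 / max_d if max_d else 0.0,
        "ent": ent,
        "lam": sum(long_v) / total_v if total_v else 0.0,
        "tt": sum(long_v) / len(long_v) if long_v else 0.0,
        "max_vert_l": max(long_v) if long_v else 0.0,
    }


def random_symmetric_distances(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric matrix with zero diagonal (distance-matrix shaped)."""
    m = rng.uniform(0.1, 10.0, size=(n, n))
    m = np.triu(m, 1)
    return m + m.T
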