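"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (python loops, direct formulas)
and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_glcm(labels: np.ndarray, n_levels: int, offsets) -> np.ndarray:
    """Pooled symmetric co-occurrence probabilities via explicit loops."""
    pooled = np.zeros((n_levels, n_levels))
    used = 0
    nx, ny, nz = labels.shape
    for dx, dy, dz in offsets:
        counts = np.zeros((n_levels, n_levels))
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    a = labels[x, y, z]
                    if a == 0:
                        continue
                    X, Y, Z = x + dx, y + dy, z + dz
                    if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                        b = labels[X, Y, Z]
                        if b > 0:
                            counts[a - 1, b - 1] += 1
                            counts[b - 1, a - 1] += 1
        if counts.sum() > 0:
            pooled += counts / counts.sum()
            used += 1
    return pooled / used


def brute_runs(labels: np.ndarray, offsets) -> list[tuple[int, int]]:
    """All (gray level, run length) runs over the given directions."""
    nx, ny, nz = labels.shape
    runs = []
    for d in offsets:
        starts = []
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    px, py, pz = x - d[0], y - d[1], z - d[2]
                    if not (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz):
                        starts.append((x, y, z))
        for sx, sy, sz in starts:
            x, y, z = sx, sy, sz
            cur, length = 0, 0
            while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                v = labels[x, y, z]
                if v == cur:
                    length += 1
                else:
                    if cur > 0:
                        runs.append((cur, length))
                    cur, length = v, 1
                x, y, z = x + d[0], y + d[1], z + d[2]
            if cur > 0:
                runs.append((cur, length))
    return runs


def brute_zones(labels: np.ndarray) -> list[tuple[int, int]]:
    """(gray level, zone size) via explicit 26-connected flood fill."""
    visited = np.zeros(labels.shape, dtype=bool)
    nx, ny, nz = labels.shape
    zones = []
    neigh = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if labels[x, y, z] == 0 or visited[x, y, z]:
                    continue
                level = labels[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        X, Y, Z = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz
                            and not visited[X, Y, Z]
                            and labels[X, Y, Z] == level
                        ):
                            visited[X, Y, Z] = True
                            stack.append((X, Y, Z))
                zones.append((int(level), size))
    return zones


def brute_logrank(t1, e1, t2, e2) -> float:
    """Two-group log-rank chi-square via the observed-minus-expected sums."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        e1_t = d * n1 / n
        o_minus_e += d1 - e1_t
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def brute_cindex(marker, time, event) -> float:
    """Concordance by exhaustive ordered-pair enumeration."""
    marker, time, event = map(np.asarray, (marker, time, event))
    num = den = 0.0
    n = len(marker)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if marker[i] > marker[j]:
                    num += 1
                elif marker[i] == marker[j]:
                    num += 0.5
    return num / den


def brute_auc_at_horizon(marker, time, event, horizon) -> float:
    """Empirical case/control ROC AUC at a horizon (no censoring!)."""
    marker, time, event = map(np.asarray, (marker, time, event))
    cases = marker[(time <= horizon) & (event == 1)]
    controls = marker[time > horizon]
    num = 0.0
    for m in cases:
        for c in controls:
            num += 1.0 if m > c else (0.5 if m == c else 0.0)
    return num / (len(cases) * len(controls))


def brute_net_benefit(pred, is_event, threshold) -> float:
    """Confusion-matrix net benefit for known event status."""
    pred, is_event = np.asarray(pred), np.asarray(is_event, bool)
    n = len(pred)
    pos = pred >= threshold
    tp = np.sum(pos & is_event)
    fp = np.sum(pos & ~is_event)
    return tp / n - fp / n * threshold / (1 - threshold)
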