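"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the slowest, most literal formulation of
each definition (per-candidate scans, flood fill, full enumeration, explicit
double loops) so they stay independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


# ---------------------------------------------------------------------------
# Otsu oracle: scan every candidate threshold, compute class stats directly.

def otsu_oracle(block: np.ndarray) -> float:
    """Between-class-variance scan over midpoints of consecutive observed levels."""
    v = np.asarray(block, dtype=float).ravel()
    levels = np.unique(v)
    assert levels.size >= 2
    best_t, best_var = None, -1.0
    for lo, hi in zip(levels[:-1], levels[1:]):
        t = (lo + hi) / 2.0
        bg = v[v <= t]
        fg = v[v > t]
        w0, w1 = bg.size / v.size, fg.size / v.size
        var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        # strict improvement beyond fp round-off -> ties keep the lowest t
        if var > best_var * (1.0 + 1e-9):
            best_var, best_t = var, t
    return best_t


# ---------------------------------------------------------------------------
# Connected-component oracle: breadth-first flood fill.

def flood_fill_components(binary: np.ndarray, connectivity: int = 8):
    """Return (component count, sorted component areas) by explicit flood fill."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary)
    areas = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                area = 0
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    cr, cc = q.popleft()
                    area += 1
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
                areas.append(area)
    return len(areas), sorted(areas)


# ---------------------------------------------------------------------------
# GLCM + Haralick oracle: explicit double loop over pixel positions.

def glcm_oracle(q: np.ndarray, dx: int, dy: int, levels: int, symmetric: bool) -> np.ndarray:
    q = np.asarray(q)
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def haralick_oracle(p: np.ndarray) -> dict[str, float]:
    L = p.shape[0]
    energy = contrast = homogeneity = 0.0
    for i in range(L):
        for j in range(L):
            energy += p[i, j] ** 2
            contrast += (i - j) ** 2 * p[i, j]
            homogeneity += p[i, j] / (1 + (i - j) ** 2)
    return {"energy": energy, "contrast": contrast, "homogeneity": homogeneity}


# ---------------------------------------------------------------------------
# Mann-Whitney oracle: full enumeration over all rank labellings (tie-free).

def mwu_oracle(x, y):
    """(U for x, exact two-sided p) by enumerating all C(n+m, n) labellings."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    u_obs = sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                for xi in x for yj in y)
    combined = sorted(x + y)
    us = []
    for positions in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in positions]
        ys = [combined[i] for i in range(n + m) if i not in positions]
        us.append(sum(1.0 if a > b else 0.5 if a == b else 0.0
                      for a in xs for b in ys))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Leading singular value by power iteration on M^T M.

def leading_singular_value_oracle(m: np.ndarray, iters: int = 2000) -> float:
    m = np.asarray(m, dtype=float)
    g = m.T @ m
    v = np.ones(g.shape[0]) / math.sqrt(g.shape[0])
    for _ in range(iters):
        nv = g @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return 0.0
        v = nv / norm
    return math.sqrt(float(v @ g @ v))


# ---------------------------------------------------------------------------
# Small deterministic synthetic dataset on disk, shared across tests.

@pytest.fixture(scope="session")
def preset_dataset(tmp_path_factory):
    import stedtex as st

    d = tmp_path_factory.mktemp("preset_dataset")
    labels = st.generate_group_dataset(st.control_spec(), st.invasive_spec(),
                                       n_images_per_group=3, seed=42, out_dir=d)
    return d, labels


@pytest.fixture(scope="session")
def preset_features(preset_dataset):
    import stedtex as st

    d, _ = preset_dataset
    cfg = st.PipelineConfig(stats=st.StatsConfig(seed=7, n_boot=2000))
    table = st.run_extract(d / "labels.csv", cfg, d / "features.csv")
    return table, cfg, d
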