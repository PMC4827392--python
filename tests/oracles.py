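"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — nested loops, dense matrices,
textbook iterations — and shares no code with the package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# textbook NIPALS PLS2
# ---------------------------------------------------------------------------

def nipals_pls2(X: np.ndarray, Y: np.ndarray, m: int, max_iter: int = 1000,
                tol: float = 1e-14) -> dict:
    """Power-iteration NIPALS for two blocks, x-score deflation of both.

    Blocks must already be centered.  Returns the factor lists plus the
    training-data prediction ``T diag(b) Cᵀ`` built purely from the scores.
    """
    Xr, Yr = X.copy().astype(float), Y.copy().astype(float)
    Ws, Cs, Ps, Ts, bs = [], [], [], [], []
    for _ in range(m):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            w /= np.linalg.norm(w)
            t = Xr @ w
            c = Yr.T @ t
            c /= np.linalg.norm(c)
            u = Yr @ c
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        p = Xr.T @ t / tt
        q = Yr.T @ t / tt
        bs.append((t @ u) / tt)
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, q)
        Ws.append(w); Cs.append(c); Ps.append(p); Ts.append(t)
    T = np.column_stack(Ts)
    C = np.column_stack(Cs)
    return {
        "W": np.column_stack(Ws),
        "C": C,
        "P": np.column_stack(Ps),
        "T": T,
        "b": np.asarray(bs),
        "Y_hat_train": (T * np.asarray(bs)) @ C.T,
    }


# ---------------------------------------------------------------------------
# dense-SVD PLS with deflation
# ---------------------------------------------------------------------------

def dense_svd_pls(Xc: np.ndarray, Yc: np.ndarray, m: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leading singular pairs of the explicitly formed cross-covariance,
    deflating both blocks on the x-score between components."""
    Xr, Yr = Xc.copy().astype(float), Yc.copy().astype(float)
    pairs = []
    for _ in range(m):
        U, _, Vt = np.linalg.svd(Xr.T @ Yr)
        w, c = U[:, 0], Vt[0]
        t = Xr @ w
        tt = t @ t
        Xr = Xr - np.outer(t, Xr.T @ t / tt)
        Yr = Yr - np.outer(t, Yr.T @ t / tt)
        pairs.append((w, c))
    return pairs


# ---------------------------------------------------------------------------
# exhaustive nearest-patch search
# ---------------------------------------------------------------------------

def brute_force_patch(
    qvol: np.ndarray,
    atlas_x: np.ndarray,
    atlas_y: np.ndarray,
    side: int,
    radius: int = 0,
    aggregate: str = "center",
) -> np.ndarray:
    """Per-voxel exhaustive search over (atlas, offset) candidates.

    Distance is the SSD over patch positions lying inside the grid for both
    the query and the (offset) atlas window; candidates are visited in
    (atlas index, lexicographic offset) order and ties keep the first.
    """
    grid = qvol.shape
    ndim = len(grid)
    h = side // 2
    offsets = list(itertools.product(*[range(-radius, radius + 1)] * ndim))
    window = list(itertools.product(*[range(-h, h + 1)] * ndim))

    def inside(v):
        return all(0 <= x < g for x, g in zip(v, grid))

    out = np.zeros(grid)
    for v in np.ndindex(grid):
        best = np.inf
        best_y = 0.0
        for j in range(atlas_x.shape[0]):
            for off in offsets:
                vo = tuple(a + b for a, b in zip(v, off))
                if not inside(vo):
                    continue
                d = 0.0
                ys = []
                for p in window:
                    vp = tuple(a + b for a, b in zip(v, p))
                    vop = tuple(a + b for a, b in zip(vo, p))
                    if inside(vp) and inside(vop):
                        d += (qvol[vp] - atlas_x[j][vop]) ** 2
                        ys.append(atlas_y[j][vop])
                yval = atlas_y[j][vo] if aggregate == "center" else float(np.mean(ys))
                if d < best:
                    best = d
                    best_y = yval
        out[v] = best_y
    return out


# ---------------------------------------------------------------------------
# AUC by exhaustive pair counting
# ---------------------------------------------------------------------------

def pair_count_auc(values: np.ndarray, is_pos: np.ndarray) -> float:
    pos = np.asarray(values)[np.asarray(is_pos, bool)]
    neg = np.asarray(values)[~np.asarray(is_pos, bool)]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# strongest-first matching via a sorted pair list
# ---------------------------------------------------------------------------

def sorted_pair_matching(corr: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Accept pairs in descending |correlation| order while both sides are free."""
    order = sorted(
        ((abs(corr[i, j]), i, j) for i in range(corr.shape[0]) for j in range(corr.shape[1])),
        reverse=True,
    )
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for a, i, j in order:
        if a <= threshold:
            break
        if i in used_i or j in used_j:
            continue
        pairs.append((i, j, corr[i, j]))
        used_i.add(i)
        used_j.add(j)
    return pairs


# ---------------------------------------------------------------------------
# BFS flood fill, faces-only connectivity
# ---------------------------------------------------------------------------

def flood_fill_label(binary: np.ndarray) -> tuple[np.ndarray, int]:
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    neighbors = []
    for ax in range(binary.ndim):
        for step in (-1, 1):
            d = [0] * binary.ndim
            d[ax] = step
            neighbors.append(tuple(d))
    for start in np.ndindex(binary.shape):
        if not binary[start] or labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            v = stack.pop()
            for d in neighbors:
                nb = tuple(a + b for a, b in zip(v, d))
                if all(0 <= x < g for x, g in zip(nb, binary.shape)):
                    if binary[nb] and not labels[nb]:
                        labels[nb] = current
                        stack.append(nb)
    return labels, current
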