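"""Independent, loop-based reference implementations used only by tests.

Everything here is written directly from the defining formulas (explicit
convolution loops, finite differences, exhaustive scans, combinatorial
sums) and never calls the package's own computational paths.
"""

import math

import numpy as np

# ---------------------------------------------------------------------------
# tiny-network forward pieces (explicit loops)


def conv3x3_loop(x, w, b):
    """x: (C, H, W); w: (O, C, 3, 3); zero padding 1, stride 1."""
    c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    out = np.zeros((o, h, wd))
    for k in range(o):
        for i in range(h):
            for j in range(wd):
                acc = b[k]
                for cc in range(c):
                    for di in range(3):
                        for dj in range(3):
                            acc += w[k, cc, di, dj] * xp[cc, i + di, j + dj]
                out[k, i, j] = acc
    return out


def relu_loop(x):
    return np.where(x > 0, x, 0.0)


def fd_grad(f, a, eps=1e-4):
    """Central finite-difference gradient of scalar f at array a."""
    g = np.zeros_like(a, dtype=float)
    it = np.nditer(a, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        ap = a.copy()
        ap[idx] += eps
        am = a.copy()
        am[idx] -= eps
        g[idx] = (f(ap) - f(am)) / (2 * eps)
        it.iternext()
    return g


def grad_cam_oracle(feature_map, score_of_map):
    """Grad-CAM from its definition: channel weights are spatial means of
    the score gradient w.r.t. the map; output is the ReLU'd weighted sum."""
    grads = fd_grad(score_of_map, feature_map)
    weights = grads.mean(axis=(1, 2))
    cam = np.zeros(feature_map.shape[1:])
    for k in range(feature_map.shape[0]):
        cam += weights[k] * feature_map[k]
    return np.maximum(cam, 0.0)


# ---------------------------------------------------------------------------
# geometry


def contour_distance_oracle(mask):
    """Normalized contour distance by exhaustive all-pairs search: for every
    in-mask pixel, the minimum Euclidean distance to any background pixel,
    divided by the maximum such distance over the mask."""
    h, w = mask.shape
    bg = np.argwhere(~mask)
    d = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                d[i, j] = np.min(np.hypot(bg[:, 0] - i, bg[:, 1] - j))
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def best_window_oracle(values, mask, side, minimize=False, centre=None,
                       min_sep=None):
    """Exhaustive scan over all fully-interior square windows."""
    h, w = mask.shape
    best = None
    for r0 in range(h - side + 1):
        for c0 in range(w - side + 1):
            if not mask[r0 : r0 + side, c0 : c0 + side].all():
                continue
            if centre is not None:
                cr, cc = r0 + (side - 1) / 2, c0 + (side - 1) / 2
                if np.hypot(cr - centre[0], cc - centre[1]) < min_sep:
                    continue
            m = values[r0 : r0 + side, c0 : c0 + side].mean()
            key = (m if minimize else -m, r0, c0)
            if best is None or key < best[0]:
                best = (key, (r0, c0, m))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# ensemble


def threshold_search_oracle(conf_a, conf_b, y, min_prec):
    """Exhaustive enumeration over the same grid contract: thresholds are
    observed confidences >= 0.5 plus 0.5 itself, AND-combined."""
    grid_a = sorted(set([0.5] + [c for c in conf_a if c >= 0.5]))
    grid_b = sorted(set([0.5] + [c for c in conf_b if c >= 0.5]))
    best = None
    for ta in grid_a:
        for tb in grid_b:
            call = (conf_a >= ta) & (conf_b >= tb)
            acc = float((call == (y == 1)).mean())
            if call.sum() == 0:
                continue
            prec = float((y[call] == 1).mean())
            if prec < min_prec:
                continue
            key = (-acc, -prec, ta, tb)
            if best is None or key < best[0]:
                best = (key, (ta, tb, acc, prec))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_tail_oracle(k, n_universe, n_set, n_draw):
    """P(X >= k) by direct combinatorial summation."""
    total = 0.0
    for x in range(k, min(n_set, n_draw) + 1):
        total += (math.comb(n_set, x) * math.comb(n_universe - n_set, n_draw - x)
                  / math.comb(n_universe, n_draw))
    return min(total, 1.0)
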