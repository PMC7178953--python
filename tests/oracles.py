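"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — O(nm) distance scans, explicit
neighbour checks, a pure-python monotone-chain hull with point-in-polygon
rasterization, and direct double-sum convolution — so it shares no code
path with the package implementations it checks.
"""

import numpy as np


def brute_contour(mask):
    """Foreground pixels with >= 1 background 4-neighbour (explicit scan)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    pts.append((r, c))
                    break
    return np.array(pts, dtype=float)


def _all_pairs(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def brute_mad(a, b):
    d = _all_pairs(a, b)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def brute_hausdorff(a, b):
    d = _all_pairs(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_yasnoff(a, b, w):
    d = _all_pairs(a, b)
    return 100.0 / w * np.sqrt((d.min(axis=1) ** 2).sum())


def brute_dsc(x, y):
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    return 2.0 * np.sum(x & y) / (np.sum(x) + np.sum(y))


def monotone_chain_hull(points):
    """Convex hull vertices (counter-clockwise) of 2-D points, pure python."""
    pts = sorted({(float(p[0]), float(p[1])) for p in points})
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def brute_hull_mask(mask):
    """Rasterized filled convex hull: pixel centres inside (or on) the hull
    polygon of the foreground pixel centres."""
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    hull = monotone_chain_hull(pts)
    h, w = mask.shape
    out = np.zeros_like(mask)
    if len(hull) <= 2:
        return mask.copy()
    for r in range(h):
        for c in range(w):
            inside = True
            for i in range(len(hull)):
                o, a = hull[i], hull[(i + 1) % len(hull)]
                cr = (a[0] - o[0]) * (c - o[1]) - (a[1] - o[1]) * (r - o[0])
                if cr < -1e-9:
                    inside = False
                    break
            if inside:
                out[r, c] = True
    return out


def brute_chd(mask):
    a = brute_contour(mask)
    c = brute_contour(brute_hull_mask(mask))
    return brute_hausdorff(a, c)


def direct_conv2d(x, w, dilation=1):
    """Direct evaluation of (F *_l k)(p) = sum_{s + l t = p} F(s) k(t) on one
    channel pair, with zero padding r*l so the output keeps the input shape."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    k = w.shape[0]
    r = k // 2
    h, ww = x.shape
    out = np.zeros_like(x)
    for pr in range(h):
        for pc in range(ww):
            acc = 0.0
            for ti in range(-r, r + 1):
                for tj in range(-r, r + 1):
                    sr = pr - dilation * ti
                    sc = pc - dilation * tj
                    if 0 <= sr < h and 0 <= sc < ww:
                        acc += x[sr, sc] * w[ti + r, tj + r]
            out[pr, pc] = acc
    return out


def random_blob_mask(rng, shape, n_blobs=(1, 3), radius=(2, 8)):
    """A random nonempty union of filled discs, for oracle sweeps."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(n_blobs[0], n_blobs[1] + 1)):
        r0 = rng.uniform(0, h - 1)
        c0 = rng.uniform(0, w - 1)
        rad = rng.uniform(*radius)
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask
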