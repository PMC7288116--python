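"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(explicit loops, closed forms, exhaustive search), deliberately sharing no
code with the implementation it checks.
"""

import math

import numpy as np

# ---- vegetation index scalar formulas -------------------------------------

def scalar_index(name, gre, red, nir):
    if name == "NG":
        return gre / (nir + red + gre)
    if name == "NR":
        return red / (nir + red + gre)
    if name == "NDVI":
        return (nir - red) / (nir + red)
    if name == "GNDVI":
        return (nir - gre) / (nir + gre)
    if name == "DVI":
        return nir - red
    if name == "CIG":
        return nir / gre - 1.0
    if name == "OSAVI":
        return 1.16 * (nir - red) / (nir + red + 0.16)
    if name == "RDVI":
        return (nir - red) / math.sqrt(nir + red)
    if name == "NLI":
        return (nir**2 - red) / (nir**2 + red)
    if name == "WDRVI":
        return (0.2 * nir - red) / (0.2 * nir + red)
    raise ValueError(name)


# ---- kernel smoothing ------------------------------------------------------

def brute_force_gaussian_smooth(raw, h):
    """Reflect-padded normalized Gaussian convolution by explicit sums,
    with the same truncation rule as scipy's gaussian_filter1d."""
    raw = np.asarray(raw, dtype=np.float64)
    radius = int(4.0 * h + 0.5)
    x = np.arange(-radius, radius + 1)
    kern = np.exp(-0.5 * (x / h) ** 2)
    kern /= kern.sum()
    # scipy 'reflect' = symmetric half-sample padding.
    padded = np.concatenate([raw[radius - 1::-1] if radius else raw[:0],
                             raw, raw[:-radius - 1:-1] if radius else raw[:0]])
    out = np.empty_like(raw)
    for i in range(len(raw)):
        out[i] = float(np.dot(padded[i:i + 2 * radius + 1], kern[::-1]))
    return out


# ---- convex hull area ------------------------------------------------------

def gift_wrap_hull(points):
    """Jarvis march convex hull, CCW vertex order."""
    pts = [tuple(p) for p in np.asarray(points, dtype=np.float64)]
    pts = sorted(set(pts))
    if len(pts) < 3:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1 % len(pts)]
        for p in pts:
            if p == current:
                continue
            c = cross(current, candidate, p)
            if c < 0 or (
                c == 0
                and (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
                > (candidate[0] - current[0]) ** 2 + (candidate[1] - current[1]) ** 2
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    return hull


def hull_area_oracle(points):
    """Hull area by triangle fan over the gift-wrapped hull."""
    hull = gift_wrap_hull(points)
    if len(hull) < 3:
        return 0.0
    x0, y0 = hull[0]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull[1:-1], hull[2:]):
        area += 0.5 * abs((x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0))
    return area


# ---- GLCM and texture ------------------------------------------------------

def glcm_oracle(patch, levels, offsets):
    """Ordered pair counting by explicit python loops."""
    q = [[min(int(v) * levels // 256, levels - 1) for v in row] for row in patch]
    m, n = len(q), len(q[0])
    counts = np.zeros((levels, levels))
    for dy, dx in offsets:
        for i in range(m):
            for j in range(n):
                i2, j2 = i + dy, j + dx
                if 0 <= i2 < m and 0 <= j2 < n:
                    counts[q[i][j]][q[i2][j2]] += 1
    return counts / counts.sum()


def texture_oracle(p):
    """CON/COR/ASM/INM by explicit double loops."""
    N = p.shape[0]
    CON = ASM = INM = 0.0
    mu_i = mu_j = 0.0
    for i in range(N):
        for j in range(N):
            CON += abs(i - j) ** 2 * p[i, j]
            ASM += p[i, j] ** 2
            INM += p[i, j] / (1 + abs(i - j))
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(N):
        for j in range(N):
            var_i += p[i, j] * (i - mu_i) ** 2
            var_j += p[i, j] * (j - mu_j) ** 2
            cov += i * j * p[i, j]
    if var_i * var_j == 0:
        COR = 0.0
    else:
        COR = (cov - mu_i * mu_j) / math.sqrt(var_i * var_j)
    return CON, COR, ASM, INM


def moments_oracle(patch):
    vals = [float(v) for row in np.atleast_2d(patch) for v in row]
    n = len(vals)
    mu = sum(vals) / n
    m2 = sum((v - mu) ** 2 for v in vals) / n
    m3 = sum((v - mu) ** 3 for v in vals) / n
    s = math.copysign(abs(m3) ** (1 / 3), m3) if m3 else 0.0
    return mu, math.sqrt(m2), s


# ---- detection scoring -----------------------------------------------------

def containment_score_oracle(windows, centers):
    """C and E per exhaustive center-in-cell counting."""
    nc = ne = 0
    for x0, x1, y0, y1 in windows:
        k = sum(1 for (x, y) in centers if x0 <= x < x1 and y0 <= y < y1)
        if k == 1:
            nc += 1
        else:
            ne += 1
    n = len(windows)
    return 100.0 * nc / n, 100.0 * ne / n
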