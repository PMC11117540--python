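"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops with textbook formulas (Heron's
area, perpendicular-bisector circumcentres, shapely half-plane clipping for
the octagon, direct DFT sums for the transform) so it shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

import math
import statistics
from fractions import Fraction

import numpy as np
from shapely.geometry import Polygon


# --------------------------------------------------------------------------
# direct O(N^2) evaluation of the fast-FrFT stage loop and coefficient sum

def direct_frft(x, alpha: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    big_k = complex(math.cos(-math.pi * alpha / 2), math.sin(-math.pi * alpha / 2))
    y = [complex(v) for v in x]
    n_stages = int(round(math.log2(n)))
    for k in range(1, n_stages + 1):
        filt = [
            (m + 1) / 2 * np.exp(1j * math.pi * alpha * (m - n / 2) ** 2 / 2**k)
            for m in range(n)
        ]
        v = [y[m] * filt[m] for m in range(n)]
        z = [
            sum(v[m] * np.exp(-2j * math.pi * m * q / n) for m in range(n))
            for q in range(n)
        ]
        scale = big_k ** (2 ** (k - 1))
        z = [zq * scale for zq in z]
        y = [
            sum(z[q] * np.exp(2j * math.pi * m * q / n) for q in range(n)) / n
            for m in range(n)
        ]
    coeffs = [
        sum(
            y[m]
            * np.exp(-1j * math.pi * alpha * (m - n / 2) ** 2 / n)
            * np.exp(-2j * math.pi * m * k / n)
            for m in range(n)
        )
        / n
        for k in range(n)
    ]
    return np.asarray(coeffs)


def direct_stage_filter(y, k: int, alpha: float) -> np.ndarray:
    y = [complex(v) for v in np.asarray(y)]
    n = len(y)
    big_k = complex(math.cos(-math.pi * alpha / 2), math.sin(-math.pi * alpha / 2))
    filt = [
        (m + 1) / 2 * np.exp(1j * math.pi * alpha * (m - n / 2) ** 2 / 2**k)
        for m in range(n)
    ]
    v = [y[m] * filt[m] for m in range(n)]
    z = [
        sum(v[m] * np.exp(-2j * math.pi * m * q / n) for m in range(n))
        for q in range(n)
    ]
    scale = big_k ** (2 ** (k - 1))
    return np.asarray(
        [
            sum(z[q] * scale * np.exp(2j * math.pi * m * q / n) for q in range(n)) / n
            for m in range(n)
        ]
    )


# --------------------------------------------------------------------------
# geometric features, one loop-based function each

def _dist(a, b) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def bf_scca(pts) -> float:
    return sum(
        math.pi * (_dist(pts[i], pts[i + 1]) / 2) ** 2 for i in range(len(pts) - 1)
    )


def _tri_area(a, b, c) -> float:
    return abs(
        (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    ) / 2


def bf_scta(pts) -> float:
    return sum(_tri_area(pts[i], pts[i + 1], pts[i + 2]) for i in range(len(pts) - 2))


def _heron_area(a, b, c) -> float:
    # Kahan's numerically stable ordering of Heron's formula
    sa, sb, sc = sorted([_dist(b, c), _dist(a, c), _dist(a, b)], reverse=True)
    val = (sa + (sb + sc)) * (sc - (sa - sb)) * (sc + (sa - sb)) * (sa + (sb - sc))
    return math.sqrt(max(val, 0.0)) / 4


def _circumcentre(a, b, c):
    # solve |C-a|^2 = |C-b|^2 and |C-a|^2 = |C-c|^2
    mat = np.array(
        [[2 * (b[0] - a[0]), 2 * (b[1] - a[1])],
         [2 * (c[0] - a[0]), 2 * (c[1] - a[1])]]
    )
    rhs = np.array(
        [b[0] ** 2 - a[0] ** 2 + b[1] ** 2 - a[1] ** 2,
         c[0] ** 2 - a[0] ** 2 + c[1] ** 2 - a[1] ** 2]
    )
    return np.linalg.solve(mat, rhs)


def _angle_at(mid, p, q) -> float:
    u = (p[0] - mid[0], p[1] - mid[1])
    v = (q[0] - mid[0], q[1] - mid[1])
    nu, nv = math.hypot(*u), math.hypot(*v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    return math.acos(min(1.0, max(-1.0, cosang)))


def bf_heron(pts):
    # exact rational arithmetic: float coordinates convert losslessly to
    # Fraction, so areas, squared radii and circumcentres are exact and the
    # comparison measures only the implementation's rounding
    scale = max(max(abs(x), abs(y)) for x, y in pts)
    cutoff = Fraction(1e-12 * max(scale, 1.0) ** 2)
    radii_sq, centres = [], []
    for i in range(len(pts) - 2):
        a, b, c = [
            (Fraction(p[0]), Fraction(p[1])) for p in (pts[i], pts[i + 1], pts[i + 2])
        ]
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area2) / 2 < cutoff:
            continue
        la2 = (c[0] - b[0]) ** 2 + (c[1] - b[1]) ** 2
        lb2 = (c[0] - a[0]) ** 2 + (c[1] - a[1]) ** 2
        lc2 = (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2
        radii_sq.append(la2 * lb2 * lc2 / (4 * area2**2))
        # circumcentre: exact solution of the perpendicular-bisector system
        m11, m12 = 2 * (b[0] - a[0]), 2 * (b[1] - a[1])
        m21, m22 = 2 * (c[0] - a[0]), 2 * (c[1] - a[1])
        r1 = b[0] ** 2 - a[0] ** 2 + b[1] ** 2 - a[1] ** 2
        r2 = c[0] ** 2 - a[0] ** 2 + c[1] ** 2 - a[1] ** 2
        det = m11 * m22 - m12 * m21
        centres.append(((m22 * r1 - m12 * r2) / det, (m11 * r2 - m21 * r1) / det))
    shca = sum(math.pi * float(r2) for r2 in radii_sq)
    sdhc = sum(
        math.sqrt(
            float(
                (centres[i + 1][0] - centres[i][0]) ** 2
                + (centres[i + 1][1] - centres[i][1]) ** 2
            )
        )
        for i in range(len(centres) - 1)
    )
    floats = [(float(cx), float(cy)) for cx, cy in centres]
    sahc = sum(
        _angle_at(floats[i + 1], floats[i], floats[i + 2])
        for i in range(len(floats) - 2)
    )
    return shca, sdhc, sahc


def bf_ssvl(pts) -> float:
    return sum(_dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1))


def bf_sh45(pts) -> float:
    return sum(abs(x - y) / math.sqrt(2) for x, y in pts)


def bf_sh135(pts) -> float:
    return sum(abs(x + y) / math.sqrt(2) for x, y in pts)


def bf_aoct(pts) -> float:
    if len(pts) < 2:
        return 0.0
    big = 10 * max(1.0, max(max(abs(x), abs(y)) for x, y in pts))
    region = Polygon(
        [(-big, -big), (big, -big), (big, big), (-big, big)]
    )
    for j in range(8):
        th = j * math.pi / 4
        nx, ny = math.cos(th), math.sin(th)
        h = max(x * nx + y * ny for x, y in pts)
        # half-plane {p . n <= h} as a huge rectangle behind the boundary line
        px, py = -ny, nx  # direction along the boundary
        c = (h * nx, h * ny)
        half = Polygon(
            [
                (c[0] + big * px, c[1] + big * py),
                (c[0] - big * px, c[1] - big * py),
                (c[0] - big * px - 2 * big * nx, c[1] - big * py - 2 * big * ny),
                (c[0] + big * px - 2 * big * nx, c[1] + big * py - 2 * big * ny),
            ]
        )
        region = region.intersection(half)
    return region.area


def bf_sdtc(pts) -> float:
    return sum(math.hypot(x, y) for x, y in pts)


def bf_satp(pts) -> float:
    total = 0.0
    for i in range(len(pts) - 2):
        a, mid, c = pts[i], pts[i + 1], pts[i + 2]
        if _dist(a, mid) == 0 or _dist(c, mid) == 0:
            continue
        total += _angle_at(mid, a, c)
    return total


def bf_tacr(pts) -> float:
    o = (0.0, 0.0)
    return sum(_tri_area(o, pts[i], pts[i + 1]) for i in range(len(pts) - 1))


def bf_scra(pts) -> float:
    return sum(
        (abs(x - y) / math.sqrt(2)) * (abs(x + y) / math.sqrt(2)) for x, y in pts
    )


def bf_tdsd(pts) -> float:
    if len(pts) < 2:
        return 0.0
    along = [(x + y) / math.sqrt(2) for x, y in pts]
    across = [(y - x) / math.sqrt(2) for x, y in pts]
    return statistics.stdev(across) + statistics.stdev(along)


def bf_elpa(pts) -> float:
    if len(pts) < 2:
        return 0.0
    n = len(pts)
    mx = sum(x for x, _ in pts) / n
    my = sum(y for _, y in pts) / n
    sxx = sum((x - mx) ** 2 for x, _ in pts) / (n - 1)
    syy = sum((y - my) ** 2 for _, y in pts) / (n - 1)
    sxy = sum((x - mx) * (y - my) for x, y in pts) / (n - 1)
    # eigenvalues of [[sxx, sxy], [sxy, syy]] by the quadratic formula
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = math.sqrt(max(tr**2 / 4 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    return math.pi * math.sqrt(max(l1, 0.0) * max(l2, 0.0))


def bf_ctm(pts) -> list[float]:
    r = [math.hypot(x, y) for x, y in pts]
    rmax = max(r)
    if rmax == 0:
        return [1.0] * 19
    return [
        sum(1 for ri in r if ri <= k / 20 * rmax) / len(r) for k in range(1, 20)
    ]


def bf_all_features(pts) -> np.ndarray:
    pts = [tuple(p) for p in np.asarray(pts, dtype=float)]
    shca, sdhc, sahc = bf_heron(pts)
    head = [
        bf_scca(pts), bf_scta(pts), shca, sdhc, sahc, bf_ssvl(pts),
        bf_sh45(pts), bf_sh135(pts), bf_aoct(pts), bf_sdtc(pts),
        bf_satp(pts), bf_tacr(pts), bf_scra(pts), bf_tdsd(pts), bf_elpa(pts),
    ]
    return np.asarray(head + bf_ctm(pts))
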