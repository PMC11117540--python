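"""Geometric features of an ordered 2D point cloud.

Thirty-four descriptors of the fast-FrFT scatter, grouped by what they read
off the cloud:

* sequence geometry along the coefficient order — circle/triangle areas over
  consecutive points (SCCA, SCTA), circumcircle ("Heron's circular") area,
  centre spacing and centre turning angles (SHCA, SDHC, SAHC), polyline
  length (SSVL), turning angles (SATP), triangle areas against the origin
  (TACR);
* dispersion of the point *set* — distances to the 45 and 135 degree
  diagonals (SH45, SH135), bounding-octagon area (AOCT), radial distance sum
  (SDTC), per-point diagonal rectangles (SCRA), Poincare-style SD1+SD2
  dispersion (TDSD), fitted-ellipse area (ELPA);
* concentration — 19 central tendency measures CTM1..CTM19, the fraction of
  points inside circles of radius (k/20)*r_max around the origin.

All features are deterministic, finite for finite input, and follow simple
equivariances: lengths scale linearly, areas quadratically, angles and CTM
fractions are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "consecutive_circle_area",
    "consecutive_triangle_area",
    "circumcircle_features",
    "polyline_length",
    "diagonal_distance_sums",
    "octagon_area",
    "radial_distance_sum",
    "turning_angle_sum",
    "origin_triangle_area",
    "rectangle_area_sum",
    "poincare_dispersion",
    "ellipse_area",
    "central_tendency_measures",
    "extract_features",
]

#: Canonical order of the 34 features (CSV header order).
FEATURE_NAMES: tuple[str, ...] = (
    "SCCA", "SCTA", "SHCA", "SDHC", "SAHC", "SSVL", "SH45", "SH135",
    "AOCT", "SDTC", "SATP", "TACR", "SCRA", "TDSD", "ELPA",
) + tuple(f"CTM{i}" for i in range(1, 20))

#: Per-feature behaviour under uniform scaling of the cloud: exponent of s.
SCALE_DEGREE: dict[str, int] = {
    **{n: 2 for n in ("SCCA", "SCTA", "SHCA", "AOCT", "TACR", "SCRA", "ELPA")},
    **{n: 1 for n in ("SDHC", "SSVL", "SH45", "SH135", "SDTC", "TDSD")},
    **{n: 0 for n in ("SAHC", "SATP")},
    **{f"CTM{i}": 0 for i in range(1, 20)},
}

_DEGENERATE_AREA_REL = 1e-12  # triangle-area cutoff, relative to scale^2


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2D vectors."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


@dataclass
class FeatureMatrix:
    """Stacked feature vectors with binary class labels."""

    X: np.ndarray  # (m, n_features)
    y: np.ndarray  # (m,) labels encoded 0/1
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes are inconsistent")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaN")

    @property
    def m(self) -> int:
        return self.X.shape[0]


def _as_points(points) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must have shape (N, 2)")
    if p.shape[0] == 0:
        raise ValueError("empty point cloud")
    if not np.isfinite(p).all():
        raise ValueError("points must be finite")
    return p


def consecutive_circle_area(points) -> float:
    """SCCA: sum of areas of circles whose diameters join consecutive points."""
    p = _as_points(points)
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return float(np.sum(np.pi * (d / 2.0) ** 2))


def consecutive_triangle_area(points) -> float:
    """SCTA: sum of triangle areas over consecutive point triples."""
    p = _as_points(points)
    if len(p) < 3:
        return 0.0
    u = p[1:-1] - p[:-2]
    v = p[2:] - p[:-2]
    return float(np.sum(np.abs(_cross2(u, v)) / 2.0))


def _circumcircles(p: np.ndarray):
    """Circumradius and circumcentre per consecutive triple; degenerate triples dropped."""
    a, b, c = p[:-2], p[1:-1], p[2:]
    area2 = _cross2(b - a, c - a)  # signed, = 2*area
    scale = max(float(np.abs(p).max()), 1.0)
    ok = np.abs(area2) / 2.0 >= _DEGENERATE_AREA_REL * scale**2
    a, b, c, area2 = a[ok], b[ok], c[ok], area2[ok]
    la = np.linalg.norm(c - b, axis=1)
    lb = np.linalg.norm(c - a, axis=1)
    lc = np.linalg.norm(b - a, axis=1)
    r = la * lb * lc / (2.0 * np.abs(area2))
    # circumcentre from the perpendicular-bisector solution
    d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1])
               + c[:, 0] * (a[:, 1] - b[:, 1]))
    sa = np.einsum("ij,ij->i", a, a)
    sb = np.einsum("ij,ij->i", b, b)
    sc = np.einsum("ij,ij->i", c, c)
    ux = (sa * (b[:, 1] - c[:, 1]) + sb * (c[:, 1] - a[:, 1]) + sc * (a[:, 1] - b[:, 1])) / d
    uy = (sa * (c[:, 0] - b[:, 0]) + sb * (a[:, 0] - c[:, 0]) + sc * (b[:, 0] - a[:, 0])) / d
    return r, np.column_stack([ux, uy])


def circumcircle_features(points) -> tuple[float, float, float]:
    """(SHCA, SDHC, SAHC): circumcircle areas, centre spacings, centre turning angles.

    Each consecutive point triple defines a circumscribed circle (radius via
    R = abc/4A with A from Heron's formula); near-collinear triples are
    skipped. SHCA sums pi*R^2, SDHC sums distances between successive
    centres, SAHC sums the interior angle at each middle centre of three
    successive centres.
    """
    p = _as_points(points)
    if len(p) < 3:
        return 0.0, 0.0, 0.0
    r, centres = _circumcircles(p)
    shca = float(np.sum(np.pi * r**2))
    sdhc = float(np.sum(np.linalg.norm(np.diff(centres, axis=0), axis=1))) if len(centres) >= 2 else 0.0
    sahc = _turning_angles(centres) if len(centres) >= 3 else 0.0
    return shca, sdhc, sahc


def polyline_length(points) -> float:
    """SSVL: total length of the polyline through the points in order."""
    p = _as_points(points)
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def diagonal_distance_sums(points) -> tuple[float, float]:
    """(SH45, SH135): summed perpendicular distances to the lines y=x and y=-x."""
    p = _as_points(points)
    sh45 = float(np.sum(np.abs(p[:, 0] - p[:, 1])) / np.sqrt(2.0))
    sh135 = float(np.sum(np.abs(p[:, 0] + p[:, 1])) / np.sqrt(2.0))
    return sh45, sh135


def octagon_area(points) -> float:
    """AOCT: area of the smallest enclosing octagon with sides at 45-degree steps.

    The octagon is the intersection of eight half-planes whose outward
    normals point at angles j*45 degrees; each boundary line sits at the
    cloud's support value in that direction. Adjacent boundary lines are
    intersected to get the vertices and the area follows by the shoelace
    formula. Inactive diagonal constraints simply reproduce the bounding
    box corners.
    """
    p = _as_points(points)
    if len(p) < 2:
        return 0.0
    theta = np.arange(8) * (np.pi / 4.0)
    normals = np.column_stack([np.cos(theta), np.sin(theta)])
    h = (p @ normals.T).max(axis=0)  # support values
    verts = []
    for j in range(8):
        jn = (j + 1) % 8
        a = np.array([normals[j], normals[jn]])
        v = np.linalg.solve(a, np.array([h[j], h[jn]]))
        verts.append(v)
    v = np.asarray(verts)
    x, y = v[:, 0], v[:, 1]
    return float(np.abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def radial_distance_sum(points, center=(0.0, 0.0)) -> float:
    """SDTC: sum of distances from each point to the coordinate centre."""
    p = _as_points(points)
    return float(np.sum(np.linalg.norm(p - np.asarray(center, dtype=float), axis=1)))


def _turning_angles(p: np.ndarray) -> float:
    """Sum of interior angles at the middle point of consecutive triples, in [0, pi]."""
    u = p[:-2] - p[1:-1]
    v = p[2:] - p[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    if not ok.any():
        return 0.0
    cosang = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    return float(np.sum(np.arccos(np.clip(cosang, -1.0, 1.0))))


def turning_angle_sum(points) -> float:
    """SATP: summed angle at the middle point of each consecutive triple."""
    p = _as_points(points)
    if len(p) < 3:
        return 0.0
    return _turning_angles(p)


def origin_triangle_area(points, center=(0.0, 0.0)) -> float:
    """TACR: sum of triangle areas spanned by consecutive point pairs and the centre."""
    p = _as_points(points) - np.asarray(center, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.sum(np.abs(_cross2(p[:-1], p[1:])) / 2.0))


def rectangle_area_sum(points) -> float:
    """SCRA: per-point rectangle areas with sides equal to the two diagonal distances."""
    p = _as_points(points)
    return float(np.sum(np.abs(p[:, 0] - p[:, 1]) * np.abs(p[:, 0] + p[:, 1])) / 2.0)


def poincare_dispersion(points) -> float:
    """TDSD: SD1 + SD2, sample standard deviations across and along the identity line."""
    p = _as_points(points)
    if len(p) < 2:
        return 0.0
    along = (p[:, 0] + p[:, 1]) / np.sqrt(2.0)
    across = (p[:, 1] - p[:, 0]) / np.sqrt(2.0)
    return float(np.std(across, ddof=1) + np.std(along, ddof=1))


def ellipse_area(points) -> float:
    """ELPA: area of the covariance ellipse, pi * sqrt(lambda1 * lambda2)."""
    p = _as_points(points)
    if len(p) < 2:
        return 0.0
    cov = np.cov(p, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    return float(np.pi * np.sqrt(max(det, 0.0)))


def central_tendency_measures(points, center=(0.0, 0.0)) -> np.ndarray:
    """CTM1..CTM19: fraction of points within radius (k/20)*r_max of the centre.

    A cloud collapsed onto the centre (r_max = 0) is maximally concentrated:
    all 19 values are 1.
    """
    p = _as_points(points)
    r = np.linalg.norm(p - np.asarray(center, dtype=float), axis=1)
    r_max = r.max()
    if r_max == 0.0:
        return np.ones(19)
    rho = np.arange(1, 20) / 20.0 * r_max
    return (r[None, :] <= rho[:, None]).mean(axis=1)


def extract_features(points, center: str = "origin") -> np.ndarray:
    """Compute the full 34-feature vector for one ordered point cloud.

    Parameters
    ----------
    points : array-like, shape (N, 2)
        Ordered (Re, Im) coefficient pairs; N >= 1.
    center : {"origin", "centroid"}
        Reference centre for the radial features (SDTC, TACR, CTMs). The
        default is the coordinate origin; "centroid" recentres on the
        cloud mean.

    Returns
    -------
    ndarray, shape (34,)
        Values in ``FEATURE_NAMES`` order.
    """
    p = _as_points(points)
    if center == "origin":
        ctr = (0.0, 0.0)
    elif center == "centroid":
        ctr = tuple(p.mean(axis=0))
    else:
        raise ValueError(f"unknown center {center!r}")
    shca, sdhc, sahc = circumcircle_features(p)
    sh45, sh135 = diagonal_distance_sums(p)
    vals = [
        consecutive_circle_area(p),
        consecutive_triangle_area(p),
        shca, sdhc, sahc,
        polyline_length(p),
        sh45, sh135,
        octagon_area(p),
        radial_distance_sum(p, ctr),
        turning_angle_sum(p),
        origin_triangle_area(p, ctr),
        rectangle_area_sum(p),
        poincare_dispersion(p),
        ellipse_area(p),
    ]
    return np.concatenate([np.asarray(vals, dtype=float),
                           central_tendency_measures(p, ctr)])
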