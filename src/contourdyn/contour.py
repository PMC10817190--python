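"""Smooth closed-contour representation via periodic Gaussian process regression.

A segmented cell outline arrives as an ordered polygon of points in the image
plane (micrometers).  We turn it into a smooth, periodic curve
``Phi(theta) = (x(theta), y(theta))``, ``theta in [0, 2*pi)``, by fitting two
independent GPs (one per coordinate) whose covariance on the circle is the
Poisson kernel

    k_r(theta, theta') = (1 - r^2) / (1 - 2 r cos(theta - theta') + r^2),

plus i.i.d. observation noise ``sigma_noise^2``.  The radius ``r`` controls
rigidity (Fourier mode m is shrunk like ``r^|m|``), so large ``r`` keeps fine
detail and small ``r`` smooths aggressively.  After fitting, the curve is
re-parametrized by normalized arc length, and N virtual markers are placed
equidistantly along the contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GPRConfig",
    "ContourSamples",
    "SmoothContour",
    "GeometryBundle",
    "fit_contour",
    "geometry",
    "vmdr",
    "poisson_kernel",
    "circle_samples",
    "SelfIntersectionWarning",
]

TWO_PI = 2.0 * np.pi


class SelfIntersectionWarning(UserWarning):
    """Fitted contour polygon crosses itself (tolerated, transient)."""


@dataclass(frozen=True)
class GPRConfig:
    """Hyperparameters of the periodic contour regression.

    r_cont : Poisson-kernel radius in [0, 1); larger keeps more detail.
    sigma_noise : observation noise scale (dimensionless, applied to the
        coordinates in um); the allowed deviation between the raw
        segmentation points and the fitted curve.
    jitter : diagonal conditioning term added to the covariance.
    """

    r_cont: float = 0.6
    sigma_noise: float = 0.05
    jitter: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_cont < 1.0):
            raise ValueError(f"r_cont must be in [0, 1), got {self.r_cont}")
        if self.sigma_noise <= 0.0:
            raise ValueError(f"sigma_noise must be > 0, got {self.sigma_noise}")


@dataclass(frozen=True)
class ContourSamples:
    """Ordered planar points (um) interpreted as a closed polygon."""

    points: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (M, 2)")
        if pts.shape[0] < 4:
            raise ValueError("need at least 4 contour points")
        object.__setattr__(self, "points", pts)


def poisson_kernel(delta: np.ndarray, r: float) -> np.ndarray:
    """Un-normalized Poisson kernel k_r as a function of the angle difference."""
    denom = 1.0 - 2.0 * r * np.cos(delta) + r * r
    return (1.0 - r * r) / denom


def _poisson_kernel_d1(delta: np.ndarray, r: float) -> np.ndarray:
    denom = 1.0 - 2.0 * r * np.cos(delta) + r * r
    return -(1.0 - r * r) * 2.0 * r * np.sin(delta) / denom**2


def _poisson_kernel_d2(delta: np.ndarray, r: float) -> np.ndarray:
    denom = 1.0 - 2.0 * r * np.cos(delta) + r * r
    s, c = np.sin(delta), np.cos(delta)
    return (1.0 - r * r) * (8.0 * r * r * s * s / denom**3 - 2.0 * r * c / denom**2)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _chord_length_theta(pts: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord length of the closed polygon, in [0, 2*pi)."""
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    if np.any(seg[:-1] == 0.0):
        raise ValueError("consecutive contour points must be distinct")
    total = seg.sum()
    if total == 0.0:
        raise ValueError("degenerate contour: all points coincide")
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return TWO_PI * cum / total


def polygon_self_intersects(pts: np.ndarray) -> bool:
    """Segment-pair sweep over the closed marker polygon."""
    n = len(pts)
    a = pts
    b = np.roll(pts, -1, axis=0)

    def orient(p, q, r):
        return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - (
            q[..., 1] - p[..., 1]
        ) * (r[..., 0] - p[..., 0])

    i, j = np.triu_indices(n, k=2)
    # skip the wrap-around adjacency (segment 0 vs segment n-1)
    keep = ~((i == 0) & (j == n - 1))
    i, j = i[keep], j[keep]
    o1 = orient(a[i], b[i], a[j])
    o2 = orient(a[i], b[i], b[j])
    o3 = orient(a[j], b[j], a[i])
    o4 = orient(a[j], b[j], b[i])
    return bool(np.any((o1 * o2 < 0) & (o3 * o4 < 0)))


@dataclass
class GeometryBundle:
    """Per-contour geometric quantities evaluated at the markers."""

    length: float  # total arc length L, um
    area: float  # enclosed (shoelace) area A, um^2
    curvature: np.ndarray  # signed curvature at markers, 1/um (convex > 0)
    normals: np.ndarray  # outward unit normals at markers, (N, 2)
    centroid: np.ndarray  # Phi_CM, arc-length mean of Phi, um


class SmoothContour:
    """GPR posterior-mean closed curve, evaluable at any normalized arc length.

    ``theta`` always denotes the *normalized arc-length* coordinate in
    [0, 2*pi).  Internally the GP is conditioned on an auxiliary chord-length
    parameter ``u``; a dense monotone table translates between the two.
    """

    def __init__(
        self,
        theta_train: np.ndarray,
        alpha: np.ndarray,
        cfg: GPRConfig,
        n_markers: int,
        n_dense: int = 512,
    ) -> None:
        if n_markers < 16:
            raise ValueError("need at least 16 markers")
        self.cfg = cfg
        self._theta_train = theta_train
        self._alpha = alpha  # (M, 2) dual coefficients for (x, y)
        self.n_markers = n_markers
        self._n_dense = n_dense
        self._build_arclength_table()
        self.theta = TWO_PI * np.arange(n_markers) / n_markers
        self.positions = self.position(self.theta)
        self._theta_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- raw GP evaluation in the internal parameter u ------------------
    def _eval_u_orders(self, u: np.ndarray, orders: tuple[int, ...]) -> dict:
        """Posterior mean and u-derivatives, sharing one trig pass."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        delta = u[:, None] - self._theta_train[None, :]
        r = self.cfg.r_cont
        c = np.cos(delta)
        denom = 1.0 - 2.0 * r * c + r * r
        inv = 1.0 / denom
        one_m_r2 = 1.0 - r * r
        out = {}
        if 0 in orders:
            out[0] = (one_m_r2 * inv) @ self._alpha
        if 1 in orders or 2 in orders:
            s = np.sin(delta)
            inv2 = inv * inv
            if 1 in orders:
                out[1] = (-one_m_r2 * 2.0 * r * s * inv2) @ self._alpha
            if 2 in orders:
                out[2] = (
                    one_m_r2 * (8.0 * r * r * s * s * inv2 * inv - 2.0 * r * c * inv2)
                ) @ self._alpha
        return out

    def _eval_u(self, u: np.ndarray, deriv: int = 0) -> np.ndarray:
        return self._eval_u_orders(u, (deriv,))[deriv]

    def _build_arclength_table(self) -> None:
        n = self._n_dense
        u = TWO_PI * np.arange(n + 1) / n
        ev = self._eval_u_orders(u, (0, 1))
        pos, d1 = ev[0], ev[1]
        speed = np.linalg.norm(d1, axis=1)
        if np.min(speed) <= 1e-12:
            raise ValueError("zero-length tangent: contour parametrization degenerate")
        # trapezoidal cumulative arc length on the periodic grid
        du = TWO_PI / n
        seg = 0.5 * (speed[:-1] + speed[1:]) * du
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(s[-1])
        self._u_grid = u
        self._thetanorm_grid = TWO_PI * s / self.length
        self._speed_grid = speed
        # shoelace area via quadrature of x * y' du (exact for the GP curve)
        x, y = pos[:, 0], pos[:, 1]
        xd, yd = d1[:, 0], d1[:, 1]
        self.area = float(np.trapezoid(0.5 * (x * yd - y * xd), dx=du))
        w = speed[:-1]
        self.centroid = (pos[:-1] * w[:, None]).sum(axis=0) / w.sum()
        self._pos_grid = pos
        self._dpos_dtheta_grid = d1 * (self.length / (TWO_PI * speed))[:, None]

    def _u_of_theta(self, theta: np.ndarray) -> np.ndarray:
        th = np.mod(theta, TWO_PI)
        return np.interp(th, self._thetanorm_grid, self._u_grid)

    # -- public evaluation in normalized arc length ---------------------
    def position(self, theta: np.ndarray) -> np.ndarray:
        """Phi(theta); periodic in theta."""
        return self._eval_u(self._u_of_theta(theta))

    def derivative(self, theta: np.ndarray) -> np.ndarray:
        """dPhi/dtheta (chain rule through the arc-length reparametrization)."""
        u = self._u_of_theta(theta)
        d1 = self._eval_u(u, deriv=1)
        speed = np.linalg.norm(d1, axis=1)
        return d1 * (self.length / (TWO_PI * speed))[:, None]

    def tangent(self, theta: np.ndarray) -> np.ndarray:
        d1 = self._eval_u(self._u_of_theta(theta), deriv=1)
        return d1 / np.linalg.norm(d1, axis=1)[:, None]

    def normal(self, theta: np.ndarray) -> np.ndarray:
        """Outward unit normal of the CCW-oriented contour."""
        t = self.tangent(theta)
        return np.column_stack([t[:, 1], -t[:, 0]])

    def curvature(self, theta: np.ndarray) -> np.ndarray:
        """Signed curvature, positive on convex segments of a CCW contour."""
        u = self._u_of_theta(theta)
        d1 = self._eval_u(u, deriv=1)
        d2 = self._eval_u(u, deriv=2)
        num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        speed = np.linalg.norm(d1, axis=1)
        return num / speed**3

    def dense_theta_cache(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Monotone dense theta grid with positions and dPhi/dtheta.

        Reuses the arc-length table (no extra kernel evaluations); the grid is
        dense but not uniform in theta, which ``np.interp`` handles directly.
        """
        return self._thetanorm_grid, self._pos_grid, self._dpos_dtheta_grid

    def marker_state(self, theta: np.ndarray):
        """(positions, outward normals, curvature) in one shared kernel pass."""
        u = self._u_of_theta(theta)
        ev = self._eval_u_orders(u, (0, 1, 2))
        pos, d1, d2 = ev[0], ev[1], ev[2]
        speed = np.linalg.norm(d1, axis=1)
        normals = np.column_stack([d1[:, 1], -d1[:, 0]]) / speed[:, None]
        kappa = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) / speed**3
        return pos, normals, kappa

    def geometry(self) -> GeometryBundle:
        """Arc length, area, marker curvatures/normals, and the centroid."""
        return GeometryBundle(
            length=self.length,
            area=self.area,
            curvature=self.curvature(self.theta),
            normals=self.normal(self.theta),
            centroid=self.centroid.copy(),
        )


def fit_contour(
    samples: ContourSamples | np.ndarray,
    cfg: GPRConfig | None = None,
    n_markers: int = 200,
    n_dense: int = 512,
    check_self_intersection: bool = True,
) -> SmoothContour:
    """Fit the periodic GPR posterior mean through ordered contour points.

    Sample locations on the circle are assigned by normalized cumulative chord
    length of the input polygon; the input is orientation-normalized to
    counter-clockwise first.  Markers of the returned contour are equidistant
    in arc length.
    """
    cfg = cfg or GPRConfig()
    pts = samples.points if isinstance(samples, ContourSamples) else np.asarray(samples, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need an (M, 2) array with M >= 4")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0 or sv[1] / sv[0] < 1e-10:
        raise ValueError("degenerate contour: points coincident or collinear")
    if _polygon_area(pts) < 0.0:
        pts = pts[::-1]
    theta = _chord_length_theta(pts)
    r = cfg.r_cont
    K = poisson_kernel(theta[:, None] - theta[None, :], r)
    K[np.diag_indices_from(K)] += cfg.sigma_noise**2 + cfg.jitter
    c = cho_factor(K, lower=True)
    alpha = cho_solve(c, pts)
    contour = SmoothContour(theta, alpha, cfg, n_markers, n_dense)
    if check_self_intersection and polygon_self_intersects(contour.positions):
        warnings.warn(
            "fitted contour polygon self-intersects (transient states tolerated)",
            SelfIntersectionWarning,
            stacklevel=2,
        )
    return contour


def geometry(contour: SmoothContour) -> GeometryBundle:
    """Geometric quantities of a fitted contour (module-level convenience)."""
    return contour.geometry()


def vmdr(theta_markers: np.ndarray) -> np.ndarray:
    """Virtual-marker distance ratios: circular gap over the equidistant gap.

    The mean over markers is exactly 1 because the gaps wind once around the
    circle.
    """
    th = np.asarray(theta_markers, dtype=float)
    if th.ndim != 1 or th.size < 3:
        raise ValueError("need at least 3 marker coordinates")
    if np.unique(np.mod(th, TWO_PI)).size != th.size:
        raise ValueError("duplicate marker coordinates")
    gaps = np.mod(np.diff(np.concatenate([th, th[:1]])), TWO_PI)
    return gaps / (TWO_PI / th.size)


def circle_samples(
    area: float = 80.0,
    n_points: int = 100,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
) -> np.ndarray:
    """Points on a circle of the given area; theta = 0 at the rightmost point."""
    radius = np.sqrt(area / np.pi)
    ang = phase + TWO_PI * np.arange(n_points) / n_points
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )
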