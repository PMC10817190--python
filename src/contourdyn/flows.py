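"""Deterministic retraction flows and normal-direction contour propagation.

Two geometric flows act as the model's retraction machinery:

* APCSF (area-preserving curve-shortening flow): normal speed
  ``-(kappa - 2*pi/L)``.  It is the arc-length gradient flow under an area
  constraint; since the turning number of a simple closed curve gives
  ``integral kappa ds = 2*pi``, the net area flux vanishes and every contour
  relaxes to the circle of equal area.
* AAF (area adjustment flow): normal speed
  ``-((A - A_ref)/(A_ref * L)) * <Phi - Phi_CM, n>``, which inflates or
  deflates the contour toward a reference area and, used alone, preserves the
  shape (it is a pure scaling about the centroid).

Contours are propagated with explicit Euler steps along the outward normal,
with the periodic-GPR re-fit after each step acting as the smoother of the
two-step scheme.
"""

from __future__ import annotations

import numpy as np

from .contour import GeometryBundle, GPRConfig, SmoothContour, fit_contour

__all__ = ["apcsf_speed", "aaf_speed", "propagate_normal", "evolve_pure_flow"]


def apcsf_speed(geom: GeometryBundle) -> np.ndarray:
    """Unit-weight APCSF normal speed -(kappa - 2*pi/L) at the markers."""
    return -(geom.curvature - 2.0 * np.pi / geom.length)


def aaf_speed(geom: GeometryBundle, positions: np.ndarray, a_ref: float) -> np.ndarray:
    """Unit-weight AAF normal speed toward the reference area ``a_ref``."""
    if a_ref <= 0.0:
        raise ValueError("a_ref must be positive")
    radial = np.einsum("ij,ij->i", positions - geom.centroid, geom.normals)
    return -((geom.area - a_ref) / (a_ref * geom.length)) * radial


def propagate_normal(
    contour: SmoothContour,
    f: np.ndarray,
    dt: float,
    cfg: GPRConfig | None = None,
    check_self_intersection: bool = False,
) -> SmoothContour:
    """Move each marker by ``f*dt`` along its outward normal and re-fit.

    The re-fit (smoothing step) re-distributes markers equidistantly in arc
    length; it is part of the propagation contract.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    f = np.asarray(f, dtype=float)
    if f.shape != (contour.n_markers,) or not np.all(np.isfinite(f)):
        raise ValueError("normal speed field must be finite with one value per marker")
    normals = contour.normal(contour.theta)
    new_pts = contour.positions + (f * dt)[:, None] * normals
    x, y = new_pts[:, 0], new_pts[:, 1]
    shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if shoelace <= 1e-10 * contour.area:
        raise ValueError("propagation step collapsed the contour (A <= 0)")
    return fit_contour(
        new_pts,
        cfg or contour.cfg,
        n_markers=contour.n_markers,
        n_dense=contour._n_dense,
        check_self_intersection=check_self_intersection,
    )


def evolve_pure_flow(
    contour: SmoothContour,
    flow: str,
    steps: int,
    dt: float,
    weight: float = 1.0,
    a_ref: float | None = None,
    cfg: GPRConfig | None = None,
) -> list[SmoothContour]:
    """Evolve a contour under one retraction flow alone (diagnostic harness).

    APCSF drives the isoperimetric ratio ``L^2/(4*pi*A)`` monotonically toward
    1; AAF drives A monotonically toward ``a_ref`` while preserving the
    normalized shape.  A CFL-like guard sub-steps whenever the displacement
    per step exceeds a quarter of the marker spacing.  Ten consecutive
    increases of the isoperimetric ratio abort with an error.
    """
    if flow not in ("apcsf", "aaf"):
        raise ValueError("flow must be 'apcsf' or 'aaf'")
    if flow == "aaf" and (a_ref is None or a_ref <= 0):
        raise ValueError("aaf requires a positive a_ref")
    out = [contour]
    cur = contour
    ratio_prev = np.inf
    bad_streak = 0
    for _ in range(steps):
        geom = cur.geometry()
        if flow == "apcsf":
            f = weight * apcsf_speed(geom)
        else:
            f = weight * aaf_speed(geom, cur.positions, a_ref)
        # CFL-like guard: max displacement per (sub)step <= 0.25 * L / N
        limit = 0.25 * geom.length / cur.n_markers
        n_sub = max(1, int(np.ceil(np.max(np.abs(f)) * dt / limit)))
        sub_dt = dt / n_sub
        cur = propagate_normal(cur, f, sub_dt, cfg)
        for _ in range(n_sub - 1):
            geom = cur.geometry()
            if flow == "apcsf":
                f = weight * apcsf_speed(geom)
            else:
                f = weight * aaf_speed(geom, cur.positions, a_ref)
            cur = propagate_normal(cur, f, sub_dt, cfg)
        out.append(cur)
        ratio = cur.length**2 / (4.0 * np.pi * cur.area)
        if flow == "apcsf":
            bad_streak = bad_streak + 1 if ratio > ratio_prev + 1e-12 else 0
            if bad_streak > 10:
                raise RuntimeError("APCSF diverging: isoperimetric ratio increasing")
            ratio_prev = ratio
    return out
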