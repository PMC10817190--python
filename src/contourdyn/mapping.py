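"""Regularized virtual-marker mapping between consecutive contours.

A contour sequence alone does not say which material point went where: any
tangential re-labeling is compatible with the same shapes.  The mapping
``phi_k`` assigns each virtual marker on contour ``Gamma_k`` a target
coordinate on ``Gamma_{k+1}`` by minimizing

    F_k[phi] + lambda_reg * U_k[phi],

where ``F_k`` is the mean squared trajectory length (per ``dt^2``, so in
um^2/s^2) and ``U_k = N * sum |gap_i|^2`` penalizes uneven spacing of the
mapped markers.  ``lambda_reg = 0`` gives shortest trajectories (nearest-point
projection); large ``lambda_reg`` enforces equidistant markers.

Monotonicity (no topological mapping violations) is structural: the target
coordinates are parametrized by a free offset plus strictly positive gaps
obtained from a softmax over unconstrained variables, normalized to wind
exactly 2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .contour import SmoothContour, vmdr

__all__ = ["MarkerMap", "mapping_energy", "map_contours", "propagate_chain"]

TWO_PI = 2.0 * np.pi


@dataclass
class MarkerMap:
    """Mapped marker coordinates on the next contour (circularly increasing)."""

    phi: np.ndarray  # target theta for each source marker, in [0, 2*pi)
    lambda_reg: float
    n_iter: int = 0
    objective: float = np.nan

    def __post_init__(self) -> None:
        gaps = np.mod(np.diff(np.concatenate([self.phi, self.phi[:1]])), TWO_PI)
        if np.any(gaps <= 0.0) or not np.isclose(gaps.sum(), TWO_PI):
            raise ValueError("marker map must be strictly monotone with winding 2*pi")


def _interp_periodic(theta, grid_theta, grid_vals):
    th = np.mod(theta, TWO_PI)
    x = np.interp(th, grid_theta, grid_vals[:, 0])
    y = np.interp(th, grid_theta, grid_vals[:, 1])
    return np.column_stack([x, y])


def mapping_energy(
    mmap: MarkerMap,
    gamma_k: SmoothContour,
    gamma_k1: SmoothContour,
    dt: float,
    theta_k: np.ndarray | None = None,
) -> tuple[float, float]:
    """(F, U): trajectory-length and spacing-uniformity costs of a map."""
    theta_k = gamma_k.theta if theta_k is None else np.asarray(theta_k, float)
    n = theta_k.size
    src = gamma_k.position(theta_k)
    dst = gamma_k1.position(mmap.phi)
    F = float(np.sum(np.linalg.norm(dst - src, axis=1) ** 2) / (n * dt**2))
    gaps = np.mod(np.diff(np.concatenate([mmap.phi, mmap.phi[:1]])), TWO_PI)
    U = float(n * np.sum(gaps**2))
    return F, U


def _objective_and_grad(x, src, tgrid, pos_g, dpos_g, lambda_reg, n, dt):
    w0 = x[0]
    z = x[1:] - np.max(x[1:])
    ez = np.exp(z)
    p = ez / ez.sum()
    gaps = TWO_PI * p
    theta = w0 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    pos = _interp_periodic(theta, tgrid, pos_g)
    dpos = _interp_periodic(theta, tgrid, dpos_g)
    diff = pos - src
    F = np.sum(diff * diff) / (n * dt * dt)
    U = n * np.sum(gaps * gaps)
    q = 2.0 * np.einsum("ij,ij->i", diff, dpos) / (n * dt * dt)  # dF/dtheta_i
    # theta_i depends on gap_j for j < i; U adds 2*n*gap_j
    rev = np.cumsum(q[::-1])[::-1]
    h = np.concatenate([rev[1:], [0.0]]) + lambda_reg * 2.0 * n * gaps
    grad_w0 = q.sum()
    grad_z = TWO_PI * p * (h - np.dot(p, h))
    return F + lambda_reg * U, np.concatenate([[grad_w0], grad_z])


def _nearest_point_init(src: np.ndarray, tgrid: np.ndarray, pos_g: np.ndarray):
    d2 = ((src[:, None, :] - pos_g[None, :-1, :]) ** 2).sum(axis=2)
    return tgrid[np.argmin(d2, axis=1)]


def map_contours(
    gamma_k: SmoothContour,
    gamma_k1: SmoothContour,
    theta_k: np.ndarray | None = None,
    lambda_reg: float = 10.0,
    dt: float = 1.0,
    max_iter: int = 500,
    gtol: float = 1e-8,
    init_phi: np.ndarray | None = None,
) -> MarkerMap:
    """Minimize F + lambda_reg * U over strictly monotone marker maps.

    Deterministic local descent (L-BFGS-B with analytic gradients) from the
    nearest-point initialization (or a caller-supplied warm start); target
    positions are linearly interpolated on the receiving contour's dense
    arc-length grid.
    """
    if lambda_reg < 0.0:
        raise ValueError("lambda_reg must be >= 0")
    theta_k = gamma_k.theta if theta_k is None else np.asarray(theta_k, float)
    n = theta_k.size
    src = gamma_k.position(theta_k)
    tgrid, pos_g, dpos_g = gamma_k1.dense_theta_cache()
    if init_phi is not None:
        theta0 = np.asarray(init_phi, dtype=float)
    else:
        theta0 = _nearest_point_init(src, tgrid, pos_g)
    # unwrap into a monotone sequence and convert to positive gaps
    gaps0 = np.mod(np.diff(np.concatenate([theta0, theta0[:1]])), TWO_PI)
    gaps0 = np.maximum(gaps0, 1e-3 * TWO_PI / n)
    gaps0 *= TWO_PI / gaps0.sum()
    x0 = np.concatenate([[theta0[0]], np.log(gaps0)])
    res = minimize(
        _objective_and_grad,
        x0,
        args=(src, tgrid, pos_g, dpos_g, lambda_reg, n, dt),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    x = res.x
    z = x[1:] - np.max(x[1:])
    ez = np.exp(z)
    gaps = TWO_PI * ez / ez.sum()
    theta = np.mod(x[0] + np.concatenate([[0.0], np.cumsum(gaps[:-1])]), TWO_PI)
    gaps_chk = np.mod(np.diff(np.concatenate([theta, theta[:1]])), TWO_PI)
    if np.any(gaps_chk <= 0.0):
        raise RuntimeError(
            "mapping optimizer produced a non-monotone map "
            f"(min gap {gaps_chk.min():.3e}); refusing to reorder markers"
        )
    return MarkerMap(
        phi=theta, lambda_reg=lambda_reg, n_iter=res.nit, objective=float(res.fun)
    )


def propagate_chain(
    contours: list[SmoothContour],
    lambda_reg: float = 10.0,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[MarkerMap]]:
    """Chain the per-step maps into the Lagrangian frame chi.

    Starting from the equidistant markers of the first contour, returns the
    (K, N) array of marker coordinates per frame, the (K, N) VMDR grid, and
    the per-step maps.
    """
    if len(contours) < 2:
        raise ValueError("need at least two contours")
    n = contours[0].n_markers
    chi = [contours[0].theta.copy()]
    maps: list[MarkerMap] = []
    for k in range(len(contours) - 1):
        m = map_contours(
            contours[k], contours[k + 1], chi[-1], lambda_reg, dt,
            init_phi=chi[-1],
        )
        maps.append(m)
        chi.append(m.phi.copy())
    chi_arr = np.vstack(chi)
    vm = np.vstack([vmdr(row) for row in chi_arr])
    return chi_arr, vm, maps
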