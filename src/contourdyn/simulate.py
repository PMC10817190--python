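"""Forward three-component contour-dynamics model.

The contour's normal velocity is assembled per marker as

    f = f_prot + f_APCSF + f_AAF,

    f_prot  =  w_prot * X_prot / L,
    f_APCSF = -w_APCSF * (kappa - 2*pi/L),
    f_AAF   = -w_AAF * ((A - A_ref)/(A_ref * L)) * <Phi - Phi_CM, n>,

with the protrusion field X_prot driven by a Hawkes-process realization
(sampled once for the whole horizon, since the polarization is fixed) and the
two geometric flows providing the retractions.  Each time step applies the
two-step scheme: (1) move markers along their outward normals by f*dt and
re-fit the smooth contour; (2) remap the virtual markers onto the new contour
with the regularized flow, which updates the VMDR entering X_prot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import GPRConfig, SmoothContour, circle_samples, fit_contour
from .flows import aaf_speed, apcsf_speed
from .hawkes import EventList, HawkesParams, protrusion_row, sample_hawkes
from .mapping import map_contours

__all__ = ["ModelWeights", "SimulationConfig", "CellTrack", "total_speed", "simulate"]


@dataclass(frozen=True)
class ModelWeights:
    """Component weights of the three-part normal-velocity model."""

    w_prot: float = 7.5  # um^2/s
    w_apcsf: float = 0.1  # um^2/s
    w_aaf: float = 1.0  # um/s
    a_ref: float = 80.0  # um^2

    def __post_init__(self) -> None:
        # w_prot = 0 is admitted for the pure-retraction (APCSF+AAF) regime
        if self.w_aaf <= 0 or self.a_ref <= 0:
            raise ValueError("w_aaf and a_ref must be positive")
        if self.w_apcsf < 0 or self.w_prot < 0:
            raise ValueError("w_prot and w_apcsf must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid, resolution, regularization and process parameters."""

    dt: float = 0.5  # s
    T: float = 500.0  # s
    n_markers: int = 200
    lambda_reg: float = 10.0  # um^2/s^2
    seed: int = 0
    gpr: GPRConfig = field(default_factory=GPRConfig)
    hawkes: HawkesParams = field(default_factory=HawkesParams)
    n_dense: int = 512
    initial_points: np.ndarray | None = None  # default: circle of area a_ref

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T < self.dt:
            raise ValueError("need dt > 0 and T >= dt")


@dataclass
class CellTrack:
    """A simulated (or reconstructed) contour sequence with component fields.

    Contours are stored at K+1 frames t_k = k*dt; the per-step fields live on
    the (K, N) grid of the departing frame's markers.  The decomposition
    ``f = f_prot + f_apcsf + f_aaf`` holds exactly at every node.
    """

    times: np.ndarray  # (K+1,)
    contours: list[SmoothContour]  # length K+1
    marker_theta: np.ndarray  # (K+1, N) Lagrangian marker coordinates
    vmdr: np.ndarray  # (K+1, N)
    f: np.ndarray  # (K, N) total normal speed, um/s
    f_prot: np.ndarray
    f_apcsf: np.ndarray
    f_aaf: np.ndarray
    x_prot: np.ndarray  # (K, N) protrusion process values
    events: EventList | None
    weights: ModelWeights | None
    config: SimulationConfig | None
    area: np.ndarray = field(default=None)  # (K+1,)
    arc_length: np.ndarray = field(default=None)
    centroid: np.ndarray = field(default=None)  # (K+1, 2)

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def marker_positions(self, k: int) -> np.ndarray:
        return self.contours[k].position(self.marker_theta[k])


def total_speed(
    geom,
    positions: np.ndarray,
    x_prot_row: np.ndarray,
    weights: ModelWeights,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (f, f_prot, f_apcsf, f_aaf) at the markers, in um/s."""
    f_prot = weights.w_prot * np.asarray(x_prot_row) / geom.length
    f_apcsf = weights.w_apcsf * apcsf_speed(geom)
    f_aaf = weights.w_aaf * aaf_speed(geom, positions, weights.a_ref)
    return f_prot + f_apcsf + f_aaf, f_prot, f_apcsf, f_aaf


def simulate(config: SimulationConfig, weights: ModelWeights | None = None) -> CellTrack:
    """Run the two-step propagate/remap loop and return the full track.

    Reproducible for a fixed config: a single RNG stream (seeded from the
    config) is consumed by the Hawkes sampler only; every other step is
    deterministic.
    """
    weights = weights or ModelWeights()
    n = config.n_markers
    n_steps = int(round(config.T / config.dt))
    rng = np.random.default_rng(config.seed)
    events = sample_hawkes(config.hawkes, config.T + config.dt, rng)

    if config.initial_points is None:
        init_pts = circle_samples(weights.a_ref, n_points=n)
    else:
        init_pts = np.asarray(config.initial_points, dtype=float)
    contour = fit_contour(
        init_pts, config.gpr, n_markers=n, n_dense=config.n_dense,
        check_self_intersection=False,
    )

    theta = contour.theta.copy()  # current (Lagrangian) marker coordinates
    vmdr_row = np.ones(n)

    contours = [contour]
    thetas = [theta.copy()]
    vmdrs = [vmdr_row.copy()]
    F = np.empty((n_steps, n))
    Fp = np.empty((n_steps, n))
    Fc = np.empty((n_steps, n))
    Fa = np.empty((n_steps, n))
    X = np.empty((n_steps, n))
    area = np.empty(n_steps + 1)
    arc = np.empty(n_steps + 1)
    cm = np.empty((n_steps + 1, 2))
    area[0], arc[0], cm[0] = contour.area, contour.length, contour.centroid

    for k in range(n_steps):
        t_k = k * config.dt
        pos, normals, kappa = contour.marker_state(theta)
        geom = _MarkerGeom(contour.length, contour.area, kappa, normals, contour.centroid)
        x_row = protrusion_row(events, t_k, theta, vmdr_row, config.hawkes)
        f, fp, fc, fa = total_speed(geom, pos, x_row, weights)
        F[k], Fp[k], Fc[k], Fa[k], X[k] = f, fp, fc, fa, x_row

        new_pts = pos + (f * config.dt)[:, None] * normals
        new_contour = fit_contour(
            new_pts, config.gpr, n_markers=n, n_dense=config.n_dense,
            check_self_intersection=False,
        )
        if new_contour.area < 0.05 * weights.a_ref:
            raise RuntimeError(
                f"contour collapsed at t = {t_k + config.dt:.2f} s "
                f"(A = {new_contour.area:.2f} um^2)"
            )
        mmap = map_contours(
            contour, new_contour, theta, config.lambda_reg, config.dt,
            init_phi=theta,
        )
        theta = mmap.phi
        gaps = np.mod(np.diff(np.concatenate([theta, theta[:1]])), 2 * np.pi)
        vmdr_row = gaps / (2 * np.pi / n)
        contour = new_contour
        contours.append(contour)
        thetas.append(theta.copy())
        vmdrs.append(vmdr_row.copy())
        area[k + 1], arc[k + 1], cm[k + 1] = contour.area, contour.length, contour.centroid

    return CellTrack(
        times=config.dt * np.arange(n_steps + 1),
        contours=contours,
        marker_theta=np.vstack(thetas),
        vmdr=np.vstack(vmdrs),
        f=F,
        f_prot=Fp,
        f_apcsf=Fc,
        f_aaf=Fa,
        x_prot=X,
        events=events,
        weights=weights,
        config=config,
        area=area,
        arc_length=arc,
        centroid=cm,
    )


@dataclass
class _MarkerGeom:
    """GeometryBundle-shaped view evaluated at arbitrary marker coordinates."""

    length: float
    area: float
    curvature: np.ndarray
    normals: np.ndarray
    centroid: np.ndarray
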