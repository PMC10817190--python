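"""Stochastic protrusion drivers on the circle.

Protrusion events are modeled as a spatio-temporal Hawkes (self-exciting
Poisson) process on ``[0, T) x [0, 2*pi)`` with intensity

    lambda(t, theta) = mu(theta) + sum_{t_i < t} g(t - t_i, theta - theta_i),

background ``mu(theta) = lambda0 * wrapped-Cauchy(theta; pi, r_pol)`` (the
normalized Poisson kernel centered at theta = pi) and product triggering
kernel ``g(t, theta) = g1(t) * g2(theta)`` with

    g1(t) = alpha * beta * t * exp(-beta * t)      (integral alpha/beta),
    g2(theta) = von Mises(0, kappa_M) density.

The branching ratio ``eta = alpha/beta`` must stay below 1 (subcritical), in
which case the expected event count is ``lambda0 * T / (1 - eta)``.  Sampling
uses the exact cluster (branching) construction: background events are drawn
from the inhomogeneous rate, and every event spawns a Poisson(eta) number of
offspring displaced by Gamma(2, 1/beta) in time and von Mises(0, kappa_M) in
angle.  A plain Poisson variant (no offspring) is provided for comparison.

The protrusion field transported over the contour is

    X_prot(t, theta) = c_s / VMDR(t, theta) * (lambda(t, theta) - mu(theta)),

i.e. the triggered part of the intensity, rescaled by the local virtual-marker
distance ratio to account for contour stretching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0

__all__ = [
    "HawkesParams",
    "EventList",
    "normalized_poisson_kernel",
    "background_intensity",
    "triggering_kernel",
    "sample_hawkes",
    "sample_poisson",
    "intensity",
    "ou_protrusion_field",
    "protrusion_field",
    "protrusion_row",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class HawkesParams:
    """Parameters of the protrusion point process (rates in 1/s)."""

    lambda0: float = 1.0
    alpha: float = 0.4
    beta: float = 0.5
    kappa_m: float = 100.0
    r_pol: float = 0.0
    c_s: float = 1.0  # time scale of the protrusion field, s

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.beta <= 0 or self.alpha < 0:
            raise ValueError("need lambda0 > 0, beta > 0, alpha >= 0")
        if not (0.0 <= self.r_pol < 1.0):
            raise ValueError("r_pol must be in [0, 1)")
        if self.kappa_m <= 0:
            raise ValueError("kappa_m must be > 0")

    @property
    def branching_ratio(self) -> float:
        return self.alpha / self.beta


@dataclass
class EventList:
    """Sorted point events with cluster-genealogy bookkeeping."""

    t: np.ndarray  # event times, s
    theta: np.ndarray  # event angles, rad in [0, 2*pi)
    generation: np.ndarray  # 0 = background, k = k-th offspring generation
    parent: np.ndarray  # index into this list; -1 for background events

    def __len__(self) -> int:
        return self.t.size


def wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (-pi, pi]."""
    return np.pi - np.mod(np.pi - delta, TWO_PI)


def normalized_poisson_kernel(theta, theta_p, r: float):
    """k~_r in (0, 1]: the Poisson kernel scaled to equal 1 at theta == theta_p."""
    if not (0.0 <= r < 1.0):
        raise ValueError("r must be in [0, 1)")
    delta = np.asarray(theta, dtype=float) - theta_p
    return (1.0 - r) ** 2 / (1.0 - 2.0 * r * np.cos(delta) + r * r)


def background_intensity(theta, lambda0: float, r_pol: float):
    """mu(theta): polarized background density integrating to lambda0.

    Normalizing the Poisson kernel over the circle yields the wrapped-Cauchy
    density centered at theta = pi, so mu(theta) = lambda0 * WC(theta; pi,
    r_pol); for r_pol = 0 it is the constant lambda0 / (2*pi).
    """
    th = np.asarray(theta, dtype=float)
    r = r_pol
    denom = 1.0 + 2.0 * r * np.cos(th) + r * r  # cos(theta - pi) = -cos(theta)
    return lambda0 * (1.0 - r * r) / (TWO_PI * denom)


def temporal_kernel(t, alpha: float, beta: float):
    t = np.asarray(t, dtype=float)
    out = alpha * beta * t * np.exp(-beta * t)
    return np.where(t >= 0.0, out, 0.0)


def spatial_kernel(theta, kappa_m: float):
    d = wrap_angle(np.asarray(theta, dtype=float))
    return np.exp(kappa_m * np.cos(d)) / (TWO_PI * i0(kappa_m))


def triggering_kernel(t, theta, params: HawkesParams):
    """Product kernel g(t, theta) = g1(t) * g2(theta)."""
    return temporal_kernel(t, params.alpha, params.beta) * spatial_kernel(
        theta, params.kappa_m
    )


def _sample_background_angles(n: int, r_pol: float, rng: np.random.Generator):
    if r_pol == 0.0:
        return rng.uniform(0.0, TWO_PI, size=n)
    # wrapped Cauchy with concentration r = exp(-gamma), center pi
    gamma = -np.log(r_pol)
    return np.mod(np.pi + gamma * rng.standard_cauchy(size=n), TWO_PI)


def sample_hawkes(
    params: HawkesParams,
    T: float,
    seed: int | np.random.Generator,
    stationary: bool = False,
) -> EventList:
    """Exact cluster-construction sample of the Hawkes process on [0, T).

    With ``stationary=False`` (default, matching the simulator) the process
    starts empty at t = 0; the returned count then approaches
    ``lambda0 * T / (1 - eta)`` only asymptotically in T, because early times
    lack the triggered offspring of pre-window ancestors.  With
    ``stationary=True`` background ancestors are additionally rooted in a
    burn-in interval before t = 0 (long relative to the cluster lifetime) so
    the event rate on [0, T) is the stationary one and the expected count is
    ``lambda0 * T / (1 - eta)``.
    """
    if params.branching_ratio >= 1.0:
        raise ValueError(
            f"supercritical Hawkes process: alpha/beta = {params.branching_ratio} >= 1"
        )
    if T <= 0:
        raise ValueError("T must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta_ = params.branching_ratio
    burn = 0.0
    if stationary:
        # cluster lifetime ~ (mean depth) * (mean offspring delay) = eta/(1-eta) * 2/beta
        burn = 50.0 * max(eta_ / max(1.0 - eta_, 1e-3), 1.0) * 2.0 / params.beta
    n_bg = rng.poisson(params.lambda0 * (T + burn))
    t = list(rng.uniform(-burn, T, size=n_bg))
    theta = list(_sample_background_angles(n_bg, params.r_pol, rng))
    gen = [0] * n_bg
    parent = [-1] * n_bg
    eta = params.branching_ratio
    queue = list(range(n_bg))
    while queue:
        idx = queue.pop()
        if eta == 0.0:
            continue
        n_child = rng.poisson(eta)
        for _ in range(n_child):
            tc = t[idx] + rng.gamma(2.0, 1.0 / params.beta)
            if tc >= T:
                continue
            thc = np.mod(theta[idx] + rng.vonmises(0.0, params.kappa_m), TWO_PI)
            t.append(tc)
            theta.append(thc)
            gen.append(gen[idx] + 1)
            parent.append(idx)
            queue.append(len(t) - 1)
    t_arr = np.asarray(t)
    theta_arr = np.asarray(theta)
    gen_arr = np.asarray(gen)
    parent_arr = np.asarray(parent, dtype=int)
    if burn > 0.0:
        keep = t_arr >= 0.0
        remap = np.full(t_arr.size, -1, dtype=int)
        remap[keep] = np.arange(int(keep.sum()))
        parent_arr = np.where(
            (parent_arr >= 0) & keep, remap[np.maximum(parent_arr, 0)], -1
        )[keep]
        t_arr, theta_arr, gen_arr = t_arr[keep], theta_arr[keep], gen_arr[keep]
    order = np.argsort(t_arr, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    parent_sorted = np.where(parent_arr[order] >= 0, inv[parent_arr[order]], -1)
    return EventList(
        t=t_arr[order],
        theta=theta_arr[order],
        generation=gen_arr[order],
        parent=parent_sorted,
    )


def sample_poisson(
    lambda0: float,
    r_pol: float,
    T: float,
    seed: int | np.random.Generator,
    c_s: float = 1.0,
) -> EventList:
    """Plain (non-self-exciting) Poisson variant: background events only."""
    params = HawkesParams(lambda0=lambda0, alpha=0.0, beta=0.5, r_pol=r_pol, c_s=c_s)
    return sample_hawkes(params, T, seed)


def intensity(events: EventList, t: float, theta, params: HawkesParams):
    """Conditional intensity lambda(t, theta) given the realized events."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    lam = background_intensity(th, params.lambda0, params.r_pol)
    past = events.t < t
    if np.any(past):
        dt = t - events.t[past]
        dth = th[:, None] - events.theta[past][None, :]
        lam = lam + (
            temporal_kernel(dt, params.alpha, params.beta)[None, :]
            * spatial_kernel(dth, params.kappa_m)
        ).sum(axis=1)
    return lam


def protrusion_row(
    events: EventList,
    t: float,
    thetas: np.ndarray,
    vmdr_row: np.ndarray,
    params: HawkesParams,
    window: float | None = None,
) -> np.ndarray:
    """X_prot(t, theta_i) = c_s/VMDR_i * sum g(t - t_j, theta_i - theta_j).

    ``window`` truncates the (exponentially decaying) temporal kernel; the
    default keeps every contribution above double precision.
    """
    vm = np.asarray(vmdr_row, dtype=float)
    if np.any(vm <= 0.0):
        raise ValueError("VMDR values must be strictly positive")
    if window is None:
        window = 60.0 / params.beta
    lo = np.searchsorted(events.t, t - window)
    hi = np.searchsorted(events.t, t, side="left")
    out = np.zeros(len(thetas))
    if hi > lo:
        dt = t - events.t[lo:hi]
        dth = np.asarray(thetas)[:, None] - events.theta[lo:hi][None, :]
        g1 = temporal_kernel(dt, params.alpha, params.beta)
        out = (g1[None, :] * spatial_kernel(dth, params.kappa_m)).sum(axis=1)
    return params.c_s * out / vm


def ou_protrusion_field(
    times: np.ndarray,
    thetas: np.ndarray,
    seed: int | np.random.Generator,
    mean: float = 0.64,
    std: float = 0.42,
    tau_t: float = 4.0,
    kappa_theta: float = 100.0,
) -> np.ndarray:
    """Non-canonical Ornstein-Uhlenbeck protrusion variant (provisional).

    A mean-reverting alternative to the Hawkes field behind the same
    (time x marker) grid contract: spatially correlated Gaussian noise (von
    Mises-shaped angular correlation with concentration ``kappa_theta``)
    relaxing toward ``mean`` with time constant ``tau_t`` (s), clipped at
    zero so the field stays a protrusion (non-negative) process.  The exact
    formulation is not canonical for this model; defaults here match the Hawkes field's stationary mean/std
    under the reference parameters and are documented as provisional.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    n = thetas.size
    dtheta = wrap_angle(thetas[:, None] - thetas[None, :])
    cov = np.exp(kappa_theta * (np.cos(dtheta) - 1.0))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    x = np.empty((times.size, n))
    state = chol @ rng.standard_normal(n)
    x[0] = state
    for k in range(1, times.size):
        rho = np.exp(-(times[k] - times[k - 1]) / tau_t)
        state = rho * state + np.sqrt(1.0 - rho * rho) * (
            chol @ rng.standard_normal(n)
        )
        x[k] = state
    return np.maximum(mean + std * x, 0.0)


def protrusion_field(
    events: EventList,
    times: np.ndarray,
    thetas: np.ndarray,
    vmdr_grid: np.ndarray,
    params: HawkesParams,
) -> np.ndarray:
    """X_prot on a (time x marker) grid; vmdr_grid broadcasts to that shape."""
    times = np.asarray(times, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    vm = np.broadcast_to(np.asarray(vmdr_grid, dtype=float), (times.size, thetas.size))
    rows = [
        protrusion_row(events, t, thetas, vm[k], params) for k, t in enumerate(times)
    ]
    return np.vstack(rows)
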