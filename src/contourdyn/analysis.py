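"""Kymographs and track-level motility statistics.

Center-of-mass trajectories are summarized by the ensemble mean squared
displacement MSD(t) = <||Phi_CM(t) - Phi_CM(0)||^2>, a linear diffusion fit
MSD = 2 n D t (n = 2 dimensions), and the persistent-random-walk (Fuerth)
fit MSD(t) = 2 n D (t - P (1 - exp(-t/P))) yielding a diffusion coefficient
D and persistence time P.  Kymographs plot a per-marker quantity over the
(time x Lagrangian marker) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import CellTrack

__all__ = [
    "Kymograph",
    "MSDCurve",
    "FurthFit",
    "local_motion_kymograph",
    "msd",
    "fit_diffusion",
    "fit_furth",
    "instantaneous_speed",
    "vmdr_std",
]

_DIM = 2  # planar trajectories throughout


@dataclass
class Kymograph:
    """Quantity sampled on the (frame x Lagrangian marker index) grid."""

    values: np.ndarray  # (K, N)
    times: np.ndarray  # (K,)
    quantity: str = ""
    units: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=pd.Index(self.times, name="time_s"),
            columns=pd.RangeIndex(self.values.shape[1], name="marker"),
        )


@dataclass
class MSDCurve:
    lags: np.ndarray  # s
    values: np.ndarray  # um^2; values[0] == 0
    n_tracks: int


@dataclass
class FurthFit:
    """Persistent-random-walk parameters (dimension fixed at 2)."""

    D: float  # um^2/s
    P: float  # s
    dim: int = _DIM


def local_motion_kymograph(track: CellTrack) -> Kymograph:
    """Normal-velocity kymograph f along the Lagrangian frame.

    Simulated tracks carry their f grid; tracks reconstructed from observed
    stacks (no stored fields) get the normal projection of the per-step
    marker displacement divided by dt.
    """
    if track.f is not None:
        values = track.f
    else:
        K = track.n_frames - 1
        values = np.empty((K, track.marker_theta.shape[1]))
        for k in range(K):
            src = track.contours[k].position(track.marker_theta[k])
            dst = track.contours[k + 1].position(track.marker_theta[k + 1])
            normals = track.contours[k].normal(track.marker_theta[k])
            values[k] = np.einsum("ij,ij->i", dst - src, normals) / track.dt
    return Kymograph(values, track.times[:-1], "local motion f", "um/s")


def msd(
    trajectories: list[np.ndarray] | np.ndarray,
    dt: float = 1.0,
    time_average: bool = False,
    max_lag: int | None = None,
) -> MSDCurve:
    """Mean squared displacement of centroid trajectories.

    Default: ensemble average of ||x(t) - x(0)||^2 over tracks at absolute
    lags from t = 0 (the convention behind the published long-run statistics).
    With ``time_average=True`` the MSD is additionally averaged over all start
    points within each track — the statistically efficient estimator used for
    parameter recovery; ``max_lag`` (in steps) limits the lag range.
    """
    if isinstance(trajectories, np.ndarray) and trajectories.ndim == 2:
        trajectories = [trajectories]
    trajs = [np.asarray(tr, dtype=float) for tr in trajectories]
    k = min(tr.shape[0] for tr in trajs)
    n_lags = k - 1 if max_lag is None else min(max_lag, k - 1)
    if not time_average:
        disp = np.stack([((tr[: n_lags + 1] - tr[0]) ** 2).sum(axis=1) for tr in trajs])
        return MSDCurve(
            lags=dt * np.arange(n_lags + 1), values=disp.mean(axis=0),
            n_tracks=len(trajs),
        )
    vals = np.zeros(n_lags + 1)
    for lag in range(1, n_lags + 1):
        vals[lag] = np.mean(
            [((tr[lag:] - tr[:-lag]) ** 2).sum(axis=1).mean() for tr in trajs]
        )
    return MSDCurve(lags=dt * np.arange(n_lags + 1), values=vals, n_tracks=len(trajs))


def fit_diffusion(curve: MSDCurve, window: tuple[float, float] | None = None) -> float:
    """Diffusion coefficient from a linear MSD fit: slope / (2 * n) = slope / 4.

    Default window is the upper half of the available lags (the long-time
    linear regime).
    """
    lags, vals = curve.lags, curve.values
    if window is None:
        window = (lags[-1] / 2.0, lags[-1])
    mask = (lags >= window[0]) & (lags <= window[1])
    if mask.sum() < 3:
        raise ValueError("diffusion fit window must contain at least 3 points")
    slope, _ = np.polyfit(lags[mask], vals[mask], 1)
    return float(slope) / (2.0 * _DIM)


def _furth(t, D, P):
    return 2.0 * _DIM * D * (t - P * (1.0 - np.exp(-t / np.maximum(P, 1e-12))))


def fit_furth(curve: MSDCurve) -> FurthFit:
    """Nonlinear least squares of the Fuerth formula with positivity bounds.

    Initialized from the terminal linear slope (D) and its time intercept (P);
    exact on noise-free curves generated by the formula itself.  Finite
    ensembles carry a relative MSD error that grows with the displacement
    itself (Var[MSD(t)] ~ MSD(t)^2 / n_tracks), so the fit weights residuals
    relative to the curve value.
    """
    lags, vals = curve.lags[1:], curve.values[1:]
    if lags.size < 4:
        raise ValueError("need at least 4 positive lags for the Fuerth fit")
    half = lags >= lags[-1] / 2.0
    slope, intercept = np.polyfit(lags[half], vals[half], 1)
    d0 = max(slope / (2.0 * _DIM), 1e-9)
    p0 = max(-intercept / (2.0 * _DIM * d0), lags[1])
    sigma = np.maximum(vals, 1e-12 * max(vals.max(), 1.0))
    try:
        popt, _ = curve_fit(
            _furth,
            lags,
            vals,
            p0=[d0, p0],
            sigma=sigma,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Fuerth fit did not converge: {err}") from err
    return FurthFit(D=float(popt[0]), P=float(popt[1]))


def instantaneous_speed(centroid: np.ndarray, dt: float) -> float:
    """Mean per-step centroid speed ||delta Phi_CM|| / dt, in um/min."""
    c = np.asarray(centroid, dtype=float)
    steps = np.linalg.norm(np.diff(c, axis=0), axis=1)
    return float(steps.mean() / dt * 60.0)


def vmdr_std(track: CellTrack | np.ndarray) -> float:
    """sigma_VMDR pooled over all frames and markers."""
    vm = track.vmdr if isinstance(track, CellTrack) else np.asarray(track, float)
    return float(np.std(vm, ddof=1))
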