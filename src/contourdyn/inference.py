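"""Inverse problem: decompose observed contour dynamics into model components.

Given a sequence of segmented cell contours, the two geometric retraction
flows (APCSF, AAF) are computable per frame from the contour geometry alone.
The residual needed to propagate each contour onto the next is attributed to
the protrusion component.  The component weights are estimated as follows:

* ``A_ref``: 1st percentile of the area time series;
* ``(w_APCSF, w_AAF)``: non-negative least squares matching the summed
  retraction flows to the negative part of the local-motion kymograph;
* ``w_prot``: scaled so the implied protrusion process ``X_prot = f_prot * L
  / w_prot`` has unit sample variance;
* ``f_prot`` is then refined per frame so that markers propagated under the
  total normal speed for one time step land on the receiving contour
  (point-to-curve distance along the marker normal).

A mostly-positive inferred protrusion component indicates a good fit (the
retractions are captured by the deterministic flows).  A vanishing APCSF
weight is the signature of fan-shaped locomotion, whose persistent concave
(kidney-shaped) contour is incompatible with curvature-driven rounding;
otherwise the track is labeled amoeboid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .analysis import Kymograph
from .contour import GPRConfig, SmoothContour, fit_contour
from .mapping import propagate_chain
from .simulate import CellTrack, ModelWeights

__all__ = [
    "ContourDynamicsModel",
    "InferenceResults",
    "reference_area",
    "goodness_of_fit",
    "classify",
    "membrane_intensity",
    "correlate",
]

TWO_PI = 2.0 * np.pi

#: default w_APCSF below which a track is called fan-shaped (um^2/s); an order
#: of magnitude below the smallest weight we associate with amoeboid motion.
FAN_SHAPED_THRESHOLD = 0.005


def reference_area(area_series: np.ndarray) -> float:
    """1st percentile of the area time series (linear interpolation)."""
    a = np.asarray(area_series, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 frames for the reference area")
    return float(np.percentile(a, 1.0))


def goodness_of_fit(f_prot: np.ndarray) -> float:
    """Fraction of non-negative mass: sum(f+)/ (sum(f+) + sum(|f-|))."""
    v = np.asarray(f_prot, dtype=float)
    pos = v[v > 0].sum()
    neg = -v[v < 0].sum()
    total = pos + neg
    return 1.0 if total == 0.0 else float(pos / total)


def classify(weights: ModelWeights, threshold: float = FAN_SHAPED_THRESHOLD) -> str:
    """'fan-shaped' if w_APCSF is below the threshold, else 'amoeboid'.

    Ties (w_APCSF exactly at the threshold) go to amoeboid.
    """
    return "fan-shaped" if weights.w_apcsf < threshold else "amoeboid"


def _retraction_weights(design: np.ndarray, f: np.ndarray, tau: float):
    """Estimate (w_APCSF, w_AAF) >= 0 so the retractions are optimally captured.

    Because the protrusion component is non-negative and vanishes between
    protrusion events, the weighted sum of the two deterministic flows is the
    *lower envelope* of the local motion: f - (w1*phi_APCSF + w2*phi_AAF) =
    f_prot >= 0, with equality attained wherever no protrusion acts.  This is
    implemented as asymmetric (expectile-type) least squares: residuals where
    the flows fail to capture a retraction (f_prot < 0) carry full weight,
    positive residuals carry weight ``tau`` << 1.  The problem is convex and
    solved by iteratively reweighted NNLS; tau -> 0 approaches the hard
    envelope constraint, while a finite tau keeps the estimate stable against
    reconstruction noise in the local motion.
    """
    w = np.zeros(design.shape[1])
    for _ in range(200):
        r = f - design @ w
        sw = np.sqrt(np.where(r < 0.0, 1.0, tau))
        w_new, _ = nnls(design * sw[:, None], f * sw)
        if np.allclose(w_new, w, rtol=1e-12, atol=1e-14):
            w = w_new
            break
        w = w_new
    r = f - design @ w
    obj = float(np.sum(np.where(r < 0.0, 1.0, tau) * r * r))
    return (float(w[0]), float(w[1])), obj


@dataclass
class InferenceResults:
    """Estimates, kymographs and diagnostics of a fitted contour sequence."""

    weights: ModelWeights
    a_ref: float
    kymographs: dict[str, Kymograph]
    goodness: float
    label: str
    component_shares: np.ndarray  # (K, 3): |f|-share of prot/APCSF/AAF per frame
    objective: float  # residual of the retraction least squares
    flagged_frames: np.ndarray = field(default_factory=lambda: np.array([], int))
    vmdr: np.ndarray | None = None
    marker_theta: np.ndarray | None = None
    refinement_metric: str = "point-to-curve (nearest point on the next contour)"

    @property
    def f_prot(self) -> np.ndarray:
        return self.kymographs["f_prot"].values

    def summary(self) -> str:
        shares = self.component_shares.mean(axis=0)
        lines = [
            "Contour dynamics component inference",
            "=" * 52,
            f"frames                         {self.kymographs['f'].values.shape[0] + 1}",
            f"markers                        {self.kymographs['f'].values.shape[1]}",
            f"reference area A_ref [um^2]    {self.a_ref:10.3f}",
            f"w_prot  [um^2/s]               {self.weights.w_prot:10.4f}",
            f"w_APCSF [um^2/s]               {self.weights.w_apcsf:10.4f}",
            f"w_AAF   [um/s]                 {self.weights.w_aaf:10.4f}",
            f"goodness of fit (f_prot >= 0)  {self.goodness:10.4f}",
            f"locomotion type                {self.label:>10s}",
            f"mean |f| shares prot/APCSF/AAF "
            f"{shares[0]:.3f}/{shares[1]:.3f}/{shares[2]:.3f}",
            f"refinement metric              {self.refinement_metric}",
        ]
        return "\n".join(lines)


class ContourDynamicsModel:
    """Three-component contour-dynamics model bound to an observed track.

    Parameters
    ----------
    contours : list of (M, 2) point arrays or SmoothContour
        Ordered, closed per-frame outlines in um.
    dt : frame interval in s.
    gpr, n_markers, n_dense : contour-representation settings.
    lambda_reg : regularization of the virtual-marker mapping (um^2/s^2);
        kept equal to the simulation default so inferred and simulated
        kymographs share coordinates.
    """

    def __init__(
        self,
        contours,
        dt: float,
        gpr: GPRConfig | None = None,
        n_markers: int = 200,
        n_dense: int = 512,
        lambda_reg: float = 10.0,
        expectile_tau: float = 1e-3,
    ) -> None:
        if len(contours) < 2:
            raise ValueError("need at least 2 frames")
        self.dt = float(dt)
        self.gpr = gpr or GPRConfig()
        self.lambda_reg = lambda_reg
        self.expectile_tau = expectile_tau
        self.n_markers = n_markers
        self.n_dense = n_dense
        if isinstance(contours[0], SmoothContour):
            self.contours = list(contours)
        else:
            self.contours = [
                fit_contour(np.asarray(pts, float), self.gpr, n_markers, n_dense)
                for pts in contours
            ]

    @classmethod
    def from_track(cls, track: CellTrack, **kwargs) -> "ContourDynamicsModel":
        """Build the inverse model from a simulated track's contour sequence."""
        kwargs.setdefault("n_markers", track.contours[0].n_markers)
        if track.config is not None:
            kwargs.setdefault("lambda_reg", track.config.lambda_reg)
            kwargs.setdefault("gpr", track.config.gpr)
        return cls(track.contours, track.dt, **kwargs)

    @classmethod
    def from_stack(cls, path, dt: float | None = None, **kwargs) -> "ContourDynamicsModel":
        """Build the model from a plain-text contour stack file."""
        from .trackio import read_contour_stack

        frames, times = read_contour_stack(path)
        if dt is None:
            dt = float(times[1] - times[0])
        return cls(frames, dt, **kwargs)

    # ------------------------------------------------------------------
    def deterministic_components(
        self, weights: ModelWeights, chi: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(f_APCSF, f_AAF) kymographs from the observed geometry alone."""
        if chi is None:
            chi, _, _ = propagate_chain(self.contours, self.lambda_reg, self.dt)
        phi_c, phi_a = self._deterministic_shapes(chi, weights.a_ref)
        return weights.w_apcsf * phi_c, weights.w_aaf * phi_a

    def estimate_weights(self, refine: bool = True) -> ModelWeights:
        """Estimated ModelWeights of the full inversion (see :meth:`fit`)."""
        return self.fit(refine=refine).weights

    def _deterministic_shapes(self, chi: np.ndarray, a_ref: float):
        """Unit-weight APCSF/AAF speeds on the (K, N) marker grid."""
        K = len(self.contours) - 1
        n = chi.shape[1]
        phi_c = np.empty((K, n))
        phi_a = np.empty((K, n))
        for k in range(K):
            c = self.contours[k]
            th = chi[k]
            kappa = c.curvature(th)
            normals = c.normal(th)
            pos = c.position(th)
            phi_c[k] = -(kappa - TWO_PI / c.length)
            radial = np.einsum("ij,ij->i", pos - c.centroid, normals)
            phi_a[k] = -((c.area - a_ref) / (a_ref * c.length)) * radial
        return phi_c, phi_a

    def _local_motion(self, chi: np.ndarray) -> np.ndarray:
        K = len(self.contours) - 1
        f = np.empty((K, chi.shape[1]))
        for k in range(K):
            src = self.contours[k].position(chi[k])
            dst = self.contours[k + 1].position(chi[k + 1])
            normals = self.contours[k].normal(chi[k])
            f[k] = np.einsum("ij,ij->i", dst - src, normals) / self.dt
        return f

    def _refine_total_speed(self, chi: np.ndarray, f_init: np.ndarray):
        """Per-frame point-to-curve refinement of the total normal speed.

        For each marker the propagated point ``pos + f*dt*n`` is pulled onto
        the receiving contour by iterating nearest-point corrections along
        the marker normal; residuals decouple across markers, so this solves
        the least-squares refinement marker-wise and exactly.
        """
        K, n = f_init.shape
        f_ref = f_init.copy()
        flagged = []
        for k in range(K):
            c0, c1 = self.contours[k], self.contours[k + 1]
            pos = c0.position(chi[k])
            normals = c0.normal(chi[k])
            _, pos_g, _ = c1.dense_theta_cache()
            s = f_init[k] * self.dt
            ok = True
            for _ in range(3):
                p = pos + s[:, None] * normals
                d2 = ((p[:, None, :] - pos_g[None, :-1, :]) ** 2).sum(axis=2)
                q = pos_g[np.argmin(d2, axis=1)]
                corr = np.einsum("ij,ij->i", q - p, normals)
                s = s + corr
                if np.max(np.abs(corr)) > 0.25 * c1.length:
                    ok = False
                    break
            if ok:
                f_ref[k] = s / self.dt
            else:
                flagged.append(k)
        return f_ref, np.asarray(flagged, dtype=int)

    def fit(
        self,
        weights: ModelWeights | None = None,
        refine: bool = True,
        fan_threshold: float = FAN_SHAPED_THRESHOLD,
    ) -> InferenceResults:
        """Infer components and weights; returns an :class:`InferenceResults`."""
        areas = np.array([c.area for c in self.contours])
        if np.ptp(areas) == 0.0 and np.ptp(
            np.array([c.centroid for c in self.contours]), axis=0
        ).max() < 1e-12:
            raise ValueError("degenerate (static) contour stack")
        chi, vmdr_grid, _ = propagate_chain(self.contours, self.lambda_reg, self.dt)
        f_obs = self._local_motion(chi)
        a_ref = weights.a_ref if weights is not None else reference_area(areas)
        phi_c, phi_a = self._deterministic_shapes(chi, a_ref)

        if weights is None:
            design = np.column_stack([phi_c.ravel(), phi_a.ravel()])
            (w_apcsf, w_aaf), resid = _retraction_weights(
                design, f_obs.ravel(), self.expectile_tau
            )
            if w_aaf == 0.0:
                w_aaf = np.finfo(float).tiny  # ModelWeights requires > 0
        else:
            w_apcsf, w_aaf = weights.w_apcsf, weights.w_aaf
            resid = float(
                np.linalg.norm(
                    w_apcsf * phi_c.ravel()
                    + w_aaf * phi_a.ravel()
                    - np.minimum(f_obs, 0.0).ravel()
                )
            )

        f_apcsf = w_apcsf * phi_c
        f_aaf = w_aaf * phi_a
        f_prot = f_obs - f_apcsf - f_aaf

        flagged = np.array([], dtype=int)
        if refine:
            f_total, flagged = self._refine_total_speed(chi, f_apcsf + f_aaf + f_prot)
            f_prot = f_total - f_apcsf - f_aaf
        f_sum = f_prot + f_apcsf + f_aaf

        # standardize after refinement so the reported X_prot has unit variance
        lengths = np.array([c.length for c in self.contours[:-1]])
        x_unscaled = f_prot * lengths[:, None]  # = w_prot * X_prot
        if weights is None:
            w_prot = float(np.std(x_unscaled, ddof=1))
            if w_prot == 0.0:
                raise ValueError("degenerate stack: protrusion component is constant")
        else:
            w_prot = weights.w_prot
        x_prot = x_unscaled / w_prot if w_prot > 0 else np.zeros_like(x_unscaled)

        est = ModelWeights(w_prot=w_prot, w_apcsf=w_apcsf, w_aaf=w_aaf, a_ref=a_ref)
        times = self.dt * np.arange(len(self.contours) - 1)
        kymo = {
            "f": Kymograph(f_sum, times, "local motion f", "um/s"),
            "f_prot": Kymograph(f_prot, times, "protrusion component", "um/s"),
            "f_apcsf": Kymograph(f_apcsf, times, "APCSF component", "um/s"),
            "f_aaf": Kymograph(f_aaf, times, "AAF component", "um/s"),
            "x_prot": Kymograph(x_prot, times, "standardized protrusion process", "-"),
            "vmdr": Kymograph(vmdr_grid[:-1], times, "VMDR", "-"),
        }
        abs_tot = np.abs(f_prot) + np.abs(f_apcsf) + np.abs(f_aaf)
        denom = abs_tot.sum(axis=1)
        denom[denom == 0.0] = np.inf
        shares = np.column_stack(
            [
                np.abs(f_prot).sum(axis=1) / denom,
                np.abs(f_apcsf).sum(axis=1) / denom,
                np.abs(f_aaf).sum(axis=1) / denom,
            ]
        )
        return InferenceResults(
            weights=est,
            a_ref=a_ref,
            kymographs=kymo,
            goodness=goodness_of_fit(f_prot),
            label=classify(est, fan_threshold),
            component_shares=shares,
            objective=float(resid),
            flagged_frames=flagged,
            vmdr=vmdr_grid,
            marker_theta=chi,
        )


# ----------------------------------------------------------------------
# membrane fluorescence sampling


def membrane_intensity(
    images: np.ndarray,
    contours: list[SmoothContour],
    marker_theta: np.ndarray,
    pixel_size: float,
    semi_axes: tuple[float, float] = (1.0, 0.5),
    times: np.ndarray | None = None,
) -> Kymograph:
    """Mean pixel intensity inside tangent-aligned ellipses along the contour.

    For every marker an ellipse is centered at the marker position with its
    major semi-axis (um) along the contour tangent and minor semi-axis along
    the normal; the kymograph value is the mean intensity of the pixels whose
    centers fall inside.  Intensities are normalized per frame by the 99th
    percentile pixel value (robust to detector saturation) and clipped to
    [0, 1].  Ellipses without any covered pixel, or fully outside the image,
    yield NaN; zero semi-axes degrade to nearest-pixel sampling.
    """
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("images must be a (frames, H, W) stack")
    K = min(images.shape[0], len(contours), marker_theta.shape[0])
    n = marker_theta.shape[1]
    a, b = semi_axes
    out = np.full((K, n), np.nan)
    H, W = images.shape[1:]
    for k in range(K):
        img = images[k].astype(float)
        scale = np.percentile(img, 99.0)
        if scale <= 0:
            scale = 1.0
        c = contours[k]
        th = marker_theta[k]
        pos = c.position(th)
        tang = c.tangent(th)
        norm = c.normal(th)
        for i in range(n):
            px, py = pos[i] / pixel_size  # pixel units (col, row)
            if a == 0.0 or b == 0.0:
                col, row = int(round(px - 0.5)), int(round(py - 0.5))
                if 0 <= row < H and 0 <= col < W:
                    out[k, i] = min(img[row, col] / scale, 1.0)
                continue
            rad = max(a, b) / pixel_size
            c0, c1 = int(np.floor(px - rad - 1)), int(np.ceil(px + rad + 1))
            r0, r1 = int(np.floor(py - rad - 1)), int(np.ceil(py + rad + 1))
            c0, c1 = max(c0, 0), min(c1, W - 1)
            r0, r1 = max(r0, 0), min(r1, H - 1)
            if c0 > c1 or r0 > r1:
                continue  # ellipse fully outside: flagged missing (NaN)
            cols = np.arange(c0, c1 + 1)
            rows = np.arange(r0, r1 + 1)
            cx = (cols + 0.5) * pixel_size - pos[i, 0]
            cy = (rows + 0.5) * pixel_size - pos[i, 1]
            dx, dy = np.meshgrid(cx, cy)
            u = dx * tang[i, 0] + dy * tang[i, 1]
            v = dx * norm[i, 0] + dy * norm[i, 1]
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if not mask.any():
                continue
            out[k, i] = min(img[r0 : r1 + 1, c0 : c1 + 1][mask].mean() / scale, 1.0)
    t = times if times is not None else np.arange(K, dtype=float)
    return Kymograph(out, np.asarray(t, float)[:K], "relative fluorescence intensity", "-")


def correlate(kymo_a: Kymograph | np.ndarray, kymo_b: Kymograph | np.ndarray) -> float:
    """Pearson correlation over matched non-missing kymograph nodes."""
    va = kymo_a.values if isinstance(kymo_a, Kymograph) else np.asarray(kymo_a, float)
    vb = kymo_b.values if isinstance(kymo_b, Kymograph) else np.asarray(kymo_b, float)
    if va.shape != vb.shape:
        k = min(va.shape[0], vb.shape[0])
        va, vb = va[:k], vb[:k]
    mask = np.isfinite(va) & np.isfinite(vb)
    if mask.sum() < 2:
        raise ValueError("need at least 2 matched non-missing nodes")
    return float(np.corrcoef(va[mask], vb[mask])[0, 1])
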