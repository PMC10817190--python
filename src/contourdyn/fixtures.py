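"""Synthetic contour tracks and fluorescence stacks for tests and examples.

Everything here is generated programmatically and deterministically for a
fixed seed; the fixtures emulate the qualitative features of segmented
*D. discoideum* tracks (amoeboid: persistent zigzag; fan-shaped: persistent
kidney-shaped contour with a stable concave arc) without any microscopy data.
"""

from __future__ import annotations

import numpy as np

from .contour import circle_samples
from .hawkes import HawkesParams
from .simulate import ModelWeights, SimulationConfig, simulate
from .trackio import TrackArchive

__all__ = ["make_fixture", "star_points", "kidney_points", "ellipse_points"]

TWO_PI = 2.0 * np.pi


def star_points(
    n_arms: int = 5,
    mean_radius: float = 5.0,
    amplitude: float = 1.5,
    n_points: int = 120,
) -> np.ndarray:
    """Star polygon r(phi) = R + a*cos(n_arms*phi)."""
    phi = TWO_PI * np.arange(n_points) / n_points
    r = mean_radius + amplitude * np.cos(n_arms * phi)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def ellipse_points(a: float = 2.0, b: float = 1.0, n_points: int = 120) -> np.ndarray:
    phi = TWO_PI * np.arange(n_points) / n_points
    return np.column_stack([a * np.cos(phi), b * np.sin(phi)])


def kidney_points(
    scale: float = 7.0, dimple: float = 0.65, n_points: int = 140
) -> np.ndarray:
    """Dimpled limacon r = scale*(1 + dimple*cos(phi)): one concave arc.

    For 0.5 < dimple < 1 the curve is simple with a concave dent around
    phi = pi — the kidney shape characteristic of fan-shaped locomotion.
    """
    phi = TWO_PI * np.arange(n_points) / n_points
    r = scale * (1.0 + dimple * np.cos(phi))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def make_fixture(kind: str, seed: int = 0, **params):
    """Deterministic synthetic track archive (plus images for fluorescence).

    Kinds
    -----
    circle, ellipse, star : static (optionally noisy) contour stacks.
    translating_amoeboid : simulated polarized track with the reference
        parameter set (zigzag amoeboid motion).
    fan_shaped : rigid translation of a kidney-shaped contour at constant
        speed with small boundary noise.
    fluorescence_band : image stack with a Gaussian cross-section ridge along
        a given track's contours, amplitude proportional to a supplied
        per-marker field; returns ``(archive, images, pixel_size)``.
    """
    rng = np.random.default_rng(seed)
    if kind in ("circle", "ellipse", "star"):
        n_frames = int(params.get("n_frames", 5))
        dt = float(params.get("dt", 1.0))
        noise = float(params.get("noise", 0.0))
        if kind == "circle":
            base = circle_samples(params.get("area", 80.0), params.get("n_points", 100))
        elif kind == "ellipse":
            base = ellipse_points(params.get("a", 6.0), params.get("b", 3.0))
        else:
            base = star_points()
        contours = [base + noise * rng.standard_normal(base.shape)
                    for _ in range(n_frames)]
        return TrackArchive(
            contours=contours, times=dt * np.arange(n_frames),
            config={"kind": kind, "seed": seed, "noise": noise},
        )
    if kind == "translating_amoeboid":
        cfg = SimulationConfig(
            T=float(params.get("T", 150.0)),
            dt=float(params.get("dt", 0.5)),
            n_markers=int(params.get("n_markers", 100)),
            seed=seed,
            n_dense=int(params.get("n_dense", 384)),
            hawkes=HawkesParams(r_pol=float(params.get("r_pol", 0.5))),
        )
        track = simulate(cfg, ModelWeights())
        return TrackArchive.from_cell_track(track)
    if kind == "fan_shaped":
        n_frames = int(params.get("n_frames", 40))
        dt = float(params.get("dt", 4.0))
        speed = float(params.get("speed", 0.1))  # um/s, toward the round front
        noise = float(params.get("noise", 0.05))
        base = kidney_points(n_points=int(params.get("n_points", 140)))
        contours = []
        for k in range(n_frames):
            drift = np.array([speed * dt * k, 0.0])
            contours.append(base + drift + noise * rng.standard_normal(base.shape))
        return TrackArchive(
            contours=contours, times=dt * np.arange(n_frames),
            config={"kind": kind, "seed": seed, "speed_um_s": speed, "noise": noise},
        )
    if kind == "fluorescence_band":
        archive: TrackArchive = params["archive"]
        amplitude = np.asarray(params["amplitude"], dtype=float)  # (K, N) or (N,)
        pixel_size = float(params.get("pixel_size", 0.2))
        width = float(params.get("width", 0.6))  # ridge cross-section sigma, um
        pad = 4.0
        allpts = np.vstack(archive.contours)
        lo = allpts.min(axis=0) - pad
        hi = allpts.max(axis=0) + pad
        W = int(np.ceil((hi[0] - lo[0]) / pixel_size))
        H = int(np.ceil((hi[1] - lo[1]) / pixel_size))
        K = len(archive.contours)
        if amplitude.ndim == 1:
            amplitude = np.tile(amplitude, (K, 1))
        images = np.zeros((K, H, W))
        xs = lo[0] + (np.arange(W) + 0.5) * pixel_size
        ys = lo[1] + (np.arange(H) + 0.5) * pixel_size
        for k in range(K):
            pts = archive.contours[k]
            amp = amplitude[k]
            if amp.size != pts.shape[0]:
                amp = np.interp(
                    np.linspace(0, 1, pts.shape[0], endpoint=False),
                    np.linspace(0, 1, amp.size, endpoint=False), amp,
                )
            img = images[k]
            half = int(np.ceil(3.0 * width / pixel_size))
            for (px, py), a in zip(pts, amp):
                ci = int((px - lo[0]) / pixel_size)
                ri = int((py - lo[1]) / pixel_size)
                c0, c1 = max(ci - half, 0), min(ci + half + 1, W)
                r0, r1 = max(ri - half, 0), min(ri + half + 1, H)
                if c0 >= c1 or r0 >= r1:
                    continue
                dx = xs[c0:c1] - px
                dy = ys[r0:r1] - py
                g = np.exp(-(dx[None, :] ** 2 + dy[:, None] ** 2) / (2 * width**2))
                img[r0:r1, c0:c1] += a * g
        # contours were translated into the image frame used above
        shifted = [pts - lo for pts in archive.contours]
        out = TrackArchive(contours=shifted, times=archive.times.copy(),
                           config=dict(archive.config))
        out.config.update(pixel_size_um=pixel_size, ridge_width_um=width)
        return out, images, pixel_size
    raise ValueError(f"unknown fixture kind: {kind!r}")
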