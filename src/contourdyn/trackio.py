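"""Plain-text track archives.

A track archive is a directory holding, at most:

* ``contours.tsv`` — the contour stack: one row per marker per frame,
  columns ``frame  time_s  marker_index  x_um  y_um``;
* ``fields.tsv`` — per-step component fields, columns ``frame  marker_index
  f  f_prot  f_apcsf  f_aaf  x_prot  vmdr`` (units um/s for the speeds);
* ``events.tsv`` — the protrusion point events, columns ``t_s  theta_rad
  generation  parent_index``;
* ``config.txt`` — flat ``key=value`` manifest echoing every parameter, the
  seed and the software version.

All files are tab-separated with a versioned comment line followed by one
column-header line, and round-trip at full float precision ('%.17g').
A legacy stack holding only ``contours.tsv`` loads as a partial archive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .hawkes import EventList, HawkesParams
from .simulate import CellTrack, GPRConfig, ModelWeights, SimulationConfig

__all__ = ["TrackArchive", "write_track", "read_track",
           "write_contour_stack", "read_contour_stack",
           "read_image_stack", "write_image_stack"]

FORMAT_VERSION = 1
FIELD_COLUMNS = ["f", "f_prot", "f_apcsf", "f_aaf", "x_prot", "vmdr"]
_FMT = "%.17g"


@dataclass
class TrackArchive:
    """In-memory image of a track archive directory."""

    contours: list[np.ndarray]  # per frame, (N_k, 2) um
    times: np.ndarray  # (K+1,) s
    fields: dict[str, np.ndarray] = field(default_factory=dict)  # (K, N) each
    events: EventList | None = None
    config: dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_cell_track(cls, track: CellTrack) -> "TrackArchive":
        contours = [track.marker_positions(k) for k in range(track.n_frames)]
        flds = {
            "f": track.f,
            "f_prot": track.f_prot,
            "f_apcsf": track.f_apcsf,
            "f_aaf": track.f_aaf,
            "x_prot": track.x_prot,
            "vmdr": track.vmdr[:-1],
        }
        cfg: dict[str, object] = {"format_version": FORMAT_VERSION,
                                  "software_version": _pkg_version}
        if track.config is not None:
            c = track.config
            cfg.update(
                dt=c.dt, T=c.T, N=c.n_markers, lambda_reg=c.lambda_reg,
                seed=c.seed, n_dense=c.n_dense,
                r_cont=c.gpr.r_cont, sigma_noise=c.gpr.sigma_noise,
                lambda0=c.hawkes.lambda0, alpha=c.hawkes.alpha,
                beta=c.hawkes.beta, kappa_M=c.hawkes.kappa_m,
                r_pol=c.hawkes.r_pol, c_s=c.hawkes.c_s,
            )
        if track.weights is not None:
            w = track.weights
            cfg.update(w_prot=w.w_prot, w_apcsf=w.w_apcsf, w_aaf=w.w_aaf,
                       A_ref=w.a_ref)
        return cls(contours=contours, times=track.times.copy(), fields=flds,
                   events=track.events, config=cfg)

    def to_model_inputs(self):
        return self.contours, self.times


def _header(kind: str) -> str:
    return f"# contourdyn {kind} format_version={FORMAT_VERSION}\n"


def write_contour_stack(path: str, contours, times) -> None:
    with open(path, "w") as fh:
        fh.write(_header("contour_stack"))
        fh.write("frame\ttime_s\tmarker_index\tx_um\ty_um\n")
        for k, (pts, t) in enumerate(zip(contours, times)):
            for i, (x, y) in enumerate(np.asarray(pts, float)):
                fh.write(f"{k}\t{_FMT % t}\t{i}\t{_FMT % x}\t{_FMT % y}\n")


def _parse_table(path: str, required: list[str]) -> tuple[dict, int]:
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    if start >= len(lines):
        raise ValueError(f"{path}: no header line found")
    cols = lines[start].rstrip("\n").split("\t")
    for col in required:
        if col not in cols:
            raise ValueError(f"{path}: missing required column '{col}'")
    data = {c: [] for c in cols}
    for ln, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(cols):
            raise ValueError(f"{path}:{ln}: expected {len(cols)} fields, got {len(parts)}")
        for c, v in zip(cols, parts):
            data[c].append(v)
    return data, start


def read_contour_stack(path: str) -> tuple[list[np.ndarray], np.ndarray]:
    data, _ = _parse_table(path, ["frame", "time_s", "marker_index", "x_um", "y_um"])
    frame = np.asarray(data["frame"], dtype=int)
    t = np.asarray(data["time_s"], dtype=float)
    xy = np.column_stack([np.asarray(data["x_um"], float),
                          np.asarray(data["y_um"], float)])
    uniq = np.unique(frame)
    if not np.array_equal(uniq, np.arange(uniq.size)):
        raise ValueError(f"{path}: frames must be consecutive starting at 0")
    # frames must be non-decreasing in file order (strictly increasing blocks)
    if np.any(np.diff(frame) < 0):
        bad = int(np.flatnonzero(np.diff(frame) < 0)[0]) + 3
        raise ValueError(f"{path}:{bad}: non-monotone frame order")
    contours, times = [], []
    for k in uniq:
        m = frame == k
        contours.append(xy[m])
        times.append(t[m][0])
    return contours, np.asarray(times)


def write_track(path: str, archive: TrackArchive) -> None:
    """Write the archive directory (created if needed); lossless round-trip."""
    os.makedirs(path, exist_ok=True)
    write_contour_stack(os.path.join(path, "contours.tsv"),
                        archive.contours, archive.times)
    if archive.fields:
        K, n = archive.fields[FIELD_COLUMNS[0]].shape
        with open(os.path.join(path, "fields.tsv"), "w") as fh:
            fh.write(_header("fields"))
            fh.write("frame\tmarker_index\t" + "\t".join(FIELD_COLUMNS) + "\n")
            for k in range(K):
                for i in range(n):
                    vals = "\t".join(
                        _FMT % archive.fields[c][k, i] for c in FIELD_COLUMNS
                    )
                    fh.write(f"{k}\t{i}\t{vals}\n")
    if archive.events is not None:
        ev = archive.events
        with open(os.path.join(path, "events.tsv"), "w") as fh:
            fh.write(_header("events"))
            fh.write("t_s\ttheta_rad\tgeneration\tparent_index\n")
            for i in range(len(ev)):
                fh.write(
                    f"{_FMT % ev.t[i]}\t{_FMT % ev.theta[i]}\t"
                    f"{ev.generation[i]}\t{ev.parent[i]}\n"
                )
    if archive.config:
        with open(os.path.join(path, "config.txt"), "w") as fh:
            fh.write(_header("config"))
            for key, val in archive.config.items():
                fh.write(f"{key}={val}\n")


def read_track(path: str) -> TrackArchive:
    """Read an archive directory; missing optional tables yield a partial archive."""
    stack = os.path.join(path, "contours.tsv")
    if not os.path.exists(stack):
        raise FileNotFoundError(f"{stack}: contour stack is required")
    contours, times = read_contour_stack(stack)
    archive = TrackArchive(contours=contours, times=times)
    fpath = os.path.join(path, "fields.tsv")
    if os.path.exists(fpath):
        data, _ = _parse_table(fpath, ["frame", "marker_index"] + FIELD_COLUMNS)
        frame = np.asarray(data["frame"], int)
        marker = np.asarray(data["marker_index"], int)
        K, n = frame.max() + 1, marker.max() + 1
        for c in FIELD_COLUMNS:
            grid = np.empty((K, n))
            grid[frame, marker] = np.asarray(data[c], float)
            archive.fields[c] = grid
    epath = os.path.join(path, "events.tsv")
    if os.path.exists(epath):
        data, _ = _parse_table(epath, ["t_s", "theta_rad", "generation", "parent_index"])
        archive.events = EventList(
            t=np.asarray(data["t_s"], float),
            theta=np.asarray(data["theta_rad"], float),
            generation=np.asarray(data["generation"], int),
            parent=np.asarray(data["parent_index"], int),
        )
    cpath = os.path.join(path, "config.txt")
    if os.path.exists(cpath):
        with open(cpath) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                archive.config[key] = val
    return archive


def read_image_stack(path: str) -> np.ndarray:
    """Read a (multi-page) TIFF fluorescence stack as a (frames, H, W) array."""
    import tifffile

    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    return images


def write_image_stack(path: str, images: np.ndarray) -> None:
    """Write a (frames, H, W) array as a multi-page TIFF (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(images, dtype=np.float32))


def config_from_manifest(manifest: dict) -> tuple[SimulationConfig, ModelWeights]:
    """Rebuild simulation config and weights from a parsed manifest."""
    g = lambda k, d: float(manifest.get(k, d))
    gpr = GPRConfig(r_cont=g("r_cont", 0.6), sigma_noise=g("sigma_noise", 0.05))
    hp = HawkesParams(
        lambda0=g("lambda0", 1.0), alpha=g("alpha", 0.4), beta=g("beta", 0.5),
        kappa_m=g("kappa_M", 100.0), r_pol=g("r_pol", 0.0), c_s=g("c_s", 1.0),
    )
    cfg = SimulationConfig(
        dt=g("dt", 0.5), T=g("T", 500.0), n_markers=int(g("N", 200)),
        lambda_reg=g("lambda_reg", 10.0), seed=int(g("seed", 0)),
        gpr=gpr, hawkes=hp, n_dense=int(g("n_dense", 512)),
    )
    weights = ModelWeights(
        w_prot=g("w_prot", 7.5), w_apcsf=g("w_apcsf", 0.1),
        w_aaf=g("w_aaf", 1.0), a_ref=g("A_ref", 80.0),
    )
    return cfg, weights
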