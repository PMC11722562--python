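"""Spatial-temporal map (STMap) construction and I/O.

An STMap compresses a facial video into an image: the face region of
interest (ROI) is partitioned into a grid of blocks, each block's
per-channel spatial mean is computed per frame, and the resulting time
series are stacked as rows. The map is (rows*cols) x T x 3, each row
min-max normalized to [0, 1] per channel over the temporal window, so the
pulsatile color signal survives while absolute intensity is discarded.

Face detection and landmark alignment are outside the scope of this
package; callers pass the ROI rectangle explicitly (the synthetic generator
in :mod:`multiphys.synthetic_data` bypasses video entirely).

Signals from heterogeneous sources are aligned by cubic-spline resampling
onto a uniform 30 Hz grid before map construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from PIL import Image
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, zoom

__all__ = [
    "FrameSequence",
    "STMap",
    "AugmentConfig",
    "frames_to_stmap",
    "load_frame_dir",
    "resample_30hz",
    "augment",
    "resize_stmap",
    "window_stmap",
    "save_sample",
    "load_sample",
    "export_png",
    "write_vitals_csv",
    "read_vitals_csv",
]

TARGET_RATE = 30.0


@dataclass
class FrameSequence:
    """RGB frame stack with per-frame timestamps (seconds)."""

    frames: np.ndarray  # (T, H, W, 3) uint8
    timestamps: np.ndarray  # (T,) strictly increasing

    def __post_init__(self):
        f = np.asarray(self.frames)
        t = np.asarray(self.timestamps, dtype=float)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {f.shape}")
        if f.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if t.shape != (f.shape[0],) or np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing, one per frame")
        self.frames = f
        self.timestamps = t


@dataclass
class STMap:
    """H x W x 3 map in [0, 1]; W is the temporal axis at `rate` Hz."""

    values: np.ndarray
    rate: float = TARGET_RATE
    roi_count: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[-1] != 3:
            raise ValueError(f"STMap must be (H, W, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("STMap contains non-finite values")
        self.values = v
        if self.roi_count == 0:
            self.roi_count = v.shape[0]

    @property
    def shape(self):
        return self.values.shape


@dataclass
class AugmentConfig:
    """Color jitter and blur augmentation parameters.

    jitter_* are maximum relative perturbations (factors drawn uniformly in
    [1-j, 1+j]); blur sigma is drawn uniformly from `blur_sigma_range`.
    """

    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1
    jitter_saturation: float = 0.1
    blur_sigma_range: tuple = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        for j in (self.jitter_brightness, self.jitter_contrast, self.jitter_saturation):
            if not 0.0 <= j <= 0.5:
                raise ValueError("jitter perturbations must lie in [0, 0.5]")
        lo, hi = self.blur_sigma_range
        if lo < 0 or hi < lo:
            raise ValueError("blur_sigma_range must be 0 <= lo <= hi")


def frames_to_stmap(fs: FrameSequence, grid: tuple = (8, 8), roi: tuple | None = None) -> STMap:
    """Build an STMap from frames by block-averaging an ROI grid.

    `roi` is (top, left, height, width) in pixels, defaulting to the full
    frame; `grid` = (rows, cols) must tile the ROI exactly. Each of the
    rows*cols blocks contributes one STMap row: its per-channel spatial mean
    per frame, min-max normalized over time. A block whose temporal range is
    zero in some channel carries no signal; that row-channel is set to the
    neutral value 0.5 and a warning is emitted.
    """
    T, H, W, _ = fs.frames.shape
    if roi is None:
        roi = (0, 0, H, W)
    top, left, rh, rw = roi
    rows, cols = grid
    if rh % rows or rw % cols:
        raise ValueError(f"grid {grid} does not tile ROI of size {rh}x{rw}")
    bh, bw = rh // rows, rw // cols
    patch = fs.frames[:, top : top + rh, left : left + rw, :].astype(float)
    # (T, rows, bh, cols, bw, 3) -> block means (T, rows*cols, 3)
    blocks = patch.reshape(T, rows, bh, cols, bw, 3).mean(axis=(2, 4)).reshape(T, rows * cols, 3)
    raw = blocks.transpose(1, 0, 2)  # (rows*cols, T, 3)
    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    rng_span = hi - lo
    flat = rng_span == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant block-channel(s); set to 0.5", stacklevel=2
        )
    rng_span = np.where(flat, 1.0, rng_span)
    values = (raw - lo) / rng_span
    values = np.where(np.broadcast_to(flat, values.shape), 0.5, values)
    # nominal rate from the timestamp span
    rate = (T - 1) / (fs.timestamps[-1] - fs.timestamps[0])
    return STMap(values=values, rate=rate, roi_count=rows * cols)


def load_frame_dir(path, fps: float = TARGET_RATE, timestamps_csv=None) -> FrameSequence:
    """Read a directory of PNG/JPEG frames (sorted by filename) as a FrameSequence.

    Timestamps come from ``timestamps_csv`` (single column ``t_sec``, one row
    per frame) when given, else from a uniform ``fps`` grid.
    """
    from pathlib import Path as _P

    files = sorted(p for p in _P(path).iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if len(files) < 2:
        raise ValueError(f"need at least 2 frame images in {path}")
    frames = np.stack([np.asarray(Image.open(f).convert("RGB")) for f in files])
    if timestamps_csv is not None:
        t = pd.read_csv(timestamps_csv)["t_sec"].to_numpy(dtype=float)
    else:
        t = np.arange(len(files)) / fps
    return FrameSequence(frames=frames, timestamps=t)


def window_stmap(x: STMap, width: int, overlap: int = 0) -> list:
    """Split a long map into fixed-width temporal windows (default non-overlapping).

    Trailing frames that do not fill a window are dropped. Each window keeps
    the source rate and roi_count.
    """
    if not 0 <= overlap < width:
        raise ValueError("overlap must satisfy 0 <= overlap < width")
    step = width - overlap
    out = []
    for start in range(0, x.values.shape[1] - width + 1, step):
        out.append(STMap(values=x.values[:, start : start + width].copy(),
                         rate=x.rate, roi_count=x.roi_count))
    return out


def resample_30hz(timestamps, values, rate: float = TARGET_RATE):
    """Cubic-spline resample a timestamped series onto a uniform grid.

    Returns ``(grid_times, resampled)``. The grid spans the original time
    range at `rate` Hz (30 Hz by default), endpoints included; the spline
    interpolates the samples exactly, so an input already on the grid is
    returned unchanged (up to floating point). Works on 1-D series or
    (T, ...) arrays along the first axis.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 4:
        raise ValueError("need at least 4 timestamped samples for cubic resampling")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    if v.shape[0] != t.size:
        raise ValueError(f"values first axis {v.shape[0]} != {t.size} timestamps")
    spline = CubicSpline(t, v, axis=0)
    n_out = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / rate
    return grid, spline(grid)


def augment(x: STMap, cfg: AugmentConfig) -> STMap:
    """Color jitter (brightness, contrast, saturation) + Gaussian blur.

    Factors are drawn from `cfg.seed`, so the same configuration reproduces
    the same augmented map. The output is clipped to [0, 1]; shape, rate and
    roi_count are unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    v = x.values.copy()
    b = rng.uniform(1 - cfg.jitter_brightness, 1 + cfg.jitter_brightness)
    c = rng.uniform(1 - cfg.jitter_contrast, 1 + cfg.jitter_contrast)
    s = rng.uniform(1 - cfg.jitter_saturation, 1 + cfg.jitter_saturation)
    sigma = rng.uniform(*cfg.blur_sigma_range)
    v = v * b
    mean = v.mean()
    v = (v - mean) * c + mean
    gray = v.mean(axis=-1, keepdims=True)
    v = (v - gray) * s + gray
    if sigma > 0:
        v = gaussian_filter(v, sigma=(sigma, sigma, 0))
    return STMap(values=np.clip(v, 0.0, 1.0), rate=x.rate, roi_count=x.roi_count)


def resize_stmap(x: STMap, shape: tuple) -> STMap:
    """Bilinear resize to (H, W) for a fixed network input size."""
    H, W = shape
    zh, zw = H / x.values.shape[0], W / x.values.shape[1]
    v = zoom(x.values, (zh, zw, 1), order=1)
    return STMap(values=np.clip(v, 0.0, 1.0), rate=x.rate * zw, roi_count=x.roi_count)


# ---------------------------------------------------------------------------
# container I/O


def save_sample(path, stmap: STMap, hr=np.nan, spo2=np.nan, rr=np.nan,
                bvp=None, seed: int = -1):
    """Write one sample to HDF5: /stmap, /labels, /bvp, attrs rate/seed."""
    with h5py.File(path, "w") as f:
        f.create_dataset("stmap", data=stmap.values.astype(np.float32))
        f.create_dataset("labels", data=np.array([hr, spo2, rr], dtype=np.float32))
        if bvp is not None:
            f.create_dataset("bvp", data=np.asarray(bvp, dtype=np.float32))
        f.attrs["rate"] = stmap.rate
        f.attrs["seed"] = seed
        f.attrs["roi_count"] = stmap.roi_count


def load_sample(path):
    """Read a sample written by :func:`save_sample`.

    Returns ``(STMap, dict)`` with keys hr, spo2, rr, bvp, seed.
    """
    with h5py.File(path, "r") as f:
        values = f["stmap"][...].astype(float)
        hr, spo2, rr = (float(x) for x in f["labels"][...])
        bvp = f["bvp"][...].astype(float) if "bvp" in f else None
        m = STMap(values=values, rate=float(f.attrs["rate"]),
                  roi_count=int(f.attrs.get("roi_count", values.shape[0])))
        return m, {"hr": hr, "spo2": spo2, "rr": rr, "bvp": bvp,
                   "seed": int(f.attrs.get("seed", -1))}


def export_png(path, stmap: STMap):
    """8-bit PNG of the map, each channel scaled to its own full range."""
    v = stmap.values
    lo = v.min(axis=(0, 1), keepdims=True)
    hi = v.max(axis=(0, 1), keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    img = np.round(255 * (v - lo) / span).astype(np.uint8)
    Image.fromarray(img, mode="RGB").save(path)


def write_vitals_csv(path, t_sec, bvp, hr=None, spo2=None, rr=None):
    df = pd.DataFrame({"t_sec": np.asarray(t_sec, dtype=float),
                       "bvp": np.asarray(bvp, dtype=float)})
    for name, col in (("hr", hr), ("spo2", spo2), ("rr", rr)):
        if col is not None:
            df[name] = col
    df.to_csv(path, index=False)


def read_vitals_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "t_sec" not in df.columns or "bvp" not in df.columns:
        raise ValueError("vitals CSV must have columns t_sec and bvp")
    return df
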