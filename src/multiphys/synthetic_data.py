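"""Synthetic STMap generator with known ground-truth vitals.

The generator emulates the signal structure a camera-based pulse estimator
relies on, without rendering any video:

* a pulsatile blood-volume-pulse (BVP) waveform: a small harmonic series at
  the heart-rate fundamental ``f_hr = hr/60`` Hz;
* respiratory coupling: the pulse is jointly amplitude-modulated (AM) and
  frequency-modulated (FM) at the respiratory frequency ``f_rr = rr/60``,
  and a low-frequency baseline wander at ``f_rr`` is added to every row, so
  respiration rate is recoverable from the same map;
* an SpO2-dependent channel-ratio structure: the red and blue AC/DC ratios
  are set so that the classical pulse-oximetry ratio-of-ratios
  ``R = (AC_R/DC_R) / (AC_B/DC_B)`` satisfies ``spo2 = 110 - 25 R``. This
  empirical two-wavelength calibration is a generator-internal convention
  that makes SpO2 learnable from the maps, not a property of any camera;
* noise: i.i.d. Gaussian noise (scaled to the green AC amplitude) plus a
  sinusoidal illumination drift shared across rows.

Rows get linearly spaced phase offsets, mimicking pulse-transit delays
across facial regions. Everything is drawn from ``seed``; a configuration
plus a draw index fully determines the sample. The module also provides an
independent spectral oracle (Welch periodogram argmax) used to verify that
the labels really are encoded in the maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import welch

from .heads_losses import VitalsBundle
from .stmap import STMap

__all__ = [
    "SynthConfig",
    "SyntheticSample",
    "make_bvp",
    "make_stmap_sample",
    "make_dataset",
    "raw_rows",
    "spo2_to_ratio",
    "spectral_oracle_hr",
    "spectral_oracle_rr",
]

HR_BAND = (0.7, 3.0)  # Hz, 42..180 beats/min
RR_BAND = (0.1, 0.5)  # Hz, 6..30 breaths/min


@dataclass
class SynthConfig:
    """Study conditions for synthetic STMap generation.

    Defaults describe a resting adult population imaged at 30 frames/s for
    one 256-frame analysis window: heart rate 50-140 beats/min, respiration
    8-24 breaths/min, SpO2 85-100%. The pulse carries three harmonics with
    the physiological 1 : 0.5 : 0.2 amplitude decay; respiratory AM and FM
    depths of 10% and 3% are typical of resting sinus arrhythmia. noise_sd
    is the Gaussian noise standard deviation as a fraction of the green-
    channel AC amplitude (0.3 = moderate camera noise); drift_amplitude
    scales a 0.05-0.15 Hz illumination wander relative to the same AC
    amplitude.
    """

    n_samples: int = 50
    duration_s: float = 256.0 / 30.0
    rate: float = 30.0
    hr_range: tuple = (50.0, 140.0)
    rr_range: tuple = (8.0, 24.0)
    spo2_range: tuple = (85.0, 100.0)
    pulse_harmonic_weights: tuple = (1.0, 0.5, 0.2)
    am_depth: float = 0.10
    fm_depth: float = 0.03
    noise_sd: float = 0.3
    drift_amplitude: float = 0.5
    seed: int = 0
    n_rows: int = 64
    width: int = 256

    def __post_init__(self):
        bounds = VitalsBundle.PHYSIO_BOUNDS
        for name, rng_ in (("hr", self.hr_range), ("spo2", self.spo2_range), ("rr", self.rr_range)):
            lo, hi = bounds[name]
            if rng_[0] < lo or rng_[1] > hi or rng_[0] > rng_[1]:
                raise ValueError(f"{name}_range {rng_} outside physiological bounds [{lo}, {hi}]")
        if self.rate * self.duration_s + 1e-9 < self.width:
            raise ValueError("rate * duration_s must cover the map width")

    @property
    def n_frames(self) -> int:
        return int(round(self.rate * self.duration_s))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticSample:
    """One generated STMap with its ground truth and provenance."""

    stmap: STMap
    truth: VitalsBundle
    seed: int
    draw_index: int
    config_hash: str
    oracle_hr: float = np.nan  # generator self-check estimate, beats/min


def make_bvp(hr: float, rr: float, cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Standardized pulse waveform at heart rate `hr` with respiratory AM/FM.

    The instantaneous pulse frequency is ``f_hr (1 + fm_depth sin(2 pi f_rr t))``;
    integrating gives the phase ``2 pi f_hr (t + fm_depth (1 - cos(2 pi f_rr t))
    / (2 pi f_rr))``. Harmonics k = 1..K with weights ``pulse_harmonic_weights``
    are summed at k times that phase (random phase offsets per harmonic when an
    rng is supplied), then the envelope ``1 + am_depth sin(2 pi f_rr t)`` is
    applied and the result standardized to zero mean, unit variance.
    """
    if not cfg.hr_range[0] <= hr <= cfg.hr_range[1]:
        raise ValueError(f"hr={hr} outside configured range {cfg.hr_range}")
    if not cfg.rr_range[0] <= rr <= cfg.rr_range[1]:
        raise ValueError(f"rr={rr} outside configured range {cfg.rr_range}")
    f_hr, f_rr = hr / 60.0, rr / 60.0
    t = np.arange(cfg.n_frames) / cfg.rate
    warped = t + cfg.fm_depth * (1.0 - np.cos(2 * np.pi * f_rr * t)) / (2 * np.pi * f_rr)
    sig = np.zeros_like(t)
    for k, a_k in enumerate(cfg.pulse_harmonic_weights, start=1):
        phi_k = rng.uniform(0, 2 * np.pi) if (rng is not None and k > 1) else 0.0
        sig += a_k * np.sin(2 * np.pi * k * f_hr * warped + phi_k)
    sig *= 1.0 + cfg.am_depth * np.sin(2 * np.pi * f_rr * t)
    sig -= sig.mean()
    sig /= sig.std()
    return sig


# channel optics: typical skin DC reflectance and the green AC strength;
# red/blue AC follow from the ratio-of-ratios encoding of SpO2
_DC = np.array([0.60, 0.50, 0.45])  # R, G, B
_GREEN_AC_REL = 0.05  # AC/DC of green
_BLUE_AC_REL = 0.03  # AC/DC of blue


def spo2_to_ratio(spo2: float) -> float:
    """Invert the calibration spo2 = 110 - 25 R."""
    r = (110.0 - spo2) / 25.0
    if r <= 0:
        raise ValueError(f"spo2={spo2} outside the ratio-of-ratios mapping range")
    return r


def make_stmap_sample(cfg: SynthConfig, draw_index: int = 0) -> SyntheticSample:
    """Generate one labelled STMap.

    Vitals are drawn uniformly from the configured ranges with a stream
    seeded by ``(cfg.seed, draw_index)``. Per row and channel the raw signal
    is ``DC_c (1 + ac_rel_c * bvp(t - phase_row)) + baseline + drift +
    noise``; rows are then min-max normalized per channel into the final
    map, exactly as real video rows would be.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, draw_index]))
    hr = rng.uniform(*cfg.hr_range)
    rr = rng.uniform(*cfg.rr_range)
    spo2 = rng.uniform(*cfg.spo2_range)
    raw, bvp, _ = raw_rows(cfg, hr, rr, spo2, rng)

    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    values = (raw - lo) / (hi - lo)
    stmap = STMap(values=values, rate=cfg.rate, roi_count=cfg.n_rows)
    truth = VitalsBundle(hr=hr, spo2=spo2, rr=rr, bvp=bvp).validate_physiological()
    oracle = spectral_oracle_hr(stmap, cfg.rate, nfft=8192)
    if cfg.noise_sd == 0 and abs(oracle - hr) > 3.0:
        raise RuntimeError(
            f"generator self-check failed: oracle HR {oracle:.1f} vs truth {hr:.1f}"
        )
    return SyntheticSample(stmap=stmap, truth=truth, seed=cfg.seed,
                           draw_index=draw_index, config_hash=cfg.config_hash(),
                           oracle_hr=oracle)


def raw_rows(cfg: SynthConfig, hr: float, rr: float, spo2: float,
             rng: np.random.Generator):
    """Raw (pre-normalization) row signals, (n_rows, n_frames, 3).

    Returns ``(rows, bvp, aux)`` where ``aux`` carries the generation
    components (per-channel DC and relative AC, baseline, drift, per-row
    delays) so the channel-ratio encoding can be audited from the raw
    signals.
    """
    r_ratio = spo2_to_ratio(spo2)
    ac_rel = np.array([r_ratio * _BLUE_AC_REL, _GREEN_AC_REL, _BLUE_AC_REL])
    bvp = make_bvp(hr, rr, cfg, rng)
    t = np.arange(cfg.n_frames) / cfg.rate
    f_rr = rr / 60.0
    # per-row phase offsets: pulse transit delays up to ~100 ms across the face
    delays = np.linspace(0.0, 0.1, cfg.n_rows)
    green_ac_abs = _DC[1] * _GREEN_AC_REL
    baseline = 0.3 * green_ac_abs * np.sin(2 * np.pi * f_rr * t + rng.uniform(0, 2 * np.pi))
    drift_f = rng.uniform(0.05, 0.15)
    drift = cfg.drift_amplitude * green_ac_abs * np.sin(2 * np.pi * drift_f * t + rng.uniform(0, 2 * np.pi))
    rows = np.empty((cfg.n_rows, cfg.n_frames, 3))
    for i, d in enumerate(delays):
        shifted = np.interp(t - d, t, bvp, period=None)
        noise = cfg.noise_sd * green_ac_abs * rng.standard_normal((cfg.n_frames, 3))
        rows[i] = _DC * (1.0 + np.outer(shifted, ac_rel)) + (baseline + drift)[:, None] + noise
    aux = {"dc": _DC.copy(), "ac_rel": ac_rel, "baseline": baseline,
           "drift": drift, "delays": delays}
    return rows, bvp, aux


def make_dataset(cfg: SynthConfig):
    """List of ``cfg.n_samples`` samples drawn at indices 0..n-1."""
    return [make_stmap_sample(cfg, i) for i in range(cfg.n_samples)]


def _band_peak(sig: np.ndarray, rate: float, band: tuple, nfft: int | None):
    f, p = welch(sig, fs=rate, nperseg=len(sig), nfft=nfft, detrend="constant")
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} contains no spectral bins at rate {rate}")
    return f[mask][np.argmax(p[mask])]


def spectral_oracle_hr(stmap_or_bvp, rate: float, band: tuple = HR_BAND,
                       nfft: int | None = None) -> float:
    """Heart rate (beats/min) as 60x the in-band Welch spectral peak.

    For an STMap input the row-channel spectra are averaged before the
    argmax; for a 1-D signal the periodogram is used directly. With the
    default ``nfft`` (the signal length) the estimate is quantized to the
    FFT bin width ``rate/len`` Hz; pass a larger ``nfft`` to zero-pad for
    sub-bin resolution.
    """
    if isinstance(stmap_or_bvp, STMap):
        v = stmap_or_bvp.values
        sig = v.reshape(v.shape[0], v.shape[1], 3)
        flat = sig.transpose(0, 2, 1).reshape(-1, v.shape[1])
        if flat.shape[1] < 64:
            raise ValueError("sequence too short for spectral estimation (need >= 64)")
        f, p = welch(flat, fs=rate, nperseg=flat.shape[1], nfft=nfft,
                     detrend="constant", axis=-1)
        p = p.mean(axis=0)
        mask = (f >= band[0]) & (f <= band[1])
        if not np.any(mask):
            raise ValueError(f"band {band} contains no spectral bins at rate {rate}")
        return 60.0 * f[mask][np.argmax(p[mask])]
    sig = np.asarray(stmap_or_bvp, dtype=float).reshape(-1)
    if sig.size < 64:
        raise ValueError("sequence too short for spectral estimation (need >= 64)")
    return 60.0 * _band_peak(sig, rate, band, nfft)


def spectral_oracle_rr(stmap: STMap, rate: float, band: tuple = RR_BAND,
                       nfft: int | None = 8192) -> float:
    """Respiration rate (breaths/min) from the low-frequency band peak."""
    v = stmap.values
    flat = v.transpose(0, 2, 1).reshape(-1, v.shape[1])
    f, p = welch(flat, fs=rate, nperseg=flat.shape[1], nfft=nfft,
                 detrend="constant", axis=-1)
    p = p.mean(axis=0)
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} contains no spectral bins at rate {rate}")
    return 60.0 * f[mask][np.argmax(p[mask])]
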