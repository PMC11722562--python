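"""Task gates, estimation heads and the multi-task loss.

The backbone's task-shared representation ``r`` is filtered once per scalar
task (HR, SpO2, RR) by a gate block producing a sigmoid-bounded mask
``sigma`` in (0,1)^D_r; the task-specific feature is the elementwise product
``r' = sigma * r``. Each scalar head is a single linear layer on its ``r'``.
The BVP waveform head reads the stage-2 pre-pooling token sequence (which
still carries a temporal axis) through a linear projection to a length-T
waveform; a pooled vector cannot represent a waveform, so the waveform
branch taps the network before pooling.

Losses: L1 on the (z-scored) scalar predictions, negative Pearson
correlation ``1 - rho`` on the waveform, combined as

    L = theta * (w1 * L_SpO2 + w2 * L_RR [+ w3 * L_BVP]) + L_HR

where ``theta`` ramps linearly from 0 to 1 over a warm-up fraction of
training, suppressing the auxiliary regularization early on. The waveform
term is optional (``include_bvp``) since the combined loss is also used in
settings without a BVP reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autodiff import Tensor
from .backbone import BackboneConfig, MultiPhysBackbone, SharedRepresentation, TokenSequence

__all__ = [
    "TASKS",
    "GateOutput",
    "TaskFeature",
    "VitalsBundle",
    "LossConfig",
    "GateBlock",
    "gate",
    "select",
    "MultiPhysModel",
    "neg_pearson",
    "theta",
    "total_loss",
]

TASKS = ("HR", "SpO2", "RR")


@dataclass
class GateOutput:
    """Sigmoid gate mask for one task; entries strictly in (0, 1)."""

    sigma: np.ndarray
    task: str

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        s = np.asarray(self.sigma, dtype=float)
        if np.any(s <= 0) or np.any(s >= 1):
            raise ValueError("gate outputs must lie strictly in (0, 1)")
        self.sigma = s


@dataclass
class TaskFeature:
    """Gated task-specific feature r' = sigma * r."""

    r_prime: np.ndarray
    task: str


@dataclass
class VitalsBundle:
    """Predictions or ground truth for the four vitals.

    hr beats/min, spo2 percent, rr breaths/min; bvp is an arbitrary-unit
    waveform (its shape, not scale, is supervised). Scalars may be python
    floats, arrays (batch) or autodiff tensors.
    """

    hr: object
    spo2: object
    rr: object
    bvp: object = None

    PHYSIO_BOUNDS = {"hr": (40.0, 180.0), "spo2": (70.0, 100.0), "rr": (6.0, 30.0)}

    def validate_physiological(self):
        """Range check used for synthesis ground truth."""
        for name, (lo, hi) in self.PHYSIO_BOUNDS.items():
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < lo) or np.any(v > hi):
                raise ValueError(f"{name}={v} outside physiological range [{lo}, {hi}]")
        return self


@dataclass
class LossConfig:
    """Trade-off weights and theta warm-up schedule.

    The published training recipe uses w1 = w2 = w3 = 1e-4 at large scale;
    see :class:`multiphys.pipeline.TrainConfig` for the desk-scale defaults.
    """

    w1: float = 1e-4
    w2: float = 1e-4
    w3: float = 1e-4
    warmup_fraction: float = 0.1
    include_bvp: bool = True

    def __post_init__(self):
        for w in (self.w1, self.w2, self.w3):
            if not (np.isfinite(w) and w >= 0):
                raise ValueError("trade-off weights must be finite and nonnegative")
        if not 0.0 <= self.warmup_fraction <= 1.0:
            raise ValueError("warmup_fraction must lie in [0, 1]")


class GateBlock(nn.Module):
    """Gate: Linear -> LN -> ReLU -> Linear -> LN -> Sigmoid on r."""

    def __init__(self, d_r: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(d_r, d_r, rng)
        self.ln1 = nn.LayerNorm(d_r)
        self.fc2 = nn.Linear(d_r, d_r, rng)
        self.ln2 = nn.LayerNorm(d_r)

    def forward(self, r: Tensor) -> Tensor:
        return self.ln2(self.fc2(self.ln1(self.fc1(r)).relu())).sigmoid()


def gate(block: GateBlock, r, task: str) -> GateOutput:
    """Run one task's gate block on a shared representation (numpy in/out)."""
    if isinstance(r, SharedRepresentation):
        r = r.r
    if not isinstance(r, Tensor):
        r = Tensor(np.asarray(r, dtype=float))
    return GateOutput(sigma=block(r).data, task=task)


def select(r, g: GateOutput) -> TaskFeature:
    """Elementwise feature selection r' = sigma * r."""
    if isinstance(r, SharedRepresentation):
        r = r.r
    r = r.data if isinstance(r, Tensor) else np.asarray(r, dtype=float)
    if r.shape[-1] != g.sigma.shape[-1]:
        raise ValueError(f"length mismatch: r {r.shape} vs sigma {g.sigma.shape}")
    return TaskFeature(r_prime=g.sigma * r, task=g.task)


class MultiPhysModel(nn.Module):
    """Backbone + three gates + scalar heads + waveform head.

    Scalar predictions come out z-scored (training targets are z-scored by
    the caller's statistics); :meth:`predict` un-scales them to physical
    units using the normalization stored on the model.
    """

    def __init__(self, cfg: BackboneConfig, bvp_len: int | None = None,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.backbone = MultiPhysBackbone(cfg, rng)
        d_r = cfg.D_r
        self.gate_hr = GateBlock(d_r, rng)
        self.gate_spo2 = GateBlock(d_r, rng)
        self.gate_rr = GateBlock(d_r, rng)
        self.head_hr = nn.Linear(d_r, 1, rng)
        self.head_spo2 = nn.Linear(d_r, 1, rng)
        self.head_rr = nn.Linear(d_r, 1, rng)
        self.bvp_len = bvp_len if bvp_len is not None else cfg.W
        L2 = (cfg.H // 32) * (cfg.W // 32)
        self.head_bvp = nn.Linear(L2 * self.backbone.stage2_width, self.bvp_len, rng)
        # z-score statistics for scalar targets, in physical units
        self._buffers["target_mean"] = np.array([95.0, 92.5, 16.0])
        self._buffers["target_sd"] = np.array([26.0, 4.3, 4.6])

    def set_target_stats(self, mean, sd):
        self._buffers["target_mean"][...] = mean
        self._buffers["target_sd"][...] = sd

    def forward(self, x: Tensor) -> VitalsBundle:
        shared, tokens, _ = self.backbone.forward_features(x)
        r = shared.r
        out = {}
        for name, gate_block, head in (
            ("hr", self.gate_hr, self.head_hr),
            ("spo2", self.gate_spo2, self.head_spo2),
            ("rr", self.gate_rr, self.head_rr),
        ):
            r_task = gate_block(r) * r
            out[name] = head(r_task).reshape(r.shape[0])
        B, L, C = tokens.tokens.shape
        bvp = self.head_bvp(tokens.tokens.reshape(B, L * C))
        return VitalsBundle(hr=out["hr"], spo2=out["spo2"], rr=out["rr"], bvp=bvp)

    def predict(self, x) -> VitalsBundle:
        """Forward in the current mode, un-scaling scalars to physical units."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        pred = self.forward(x)
        mean, sd = self._buffers["target_mean"], self._buffers["target_sd"]
        return VitalsBundle(
            hr=pred.hr.data * sd[0] + mean[0],
            spo2=pred.spo2.data * sd[1] + mean[1],
            rr=pred.rr.data * sd[2] + mean[2],
            bvp=pred.bvp.data,
        )


def _pearson_terms(pred, gold):
    pc = pred - pred.mean(axis=-1, keepdims=True)
    gc = gold - gold.mean(axis=-1, keepdims=True)
    cov = (pc * gc).mean(axis=-1)
    den = ((pc * pc).mean(axis=-1) * (gc * gc).mean(axis=-1)).sqrt()
    return cov / den


def neg_pearson(pred, gold):
    """1 - Pearson correlation between waveforms; in [0, 2].

    Accepts numpy arrays or autodiff tensors; batched inputs (B, T) return
    the mean over the batch. A constant reference (or prediction, for the
    differentiable path) leaves the correlation undefined and raises.
    """
    is_tensor = isinstance(pred, Tensor) or isinstance(gold, Tensor)
    pd = pred.data if isinstance(pred, Tensor) else np.asarray(pred, dtype=float)
    gd = gold.data if isinstance(gold, Tensor) else np.asarray(gold, dtype=float)
    if pd.shape != gd.shape or pd.shape[-1] < 2:
        raise ValueError(f"sequences must share a length >= 2, got {pd.shape} vs {gd.shape}")
    if np.any(gd.std(axis=-1) == 0):
        raise ValueError("reference sequence is constant; Pearson correlation undefined")
    if is_tensor:
        pred = pred if isinstance(pred, Tensor) else Tensor(pd)
        gold = gold if isinstance(gold, Tensor) else Tensor(gd)
        if np.any(pd.std(axis=-1) == 0):
            raise ValueError("constant prediction; Pearson correlation undefined")
        rho = _pearson_terms(pred, gold)
        return (1.0 - rho).mean() if rho.ndim else 1.0 - rho
    pc = pd - pd.mean(axis=-1, keepdims=True)
    gc = gd - gd.mean(axis=-1, keepdims=True)
    den = np.sqrt((pc * pc).mean(axis=-1) * (gc * gc).mean(axis=-1))
    if np.any(den == 0):
        raise ValueError("constant prediction; Pearson correlation undefined")
    rho = (pc * gc).mean(axis=-1) / den
    return float(np.mean(1.0 - rho))


def theta(step: int, total: int, cfg: LossConfig) -> float:
    """Linear warm-up ramp theta = min(1, step / (warmup_fraction * total))."""
    if total <= 0:
        raise ValueError("total number of steps must be positive")
    if not 0 <= step <= total:
        raise ValueError(f"step {step} outside [0, {total}]")
    warm = cfg.warmup_fraction * total
    if warm == 0:
        return 1.0
    return min(1.0, step / warm)


def _l1(pred, gold):
    diff = pred - (gold if isinstance(gold, Tensor) or not isinstance(pred, Tensor)
                   else Tensor(np.asarray(gold, dtype=float)))
    if isinstance(diff, Tensor):
        return (diff * diff + 1e-24).sqrt().mean()  # smooth |.| at 0 for autodiff
    return float(np.mean(np.abs(diff)))


def total_loss(pred: VitalsBundle, gold: VitalsBundle, step: int, total: int,
               cfg: LossConfig):
    """Combined multi-task loss and per-term breakdown.

    Returns ``(L, terms)`` where ``terms`` maps 'L_HR', 'L_SpO2', 'L_RR',
    'L_BVP' (if enabled) and 'theta' to floats. ``L`` is a Tensor when the
    predictions are tensors (differentiable) and a float otherwise.
    """
    th = theta(step, total, cfg)
    l_hr = _l1(pred.hr, gold.hr)
    l_spo2 = _l1(pred.spo2, gold.spo2)
    l_rr = _l1(pred.rr, gold.rr)
    aux = cfg.w1 * l_spo2 + cfg.w2 * l_rr
    terms = {"theta": th}
    if cfg.include_bvp:
        l_bvp = neg_pearson(pred.bvp, gold.bvp)
        aux = aux + cfg.w3 * l_bvp
        terms["L_BVP"] = l_bvp.item() if isinstance(l_bvp, Tensor) else float(l_bvp)
    L = th * aux + l_hr
    for key, val in (("L_HR", l_hr), ("L_SpO2", l_spo2), ("L_RR", l_rr)):
        terms[key] = val.item() if isinstance(val, Tensor) else float(val)
    return L, terms
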