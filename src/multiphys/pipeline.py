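"""Training, evaluation and experiment harnesses.

Training minimizes the combined multi-task loss with Adam over mini-batches
of (STMap, vitals) pairs. Scalar targets are z-scored by the dataset's
statistics before the L1 loss (balancing gradient magnitudes across tasks)
and un-scaled for metric reporting. Every step emits one JSON-lines record
with the loss breakdown and the current theta.

Desk-scale defaults (batch 8, 500 iterations, learning rate 1e-3, equal
task weights) are sized so a tiny model trains in minutes on one CPU; the
published large-scale recipe (batch 60, 20000 iterations, learning rate
1e-5, trade-off weights 1e-4) is available via :func:`TrainConfig.published`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .backbone import BackboneConfig
from .heads_losses import LossConfig, MultiPhysModel, VitalsBundle, neg_pearson, total_loss
from .synthetic_data import SyntheticSample

__all__ = [
    "TrainConfig",
    "MetricReport",
    "metrics",
    "train",
    "evaluate",
    "sweep_layers",
    "constant_mean_baseline",
    "save_checkpoint",
    "load_checkpoint",
    "tiny_backbone_config",
]


@dataclass
class TrainConfig:
    """Optimization settings (Adam throughout)."""

    batch_size: int = 8
    n_iters: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    deterministic: bool = True
    dtype: str = "float32"
    loss: LossConfig = field(default_factory=lambda: LossConfig(w1=1.0, w2=1.0, w3=1.0))

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch normalization)")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")

    @classmethod
    def published(cls, **overrides):
        """The published large-scale recipe."""
        base = dict(batch_size=60, n_iters=20000, learning_rate=1e-5,
                    loss=LossConfig(w1=1e-4, w2=1e-4, w3=1e-4))
        base.update(overrides)
        return cls(**base)


@dataclass
class MetricReport:
    """Per-task MAE / RMSE / Pearson plus the waveform score."""

    per_task: dict
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_task).T


def _pearson_or_reason(pred: np.ndarray, gold: np.ndarray):
    if np.std(gold) == 0 or np.std(pred) == 0:
        return None, "undefined: constant input"
    num = np.mean((pred - pred.mean()) * (gold - gold.mean()))
    return float(num / (np.std(pred) * np.std(gold))), None


def metrics(pred: list, gold: list) -> MetricReport:
    """MAE, RMSE and Pearson correlation per scalar task; mean 1-rho for BVP.

    `pred` and `gold` are aligned lists of :class:`VitalsBundle`. A constant
    gold vector leaves Pearson undefined; it is reported as None with a
    reason instead of a number.
    """
    if len(pred) != len(gold) or len(pred) < 2:
        raise ValueError("need aligned prediction/gold lists of length >= 2")
    report = {}
    for task in ("hr", "spo2", "rr"):
        p = np.array([float(np.asarray(getattr(b, task)).reshape(())) for b in pred])
        g = np.array([float(np.asarray(getattr(b, task)).reshape(())) for b in gold])
        e = p - g
        rho, reason = _pearson_or_reason(p, g)
        entry = {"mae": float(np.mean(np.abs(e))), "rmse": float(np.sqrt(np.mean(e**2))),
                 "pearson": rho}
        if reason:
            entry["pearson_reason"] = reason
        report[task] = entry
    if all(b.bvp is not None for b in gold) and all(b.bvp is not None for b in pred):
        scores = [neg_pearson(np.asarray(p.bvp), np.asarray(g.bvp)) for p, g in zip(pred, gold)]
        report["bvp"] = {"neg_pearson": float(np.mean(scores))}
    return MetricReport(per_task=report, n_samples=len(pred))


def constant_mean_baseline(train_gold: list, test_gold: list) -> MetricReport:
    """Predict each task's training-set mean for every test sample."""
    preds = []
    means = {t: float(np.mean([float(np.asarray(getattr(b, t)).reshape(())) for b in train_gold]))
             for t in ("hr", "spo2", "rr")}
    for _ in test_gold:
        preds.append(VitalsBundle(hr=means["hr"], spo2=means["spo2"], rr=means["rr"]))
    return metrics(preds, test_gold)


def _stack_batch(samples: list) -> tuple:
    x = np.stack([s.stmap.values for s in samples])
    hr = np.array([s.truth.hr for s in samples])
    spo2 = np.array([s.truth.spo2 for s in samples])
    rr = np.array([s.truth.rr for s in samples])
    bvp = np.stack([np.asarray(s.truth.bvp) for s in samples])
    return x, hr, spo2, rr, bvp


def dataset_target_stats(samples: list):
    """Mean and sd of (hr, spo2, rr) over a sample list."""
    arr = np.array([[s.truth.hr, s.truth.spo2, s.truth.rr] for s in samples])
    sd = arr.std(axis=0)
    sd = np.where(sd < 1e-6, 1.0, sd)
    return arr.mean(axis=0), sd


def train(model: MultiPhysModel, data: list, cfg: TrainConfig,
          log_path=None, fixed_batch: bool = False):
    """Adam training on the combined loss; returns the per-step history.

    ``data`` is a list of :class:`SyntheticSample` (or any object with
    ``.stmap.values`` and ``.truth``). Batches are drawn with replacement
    from ``cfg.seed``; ``fixed_batch=True`` reuses the first batch every
    step (overfit harness). Each step appends a JSON-lines record with the
    loss breakdown. Aborts on a non-finite loss, returning the history
    collected so far together with the last finite state.
    """
    from .nn import Adam

    rng = np.random.default_rng(cfg.seed)
    mean, sd = dataset_target_stats(data)
    model.set_target_stats(mean, sd)
    model.train()
    dtype = np.dtype(cfg.dtype)
    model.astype(dtype)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    log_f = open(log_path, "w") if log_path else None
    batch_idx = rng.integers(0, len(data), size=cfg.batch_size)
    try:
        for step in range(cfg.n_iters):
            if not fixed_batch:
                batch_idx = rng.integers(0, len(data), size=cfg.batch_size)
            batch = [data[i] for i in batch_idx]
            x, hr, spo2, rr, bvp = _stack_batch(batch)
            gold = VitalsBundle(hr=((hr - mean[0]) / sd[0]).astype(dtype),
                                spo2=((spo2 - mean[1]) / sd[1]).astype(dtype),
                                rr=((rr - mean[2]) / sd[2]).astype(dtype),
                                bvp=bvp.astype(dtype))
            pred = model(Tensor(x.astype(dtype)))
            loss, terms = total_loss(pred, gold, step, cfg.n_iters, cfg.loss)
            if not np.isfinite(loss.item()):
                record = {"step": step, "event": "non-finite loss; aborting", **terms}
                history.append(record)
                if log_f:
                    log_f.write(json.dumps(record) + "\n")
                break
            opt.zero_grad()
            loss.backward()
            opt.step()
            record = {"step": step, "L_total": loss.item(), **terms}
            history.append(record)
            if log_f:
                log_f.write(json.dumps(record) + "\n")
    finally:
        if log_f:
            log_f.close()
    model.eval()
    return history


def evaluate(model: MultiPhysModel, data: list) -> MetricReport:
    """Batched forward passes in evaluation mode; metric report."""
    model.eval()
    preds, golds = [], []
    for start in range(0, len(data), 16):
        chunk = data[start : start + 16]
        x, hr, spo2, rr, bvp = _stack_batch(chunk)
        if x.shape[1:3] != (model.cfg.H, model.cfg.W):
            raise ValueError(
                f"data STMap shape {x.shape[1:3]} does not match model input "
                f"({model.cfg.H}, {model.cfg.W})"
            )
        out = model.predict(x)
        for i in range(len(chunk)):
            preds.append(VitalsBundle(hr=out.hr[i], spo2=out.spo2[i], rr=out.rr[i],
                                      bvp=out.bvp[i]))
            golds.append(VitalsBundle(hr=hr[i], spo2=spo2[i], rr=rr[i], bvp=bvp[i]))
    return metrics(preds, golds)


def tiny_backbone_config(H: int = 64, W: int = 256, N_mp: int = 2) -> BackboneConfig:
    """Desk-scale model: ~8 embedding channels, shallow stages."""
    return BackboneConfig(H=H, W=W, C_embed=8, N1=1, N2=1, N_mp=N_mp,
                          n_heads=2, mlp_ratio=2, D_r=32, state_size=8)


def sweep_layers(data: list, Ns: list, cfg: TrainConfig, test_data: list | None = None,
                 H: int = 64, W: int = 256, csv_path=None) -> pd.DataFrame:
    """Train one model per stage depth N; tabulate per-task test MAE.

    Odd N assigns ceil(N/2) integrator and floor(N/2) attention layers.
    All runs share ``cfg`` and its seed. Returns (and optionally writes) a
    CSV table with columns N, mae_hr, mae_spo2, mae_rr.
    """
    test_data = test_data if test_data is not None else data
    rows = []
    for n in Ns:
        bcfg = tiny_backbone_config(H=H, W=W, N_mp=n)
        model = MultiPhysModel(bcfg, rng=cfg.seed)
        train(model, data, cfg)
        rep = evaluate(model, test_data)
        rows.append({"N": n, "mae_hr": rep.per_task["hr"]["mae"],
                     "mae_spo2": rep.per_task["spo2"]["mae"],
                     "mae_rr": rep.per_task["rr"]["mae"]})
    df = pd.DataFrame(rows, columns=["N", "mae_hr", "mae_spo2", "mae_rr"])
    if csv_path:
        df.to_csv(csv_path, index=False)
    return df


# ---------------------------------------------------------------------------
# checkpoints: single-file npz archive with a JSON manifest


def save_checkpoint(path, model: MultiPhysModel, metric_snapshot: dict | None = None):
    manifest = {
        "format_version": 1,
        "backbone_config": asdict(model.cfg),
        "bvp_len": model.bvp_len,
        "n_parameters": model.n_parameters(),
        "metrics": metric_snapshot or {},
        "saved_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state = model.state_dict()
    np.savez(path, __manifest__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple:
    """Returns (model, manifest)."""
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(bytes(z["__manifest__"]).decode())
        state = {k: z[k] for k in z.files if k != "__manifest__"}
    cfg = BackboneConfig(**manifest["backbone_config"])
    model = MultiPhysModel(cfg, bvp_len=manifest["bvp_len"], rng=0)
    # saved lists/tuples round-trip as lists in the manifest
    model.load_state_dict(state)
    model.eval()
    return model, manifest
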