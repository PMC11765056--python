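"""Cascade training: Adam, one-cycle cosine annealing, ablation modes.

One optimizer step per batch (batch size 1 by default — each case is a full
128^3-equivalent volume).  The learning rate follows the one-cycle cosine
schedule ``a_t = a_min + (a_max - a_min)(1 + cos(pi t / T)) / 2`` stepped
per epoch, from ``a_max = 1e-3`` at epoch 0 down to ``a_min = 0``.

Three training modes mirror the ablation ladder:

* ``single_mae`` — the refinement network alone on the 11-channel input,
  trained with masked MAE;
* ``dual_mae``  — both sub-models, ``0.5 * MAE(A) + MAE(B)``;
* ``dual_dvh``  — the headline configuration, ``0.5 * MAE(A) + L_DVH(B)``.

The offline x4 augmentation enumeration is applied once per run, then the
case order is reshuffled every epoch.  The CT standardizer is fitted on the
raw training cases only.  The checkpoint kept is the one with the best
validation total loss.  Runs are bit-reproducible given the seed under
single-threaded execution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .errors import ConfigError, DomainError
from .losses import dvh_loss_grad, mae_loss_grad
from .network import (
    CascadeModel,
    ModelConfig,
    build_model,
    forward,
)
from .patient_io import OAR_NAMES, PTV_NAMES, PatientCase
from .preprocess import Standardizer, augment_dataset, fit_standardizer, standardize

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "cosine_lr",
    "train",
    "predict",
    "assemble_input",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("single_mae", "dual_mae", "dual_dvh")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults are the reference recipe)."""

    lr_max: float = 1e-3
    lr_min: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 100
    batch_size: int = 1
    seed: int = 0
    mode: str = "dual_dvh"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lr_min < self.lr_max:
            raise ConfigError("need 0 <= lr_min < lr_max")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss_a: Optional[float]
    train_loss_b: float
    train_total: float
    val_loss_a: Optional[float] = None
    val_loss_b: Optional[float] = None
    val_total: Optional[float] = None


@dataclass
class TrainingHistory:
    """Per-epoch loss components and learning rates."""

    records: List[EpochRecord] = field(default_factory=list)

    def lrs(self) -> List[float]:
        return [r.lr for r in self.records]

    def val_totals(self) -> List[float]:
        return [r.val_total for r in self.records]

    def to_json(self) -> str:
        return json.dumps([dataclasses.asdict(r) for r in self.records])

    @classmethod
    def from_json(cls, text: str) -> "TrainingHistory":
        return cls(records=[EpochRecord(**r) for r in json.loads(text)])


def cosine_lr(epoch: int, total: int, lr_min: float, lr_max: float) -> float:
    """One-cycle cosine annealed rate at the given epoch (0..total)."""
    if not 0 <= epoch <= total:
        raise DomainError(f"epoch {epoch} outside 0..{total}")
    return float(lr_min + 0.5 * (lr_max - lr_min)
                 * (1.0 + np.cos(np.pi * epoch / total)))


def assemble_input(case: PatientCase, standardizer: Standardizer,
                   dtype=np.float32) -> np.ndarray:
    """Stack the fixed channel order: standardized CT, 7 OARs, 3 PTVs.

    Absent structures become all-zero channels, so the 11-channel contract
    holds for every patient.
    """
    chans = [standardize(case.ct, standardizer)]
    for name in OAR_NAMES + PTV_NAMES:
        if name in case.masks:
            chans.append(case.masks[name])
        else:
            chans.append(np.zeros(case.grid.shape))
    return np.stack(chans).astype(dtype)


class _Adam:
    def __init__(self, params: Sequence[nn.Tensor], beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.params = list(params)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray], lr: float) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, m, v, g in zip(self.params, self.m, self.v, grads):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            # keep the parameter dtype stable (lr arrives as a float64 scalar)
            step = lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
            p.data = (p.data - step).astype(p.data.dtype, copy=False)


def _case_losses(model: CascadeModel, x: np.ndarray, case: PatientCase,
                 mode: str, *, want_grads: bool):
    """Forward one case; returns (loss_a, loss_b, total, seeds-for-backward)."""
    dose_a, _, dose_b = forward(model, x)
    true = case.reference_dose
    pdm = case.possible_dose_mask
    seeds = []
    pb = dose_b.data[0]
    if mode == "dual_dvh":
        vb, gb = dvh_loss_grad(pb, true, case.masks)
    else:
        vb, gb = mae_loss_grad(pb, true, pdm)
    if want_grads:
        seeds.append((dose_b, gb[None]))
    if dose_a is not None:
        va, ga = mae_loss_grad(dose_a.data[0], true, pdm)
        if want_grads:
            seeds.append((dose_a, 0.5 * ga[None]))
        total = 0.5 * va + vb
    else:
        va, total = None, vb
    if not np.isfinite(total):
        raise RuntimeError(
            f"non-finite loss on case {case.id}: loss_a={va} loss_b={vb}")
    return va, vb, total, seeds


def _mean_losses(vals: List[Tuple[Optional[float], float, float]]):
    la = [v[0] for v in vals if v[0] is not None]
    a = float(np.mean(la)) if la else None
    b = float(np.mean([v[1] for v in vals]))
    t = float(np.mean([v[2] for v in vals]))
    return a, b, t


def train(train_cases: Sequence[PatientCase], val_cases: Sequence[PatientCase],
          model_config: ModelConfig, config: TrainConfig,
          ) -> Tuple[CascadeModel, Standardizer, TrainingHistory]:
    """Fit the cascade on phantom or real cases.

    Deterministic given ``config.seed`` under single-threaded BLAS; the
    best-validation-loss parameters are restored before returning.
    """
    train_cases = list(train_cases)
    val_cases = list(val_cases)
    if not train_cases:
        raise DomainError("empty training set")
    shapes = {c.grid.shape for c in train_cases + val_cases}
    if len(shapes) != 1:
        raise ConfigError(f"all cases must share one grid shape, got {shapes}")
    if next(iter(shapes)) != model_config.grid.shape:
        raise ConfigError("case grid does not match the model grid")
    if (config.mode == "single_mae") != model_config.single_model:
        model_config = dataclasses.replace(
            model_config, single_model=config.mode == "single_mae")

    standardizer = fit_standardizer(train_cases)
    augmented = augment_dataset(train_cases, config.seed)
    inputs = [assemble_input(c, standardizer) for c in augmented]
    val_inputs = [assemble_input(c, standardizer) for c in val_cases]

    model = build_model(model_config, init_seed=config.seed)
    params = model.all_params()
    opt = _Adam(params, config.beta1, config.beta2)
    shuffle_rng = np.random.default_rng([int(config.seed), 0x5F])

    history = TrainingHistory()
    best_val = np.inf
    best_state = None
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_min, config.lr_max)
        order = shuffle_rng.permutation(len(augmented))
        train_vals = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            acc = [np.zeros_like(p.data) for p in params]
            for j in batch:
                va, vb, tot, seeds = _case_losses(
                    model, inputs[j], augmented[j], config.mode, want_grads=True)
                train_vals.append((va, vb, tot))
                nn.backward(seeds)
                for g, p in zip(acc, params):
                    if p.grad is not None:
                        g += p.grad
            opt.step([g / len(batch) for g in acc], lr)
        rec = EpochRecord(epoch, float(lr), *_mean_losses(train_vals))
        if val_cases:
            val_vals = [
                _case_losses(model, x, c, config.mode, want_grads=False)[:3]
                for x, c in zip(val_inputs, val_cases)
            ]
            rec.val_loss_a, rec.val_loss_b, rec.val_total = _mean_losses(val_vals)
            if rec.val_total < best_val:
                best_val = rec.val_total
                best_state = [p.data.copy() for p in params]
        history.records.append(rec)
    if best_state is not None:
        for p, d in zip(params, best_state):
            p.data = d
    return model, standardizer, history


def predict(model: CascadeModel, standardizer: Standardizer,
            case: PatientCase) -> np.ndarray:
    """Final-model dose for one case, zeroed outside the possible-dose mask."""
    if case.grid.shape != model.config.grid.shape:
        raise ConfigError(
            f"case grid {case.grid.shape} != model grid {model.config.grid.shape}")
    x = assemble_input(case, standardizer,
                       dtype=model.model_b.params[0].data.dtype)
    _, _, dose_b = forward(model, x)
    dose = dose_b.data[0].copy()
    dose[case.possible_dose_mask == 0] = 0.0
    return dose


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: CascadeModel, standardizer: Standardizer,
                    history: Optional[TrainingHistory] = None) -> None:
    """Single-file checkpoint: weights + model config + standardizer + history."""
    cfg = model.config
    meta = {
        "version": _CHECKPOINT_VERSION,
        "grid_shape": list(cfg.grid.shape),
        "grid_spacing": list(cfg.grid.spacing),
        "base_width_a": cfg.base_width_a,
        "base_width_b": cfg.base_width_b,
        "in_channels": cfg.in_channels,
        "single_model": cfg.single_model,
        "init_seed": model.init_seed,
        "mu": standardizer.mu,
        "sigma": standardizer.sigma,
    }
    arrays = model.state_arrays()
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if history is not None:
        arrays["_history"] = np.frombuffer(history.to_json().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Tuple[CascadeModel, Standardizer, TrainingHistory]:
    from .patient_io import VoxelGrid  # local import to avoid cycle at module load

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ConfigError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = ModelConfig(
            grid=VoxelGrid(tuple(meta["grid_shape"]), tuple(meta["grid_spacing"])),
            base_width_a=meta["base_width_a"],
            base_width_b=meta["base_width_b"],
            in_channels=meta["in_channels"],
            single_model=meta["single_model"],
        )
        model = build_model(cfg, init_seed=meta["init_seed"])
        model.load_state_arrays(
            {k: data[k] for k in data.files if not k.startswith("_")})
        history = TrainingHistory()
        if "_history" in data.files:
            history = TrainingHistory.from_json(bytes(data["_history"]).decode())
    return model, Standardizer(meta["mu"], meta["sigma"]), history
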