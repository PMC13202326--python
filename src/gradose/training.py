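"""Dataset splitting, optimization loop, grid search, and early stopping.

The full-scale defaults mirror the clinical training recipe (Adam, learning
rate 1e-4, up to 300 epochs, early stopping after 30 epochs without
validation improvement, stratified 124/30/18-style splitting by protocol,
grid search over lr {1e-5, 1e-4, 1e-3} x batch {2, 4, 8}).  Desk-scale
presets shrink epochs/volumes/width so the whole loop runs on one CPU; they
change problem size only, never the logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Case
from .losses import LossContext, LossSpec
from .network import Adam, NetworkConfig, UNet3D, case_to_channels

__all__ = [
    "TrainConfig",
    "stratified_split",
    "early_stopping_trace",
    "train",
    "grid_search",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    loss: LossSpec = field(default_factory=LossSpec)
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 300
    patience: int = 30
    min_improve_rel: float = 1e-6  # strict relative decrease counts as improvement
    split_fractions: Tuple[float, float, float] = (124 / 172, 30 / 172, 18 / 172)
    stratify_key: str = "protocol"
    grid_learning_rates: Tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    grid_batch_sizes: Tuple[int, ...] = (2, 4, 8)
    grid_epochs: Optional[int] = None  # reduced epochs for desk-scale grid search
    seed: int = 0
    hu_range: Tuple[float, float] = (-1000.0, 2000.0)

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _strata(cases: Sequence[Case], key: str) -> Dict[str, List[int]]:
    out: Dict[str, List[int]] = {}
    for i, c in enumerate(cases):
        if key == "protocol":
            k = c.prescription.protocol_id
        else:
            k = str(c.meta.get(key, ""))
        out.setdefault(k, []).append(i)
    return out


def stratified_split(
    cases: Sequence[Case],
    fractions: Tuple[float, float, float],
    key: str = "protocol",
    seed: int = 0,
) -> Tuple[List[Case], List[Case], List[Case]]:
    """Disjoint, exhaustive train/val/test split, proportional per stratum.

    Within each stratum the requested fractions are allocated by largest
    remainder, so per-stratum proportions sit within one case of the global
    fractions; assignment within a stratum is a seeded shuffle.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    strata = _strata(cases, key)
    names = sorted(strata)
    fracs = np.asarray(fractions, dtype=float)

    # per-stratum largest-remainder allocation
    raw = {t: fracs * len(strata[t]) for t in names}
    counts = {t: np.floor(raw[t]).astype(int) for t in names}
    for t in names:
        for j in np.argsort(-(raw[t] - counts[t])):
            if counts[t].sum() == len(strata[t]):
                break
            counts[t][j] += 1

    # repair pass: match the global largest-remainder targets exactly while
    # keeping every stratum within one case of its proportional share
    n_total = len(cases)
    raw_g = fracs * n_total
    target = np.floor(raw_g).astype(int)
    for j in np.argsort(-(raw_g - target)):
        if target.sum() == n_total:
            break
        target[j] += 1
    totals = sum(counts[t] for t in names)
    while not np.array_equal(totals, target):
        over = int(np.argmax(totals - target))
        under = int(np.argmin(totals - target))
        best = max(
            (t for t in names if counts[t][over] > 0),
            key=lambda t: (counts[t][over] - raw[t][over]) - (counts[t][under] - raw[t][under]),
        )
        counts[best][over] -= 1
        counts[best][under] += 1
        totals = sum(counts[t] for t in names)

    splits: Tuple[List[Case], List[Case], List[Case]] = ([], [], [])
    for t in names:
        idx = np.array(strata[t])
        rng.shuffle(idx)
        start = 0
        for s, cnt in enumerate(counts[t]):
            splits[s].extend(cases[i] for i in idx[start:start + cnt])
            start += cnt
    return splits


def early_stopping_trace(
    val_losses: Sequence[float], patience: int, min_improve_rel: float = 1e-6
) -> Tuple[int, int]:
    """Apply the early-stopping rule to a loss trace.

    Returns ``(best_epoch, stop_epoch)`` (1-based): the epoch achieving the
    running minimum and the epoch after which training halts, i.e. the first
    epoch where ``patience`` consecutive epochs brought no relative
    improvement over the best, or the final epoch otherwise.
    """
    best = np.inf
    best_epoch = 0
    since = 0
    for e, v in enumerate(val_losses, start=1):
        if v < best * (1.0 - min_improve_rel) or not np.isfinite(best):
            best, best_epoch, since = v, e, 0
        else:
            since += 1
        if since >= patience:
            return best_epoch, e
    return best_epoch, len(val_losses)


def _epoch_pass(
    model: UNet3D,
    cases: Sequence[Case],
    contexts: Sequence[LossContext],
    inputs: Sequence[np.ndarray],
    cfg: TrainConfig,
    order: np.ndarray,
    optimizer: Optional[Adam],
) -> Dict[str, float]:
    """One pass over ``cases``; optimizes when an optimizer is given."""
    totals: Dict[str, float] = {}
    n_seen = 0
    for start in range(0, len(order), cfg.batch_size):
        batch = order[start:start + cfg.batch_size]
        x = np.stack([inputs[i] for i in batch])
        y = model.forward(x)
        gy = np.zeros_like(y)
        for j, i in enumerate(batch):
            val, comps, g = contexts[i].value_and_grad(y[j, 0].astype(float))
            gy[j, 0] = g / len(batch)
            totals["total"] = totals.get("total", 0.0) + val
            for k, v in comps.items():
                totals[k] = totals.get(k, 0.0) + v
        n_seen += len(batch)
        if optimizer is not None:
            model.backward(gy.astype(y.dtype))
            optimizer.step()
    return {k: v / n_seen for k, v in totals.items()}


def train(
    model: UNet3D,
    train_cases: Sequence[Case],
    val_cases: Sequence[Case],
    cfg: TrainConfig,
) -> Tuple[UNet3D, pd.DataFrame]:
    """Optimize the composite loss with Adam + early stopping.

    Returns the model restored to the parameters with minimum validation
    loss, and a per-epoch history with every loss component for both sets.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate)
    tr_ctx = [LossContext(cfg.loss, c) for c in train_cases]
    va_ctx = [LossContext(cfg.loss, c) for c in val_cases]
    tr_in = [case_to_channels(c, cfg.hu_range) for c in train_cases]
    va_in = [case_to_channels(c, cfg.hu_range) for c in val_cases]

    history: List[Dict[str, float]] = []
    best_state = model.get_state()
    best_val = np.inf
    since = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_cases))
        tr = _epoch_pass(model, train_cases, tr_ctx, tr_in, cfg, order, opt)
        va = _epoch_pass(model, val_cases, va_ctx, va_in, cfg, np.arange(len(val_cases)), None)
        if not np.isfinite(tr["total"]) or not np.isfinite(va["total"]):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: train={tr['total']}, val={va['total']}"
            )
        row = {"epoch": epoch}
        row.update({f"train_{k}": v for k, v in tr.items()})
        row.update({f"val_{k}": v for k, v in va.items()})
        history.append(row)
        if va["total"] < best_val * (1.0 - cfg.min_improve_rel) or not np.isfinite(best_val):
            best_val = va["total"]
            best_state = model.get_state()
            since = 0
        else:
            since += 1
        if since >= cfg.patience:
            break
    model.set_state(best_state)
    return model, pd.DataFrame(history)


def grid_search(
    cases: Sequence[Case],
    net_cfg: NetworkConfig,
    cfg: TrainConfig,
) -> Tuple[TrainConfig, pd.DataFrame]:
    """Train one model per (learning rate, batch size) grid point.

    Cases are split once (stratified by protocol); each grid point trains
    from an identically seeded initialization and is ranked by the best
    validation composite loss.  Returns the winning config and the full
    leaderboard sorted best-first.
    """
    train_cases, val_cases, _ = stratified_split(
        cases, cfg.split_fractions, cfg.stratify_key, cfg.seed
    )
    rows = []
    epochs = cfg.grid_epochs or cfg.max_epochs
    for lr in cfg.grid_learning_rates:
        for bs in cfg.grid_batch_sizes:
            run_cfg = replace(
                cfg, learning_rate=lr, batch_size=bs,
                max_epochs=epochs, patience=min(cfg.patience, epochs - 1),
            )
            model = UNet3D(net_cfg)
            try:
                _, hist = train(model, train_cases, val_cases, run_cfg)
                best_val = float(hist["val_total"].min())
            except FloatingPointError:
                best_val = np.inf  # diverged: ranks last
            rows.append({"learning_rate": lr, "batch_size": bs, "best_val_loss": best_val})
    board = pd.DataFrame(rows).sort_values("best_val_loss", kind="stable").reset_index(drop=True)
    best = board.iloc[0]
    best_cfg = replace(cfg, learning_rate=float(best.learning_rate), batch_size=int(best.batch_size))
    return best_cfg, board
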