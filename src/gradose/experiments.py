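"""Desk-scale experiment harness: loss-function comparisons on phantom cohorts.

The harness tests the qualitative claim that gradient-aware training
(Loss4) improves fall-off fidelity over plain MSE (Loss1) — lower test-set
dose-gradient loss and at-least-as-good 10%-isodose overlap (DSC).  It
trains identically seeded models per loss on identically generated phantom
cohorts and evaluates them on the held-out test split, so the loss function
is the only difference between arms.  Whether the ordering holds is
scale-dependent; see the methods note for what desk-scale results do and
do not show.

Problem sizes are desk presets (24^3 voxels at 4 mm spacing — the same
96 mm field of view as the default 48^3 x 2 mm phantom — a depth-3 U-Net
with 4 base features, 32 cases split 24/4/4) so a full comparison runs on a
single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .losses import LossSpec, dose_gradient_loss
from .metrics import case_metrics, dsc, isodose_mask, isodose_volume_errors
from .network import NetworkConfig, build_network, predict_case
from .phantom import PhantomConfig, generate_dataset
from .training import TrainConfig, stratified_split, train

__all__ = ["desk_preset", "evaluate_model", "loss_comparison", "LossComparisonResult"]


def desk_preset(
    n_cases: int = 32, epochs: int = 40, seed: int = 0
) -> Tuple[PhantomConfig, NetworkConfig, TrainConfig]:
    """Phantom/network/training configs sized for single-CPU experiments."""
    pcfg = PhantomConfig(shape=(24, 24, 24), spacing=(4.0, 4.0, 4.0))
    ncfg = NetworkConfig(depth=3, base_features=4, seed=seed)
    tcfg = TrainConfig(
        loss=LossSpec("Loss4"),
        learning_rate=1e-3,  # tiny-net preset; full-scale default is 1e-4
        batch_size=4,
        max_epochs=epochs,
        patience=max(epochs - 1, 1),
        split_fractions=(24 / 32, 4 / 32, 4 / 32),
        seed=seed,
    )
    return pcfg, ncfg, tcfg


def evaluate_model(model, test_cases) -> Dict[str, float]:
    """Test-split summary: gradient loss, 10%-isodose DSC and volume errors,
    and CTV D98/D2 mean absolute deviations (percent of prescription)."""
    grad_losses, dscs, vol_errs, d98_errs, d2_errs = [], [], [], [], []
    for case in test_cases:
        pred = predict_case(model, case)
        grad_losses.append(dose_gradient_loss(pred, case.dose))
        body = case.structures["body"]
        dscs.append(dsc(isodose_mask(case.dose, 0.10, body), isodose_mask(pred, 0.10, body)))
        cm = case_metrics(case, pred)
        vol_errs.append(cm.pre["isodose10_cm3"] - cm.cli["isodose10_cm3"])
        d98_errs.append(abs(cm.pre["ctv_d98_pct"] - cm.cli["ctv_d98_pct"]))
        d2_errs.append(abs(cm.pre["ctv_d2_pct"] - cm.cli["ctv_d2_pct"]))
    mae, rmse = isodose_volume_errors(vol_errs)
    return {
        "test_gradient_loss": float(np.mean(grad_losses)),
        "mean_dsc10": float(np.mean(dscs)),
        "isodose10_mae_cm3": mae,
        "isodose10_rmse_cm3": rmse,
        "ctv_d98_mae_pct": float(np.mean(d98_errs)),
        "ctv_d2_mae_pct": float(np.mean(d2_errs)),
        "n_test": len(test_cases),
    }


@dataclass
class LossComparisonResult:
    """Per-seed, per-loss test metrics of one comparison experiment."""

    per_seed: List[Dict[str, Dict[str, float]]] = field(default_factory=list)
    seeds: List[int] = field(default_factory=list)

    def wins(self, metric: str, a: str = "Loss4", b: str = "Loss1", sense: str = "lower") -> int:
        """Count seeds where composite ``a`` beats (or ties, for 'ge') ``b``."""
        n = 0
        for row in self.per_seed:
            va, vb = row[a][metric], row[b][metric]
            if sense == "lower" and va < vb:
                n += 1
            elif sense == "ge" and va >= vb:
                n += 1
        return n

    def mean(self, composite: str, metric: str) -> float:
        return float(np.mean([row[composite][metric] for row in self.per_seed]))


def loss_comparison(
    seeds: Sequence[int],
    composites: Sequence[str] = ("Loss1", "Loss4"),
    n_cases: int = 32,
    epochs: int = 40,
) -> LossComparisonResult:
    """Train one model per (seed, composite) and evaluate on the test split.

    For each seed a fresh phantom cohort is generated and split; models for
    the different composites share the seed, the initialization, the split,
    and the batch order, so the loss function is the only difference.
    """
    result = LossComparisonResult(seeds=list(seeds))
    for seed in seeds:
        pcfg, ncfg, tcfg = desk_preset(n_cases=n_cases, epochs=epochs, seed=seed)
        cases, _ = generate_dataset(pcfg, n_cases, seed=seed)
        tr, va, te = stratified_split(cases, tcfg.split_fractions, "protocol", seed=seed)
        row: Dict[str, Dict[str, float]] = {}
        for comp in composites:
            from dataclasses import replace

            cfg = replace(tcfg, loss=LossSpec(comp))
            model = build_network(ncfg)
            model, _ = train(model, tr, va, cfg)
            row[comp] = evaluate_model(model, te)
        result.per_seed.append(row)
    return result
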