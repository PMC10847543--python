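"""Scaled-down ablation experiment over the four network variants.

Trains baseline / baseline-M (ASPP) / baseline-A (SCSE) / full on identical
seeded phantom sets and reports the two-class pixel metrics per variant,
pooled over the validation images — the same table layout used to compare
the variants on clinical data (per-class rows plus macro averages).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .losses import LossWeights
from .model import VARIANTS, SegModelConfig, build_model
from .nn import Tensor
from .segmetrics import ConfusionCounts, evaluate_masks, metrics_from_counts
from .training import TrainConfig, preprocess, split_by_patient, train, _resize_mask


def _pooled_masks(network, val_set, threshold=0.5):
    size = network.config.input_size
    network.eval()
    preds, truths = [], []
    for image, mask in val_set:
        x = preprocess(image, size)
        prob = network(Tensor(x[None, None].astype(np.float32))).data[0, 0]
        preds.append(prob >= threshold)
        truths.append(_resize_mask(np.asarray(mask), size))
    return np.stack(preds), np.stack(truths)


def run_ablation(n_images: int = 80, epochs: int = 12, dims=(64, 48),
                 seeds=(0, 1, 2), base_channels: int = 8, depth: int = 3,
                 aspp_rates=(1, 2, 4)) -> pd.DataFrame:
    """Train every variant on each seed's phantom set.

    Returns a long-format frame with one row per (seed, variant): per-class
    IoU/F1 for the cancer class plus the macro (normal/cancer average) of
    each metric.
    """
    from .phantom import phantom_training_set

    rows = []
    for seed in seeds:
        pairs = [(img.pixels, m) for img, m in
                 phantom_training_set(n_images, dims=dims, seed=seed)]
        tr, va = split_by_patient(pairs, seed=seed)
        for variant in VARIANTS:
            cfg = SegModelConfig(variant=variant, depth=depth,
                                 base_channels=base_channels,
                                 aspp_rates=aspp_rates, input_size=dims, seed=seed)
            net = build_model(cfg)
            tcfg = TrainConfig(epochs=epochs, input_size=dims, seed=seed)
            net, hist = train(net, tr, va, LossWeights(), tcfg)
            preds, truths = _pooled_masks(net, va)
            report = evaluate_masks(preds, truths)
            macro = report.macro()
            rows.append({
                "seed": seed, "variant": variant,
                "cancer_iou": report.per_class["cancer"].iou,
                "cancer_f1": report.per_class["cancer"].f1,
                "macro_accuracy": macro["accuracy"],
                "macro_iou": macro["iou"],
                "macro_f1": macro["f1"],
                "best_epoch": hist.best_epoch,
                "best_val_iou": hist.best_val_metric,
            })
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged macro metrics per variant, baseline first."""
    order = {v: i for i, v in enumerate(VARIANTS)}
    out = (table.groupby("variant")[["macro_accuracy", "macro_iou", "macro_f1",
                                     "cancer_iou", "cancer_f1"]]
           .mean().reset_index())
    return out.sort_values("variant", key=lambda s: s.map(order)).reset_index(drop=True)
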