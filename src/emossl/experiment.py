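"""Label-efficiency experiment harness.

Protocol: the backbone is pre-trained exactly once on all training-split
clips (no labels).  Then, for every label budget n in the grid and every
repeat, a labeled subset of size n is drawn uniformly without replacement
from the training split; the SSL arm fine-tunes the frozen pre-trained
backbone's 6-unit head on it, while the baseline arm trains the identical
architecture from scratch on the *same* subset (paired subsets reduce
comparison variance).  Both arms are evaluated on the untouched validation
split, and means and standard deviations over repeats are reported per
(n, arm, metric) — the curves that show where pre-training pays off.

The default grid is 20, 35, 50, ..., 200 then 400, 600, ..., 1200; three
repeats per budget.  Per-cell seeds are stable hashes of (base_seed, n,
repeat), so adding grid points never perturbs existing cells.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset, EMOTIONS, TRAIN, VALIDATION
from .metrics import evaluate
from .model import Backbone, predict_emotions_batch
from .training import TrainConfig, finetune, pretrain, train_baseline

DEFAULT_GRID = tuple(range(20, 201, 15)) + tuple(range(400, 1201, 200))

ARMS = ("ssl", "baseline")


@dataclass
class ExperimentConfig:
    label_grid: tuple[int, ...] = DEFAULT_GRID
    repeats: int = 3
    base_seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if any(n < 1 for n in self.label_grid):
            raise ValueError("label budgets must be >= 1")


@dataclass
class CurveResult:
    """Tidy per-cell records plus the aggregate over repeats."""

    records: pd.DataFrame
    aggregate: pd.DataFrame


def cell_seed(base_seed: int, n: int, repeat: int, salt: str = "subset") -> int:
    """Stable per-cell seed below 2**31, independent of grid order."""
    digest = hashlib.sha256(f"{base_seed}:{n}:{repeat}:{salt}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sample_labeled_subset(ds: Dataset, n: int, seed: int):
    """Uniform sample of n labeled clips (without replacement) from the
    training split."""
    pool = ds.labeled(TRAIN)
    if n > len(pool):
        raise ValueError(
            f"requested {n} labeled clips but the training split has {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def _evaluate_arm(backbone, head, val_clips, val_true):
    preds = predict_emotions_batch(backbone, head, [c.values for c in val_clips])
    return evaluate(preds, val_true)


def run_curve(
    ds: Dataset,
    cfg: ExperimentConfig | None = None,
    backbone: Backbone | None = None,
    progress=None,
) -> CurveResult:
    """Run the full two-arm label-efficiency experiment on a standardized,
    split dataset.

    ``backbone`` may carry an already pre-trained encoder; otherwise one is
    pre-trained here on the training split.  ``progress`` is an optional
    callable invoked with a status string per cell.
    """
    cfg = cfg or ExperimentConfig()
    n_labeled = len(ds.labeled(TRAIN))
    for n in cfg.label_grid:
        if n > n_labeled:
            raise ValueError(
                f"grid value {n} exceeds the {n_labeled} labeled training clips"
            )
    val_clips = ds.subset(VALIDATION)
    if not val_clips:
        raise ValueError("validation split is empty")
    val_true = np.array([ds.labels[c.clip_id].intensities for c in val_clips])

    if backbone is None:
        pre_cfg = TrainConfig(**{**cfg.train.__dict__})
        pre_cfg.seed = cell_seed(cfg.base_seed, 0, 0, salt="pretrain")
        if progress:
            progress("pretraining backbone on full unlabeled training split")
        backbone, _ = pretrain(ds, pre_cfg)

    rows = []
    for n in cfg.label_grid:
        for repeat in range(cfg.repeats):
            seed = cell_seed(cfg.base_seed, n, repeat)
            subset = sample_labeled_subset(ds, n, seed)
            for arm in ARMS:
                arm_cfg = TrainConfig(**{**cfg.train.__dict__})
                arm_cfg.seed = cell_seed(cfg.base_seed, n, repeat, salt=arm)
                try:
                    if arm == "ssl":
                        head, _ = finetune(backbone, subset, arm_cfg)
                        report = _evaluate_arm(backbone, head, val_clips, val_true)
                    else:
                        bb, head, _ = train_baseline(subset, arm_cfg)
                        report = _evaluate_arm(bb, head, val_clips, val_true)
                except Exception as exc:  # annotate with cell context
                    raise RuntimeError(
                        f"training failed at n={n}, repeat={repeat}, arm={arm}"
                    ) from exc
                rows.append(
                    {"n_labels": n, "repeat": repeat, "model": arm, **report.as_dict()}
                )
                if progress:
                    progress(
                        f"n={n} repeat={repeat} arm={arm} "
                        f"mae={report.overall_mae:.4f} "
                        f"acc={report.overall_4class_accuracy:.4f}"
                    )
    records = pd.DataFrame(rows)
    return CurveResult(records=records, aggregate=aggregate(records))


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per (n_labels, model, metric); SD over repeats (ddof=1),
    0 when there is a single repeat."""
    metric_cols = [c for c in records.columns if c not in ("n_labels", "repeat", "model")]
    grouped = records.groupby(["n_labels", "model"])[metric_cols]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).fillna(0.0).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()


def report(cr: CurveResult, outdir: str | os.PathLike) -> list[str]:
    """Write records.csv, aggregate.csv, and mean+/-SD line plots (overall
    accuracy, overall MAE, and the six per-emotion versions of each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cr.records.empty:
        raise ValueError("cannot report an empty CurveResult")
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    written = []

    records_path = os.path.join(outdir, "records.csv")
    cr.records.to_csv(records_path, index=False)
    written.append(records_path)
    agg_path = os.path.join(outdir, "aggregate.csv")
    cr.aggregate.to_csv(agg_path, index=False)
    written.append(agg_path)

    metrics = ["overall_4class_accuracy", "overall_mae"]
    metrics += [f"accuracy_{e}" for e in EMOTIONS]
    metrics += [f"mae_{e}" for e in EMOTIONS]
    agg = cr.aggregate
    for metric in metrics:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for arm, color in zip(ARMS, ("C0", "C1")):
            sub = agg[agg["model"] == arm].sort_values("n_labels")
            ax.errorbar(
                sub["n_labels"],
                sub[f"{metric}_mean"],
                yerr=sub[f"{metric}_sd"],
                label=arm,
                color=color,
                marker="o",
                capsize=3,
            )
        ax.set_xlabel("labeled clips")
        ax.set_ylabel(metric.replace("_", " "))
        ax.legend()
        fig.tight_layout()
        fpath = os.path.join(outdir, f"{metric}.png")
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        written.append(fpath)
    return written
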