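"""Evaluation surfaces: confusion matrices, accuracy/F1, replicate
aggregation, the modality ablation, and whole-section projection figures.

Metrics are computed over masked tissue pixels with a ground-truth class
(1..3) only; background never enters.  Accuracy is overall pixel accuracy
(trace over total); F1 is macro-averaged over the three tissue classes so
that failure on the minority dysplastic class is not hidden by the large
non-epithelium class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModalityConfig, TrainConfig, TrainedModel, predict_section, train
from .patches import DatasetManifest
from .preprocess import DegenerateInputError, LabelMap, MultimodalStack, ParameterError

__all__ = [
    "ConfusionMatrix",
    "ReplicateMetrics",
    "EvalReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "aggregate_replicates",
    "evaluate_model",
    "ablation_run",
    "render_projection",
    "CLASS_COLORS",
]

TISSUE_CLASSES = (1, 2, 3)

#: fixed class colormap (background, stroma, dysplastic, non-dysplastic)
CLASS_COLORS = {
    0: (0.0, 0.0, 0.0),
    1: (0.35, 0.55, 0.95),
    2: (0.90, 0.20, 0.20),
    3: (0.30, 0.75, 0.35),
}


@dataclass
class ConfusionMatrix:
    """3x3 pixel confusion counts (rows truth 1..3, cols predicted 1..3)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ParameterError("counts must be a non-negative 3x3 matrix")
        self.counts = c

    @property
    def percent(self) -> np.ndarray:
        """Row-normalized percentages; rows with zero truth pixels stay 0."""
        row = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row > 0, 100.0 * self.counts / row, 0.0)
        return pct

    @property
    def empty_truth_rows(self) -> np.ndarray:
        return self.counts.sum(axis=1) == 0

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        names = ["non-epithelium", "dysplastic", "non-dysplastic"]
        pd.DataFrame(self.counts, index=names, columns=names).to_csv(path)


@dataclass
class ReplicateMetrics:
    accuracy_pct: float
    macro_f1: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    classes_in_truth: tuple[int, ...]
    confusion: ConfusionMatrix


@dataclass
class EvalReport:
    """Per-modality evaluation: replicate metrics plus mean +/- SD."""

    modality: str
    replicates: list[ReplicateMetrics]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 0
    class_pixel_counts: dict[int, int] = field(default_factory=dict)

    def finalize(self) -> "EvalReport":
        metrics = {
            "accuracy_pct": [r.accuracy_pct for r in self.replicates],
            "macro_f1": [r.macro_f1 for r in self.replicates],
        }
        for c in TISSUE_CLASSES:
            metrics[f"recall_{c}"] = [r.recall.get(c, np.nan) for r in self.replicates]
            metrics[f"precision_{c}"] = [r.precision.get(c, np.nan) for r in self.replicates]
        self.mean, self.sd = aggregate_replicates(metrics)
        self.n_replicates = len(self.replicates)
        counts = sum(r.confusion.counts.sum(axis=1) for r in self.replicates)
        self.class_pixel_counts = {
            c: int(counts[c - 1] / max(len(self.replicates), 1)) for c in TISSUE_CLASSES
        }
        return self

    def to_json(self, path: str | Path) -> None:
        d = {
            "modality": self.modality,
            "n_replicates": self.n_replicates,
            "mean": self.mean,
            "sd": self.sd,
            "replicates": [
                {
                    "accuracy_pct": r.accuracy_pct,
                    "macro_f1": r.macro_f1,
                    "recall": {str(k): v for k, v in r.recall.items()},
                    "precision": {str(k): v for k, v in r.precision.items()},
                    "confusion_counts": r.confusion.counts.tolist(),
                    "confusion_percent": r.confusion.percent.tolist(),
                }
                for r in self.replicates
            ],
        }
        Path(path).write_text(json.dumps(d, indent=2))


def confusion_matrix(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    mask: np.ndarray,
) -> ConfusionMatrix:
    """Pixel confusion counts restricted to mask AND truth in {1,2,3}."""
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    mask = np.asarray(mask, dtype=bool)
    if not (p.shape == t.shape == mask.shape):
        raise ParameterError("pred/truth/mask grid mismatch")
    sel = mask & np.isin(t, TISSUE_CLASSES)
    if not sel.any():
        raise DegenerateInputError("no evaluable pixels (empty mask or no truth labels)")
    tt = t[sel].astype(np.int64) - 1
    pp = np.clip(p[sel].astype(np.int64) - 1, 0, 2)
    # predictions outside 1..3 (background) are binned separately? they can
    # only arise from masked-out pixels, which sel excludes by construction
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (tt, pp), 1)
    return ConfusionMatrix(counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> ReplicateMetrics:
    """Accuracy, per-class precision/recall/F1 and macro F1 from counts.

    Classes absent from the truth are excluded from the macro mean and
    flagged via ``classes_in_truth``.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise DegenerateInputError("empty confusion matrix")
    acc = 100.0 * np.trace(counts) / counts.sum()
    precision, recall, f1 = {}, {}, {}
    present = []
    for c in TISSUE_CLASSES:
        i = c - 1
        tp = counts[i, i]
        col = counts[:, i].sum()
        row = counts[i, :].sum()
        if row > 0:
            present.append(c)
        p = tp / col if col > 0 else 0.0
        r = tp / row if row > 0 else np.nan
        precision[c] = float(p)
        recall[c] = float(r) if row > 0 else float("nan")
        if row > 0:
            f1[c] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    macro = float(np.mean([f1[c] for c in present])) if present else float("nan")
    return ReplicateMetrics(
        accuracy_pct=float(acc),
        macro_f1=macro,
        precision=precision,
        recall=recall,
        f1=f1,
        classes_in_truth=tuple(present),
        confusion=cm,
    )


def aggregate_replicates(metrics: dict[str, list[float]]) -> tuple[dict, dict]:
    """Mean and population SD (n divisor) per metric across replicates."""
    lengths = {len(v) for v in metrics.values()}
    if not metrics or 0 in lengths:
        raise ParameterError("need at least one replicate")
    mean, sd = {}, {}
    for k, v in metrics.items():
        arr = np.asarray(v, dtype=np.float64)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:  # metric undefined in every replicate (absent class)
            mean[k], sd[k] = float("nan"), float("nan")
            continue
        mean[k] = float(arr.mean())
        sd[k] = float(np.sqrt(np.mean((arr - mean[k]) ** 2)))
    return mean, sd


def evaluate_model(
    model: TrainedModel,
    stacks: list[MultimodalStack],
    truths: list[LabelMap],
    tile: int = 256,
    overlap: int = 32,
) -> ReplicateMetrics:
    """Whole-section inference over held-out sections, pooled confusion."""
    total = np.zeros((3, 3), dtype=np.int64)
    for stack, truth in zip(stacks, truths):
        pred = predict_section(model, stack, tile=tile, overlap=overlap)
        cm = confusion_matrix(pred, truth, stack.tissue_mask)
        total += cm.counts
    return metrics_from_confusion(ConfusionMatrix(total))


def ablation_run(
    manifest: DatasetManifest,
    train_config: TrainConfig,
    test_stacks: list[MultimodalStack],
    test_truths: list[LabelMap],
    modalities: tuple[str, ...] = ("DF", "IR", "COMBINED"),
    tile: int = 256,
    overlap: int = 32,
    verbose: bool = False,
) -> dict[str, EvalReport]:
    """Train and evaluate every modality on identical splits and seeds.

    Returns one EvalReport per modality; ``comparison_table`` renders them
    as a tidy DataFrame (3 modalities x n_replicates rows).
    """
    reports: dict[str, EvalReport] = {}
    for name in modalities:
        modality = ModalityConfig(name)
        models = train(manifest, modality, train_config, verbose=verbose)
        reps = [
            evaluate_model(m, test_stacks, test_truths, tile=tile, overlap=overlap)
            for m in models
        ]
        reports[name] = EvalReport(modality=name, replicates=reps).finalize()
    return reports


def comparison_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        for i, r in enumerate(rep.replicates):
            rows.append(
                {
                    "modality": name,
                    "replicate": i,
                    "accuracy_pct": r.accuracy_pct,
                    "macro_f1": r.macro_f1,
                    "dysplastic_recall": r.recall.get(2, float("nan")),
                }
            )
    return pd.DataFrame(rows)


def render_projection(
    pred: LabelMap,
    truth: LabelMap,
    channels: np.ndarray,
    out_path: str | Path,
    channel_name: str = "input",
) -> Path:
    """Write an input / prediction / ground-truth panel figure (PNG).

    Deterministic for fixed inputs: fixed class colormap, fixed layout,
    panel sizes proportional to the section grid.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch as MplPatch

    if pred.shape != truth.shape:
        raise ParameterError("pred/truth grid mismatch")
    chan = np.asarray(channels)
    if chan.ndim == 3:
        chan = chan[0]
    h, w = pred.shape
    cmap = ListedColormap([CLASS_COLORS[c] for c in range(4)])
    fig_w = 3 * 4.0
    fig_h = 4.0 * h / w + 0.6
    fig, axes = plt.subplots(1, 3, figsize=(fig_w, fig_h))
    axes[0].imshow(chan, cmap="gray")
    axes[0].set_title(channel_name)
    axes[1].imshow(pred.labels, cmap=cmap, vmin=0, vmax=3, interpolation="nearest")
    axes[1].set_title("prediction")
    axes[2].imshow(truth.labels, cmap=cmap, vmin=0, vmax=3, interpolation="nearest")
    axes[2].set_title("ground truth")
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    from .preprocess import CLASS_NAMES

    handles = [
        MplPatch(color=CLASS_COLORS[c], label=CLASS_NAMES[c]) for c in range(4)
    ]
    fig.legend(handles=handles, loc="lower center", ncol=4, frameon=False)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return out_path
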