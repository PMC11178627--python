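"""Cross-validation harness: folds, training, metrics, run comparison.

The evaluation protocol is stratified k-fold cross-validation (default
k = 5, an 80/20 train/validation rotation): each fold holds an equal
per-label share of the images, every image appears in exactly one fold,
and for each rotation a fresh classifier is trained on k-1 folds and
scored on the held-out one by argmax over class probabilities.

Metrics are accuracy plus macro-averaged precision, recall and F1
(classes are balanced by construction, so macro and weighted averaging
nearly coincide; macro is the stricter convention).  Runs sharing a fold
split are compared by the difference in mean accuracy and a two-sided
Welch t-test over per-fold accuracies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize as _sk_resize
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .augment import AugmentPolicy, apply_policy_stack
from .nn import SmallCNN
from .phantom import LABELS
from .pipelines import PipelineConfig, run_pipeline

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "MetricsReport",
    "make_folds",
    "compute_metrics",
    "train_eval",
    "compare_runs",
    "intensity_features",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class FoldSplit:
    """Label-stratified assignment of image indices to folds."""

    k: int
    assignments: np.ndarray  # fold index per image, values in [0, k)

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) index arrays for one rotation."""
        val = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, val


@dataclass(frozen=True)
class TrainConfig:
    """Training settings for one cross-validation run.

    Defaults follow the protocol of interest — Adam at learning rate
    0.001 with batch size 16, argmax class decision — at desk scale: a
    small CNN trained from scratch on down-sampled inputs for a handful
    of epochs.  A ``resnet50`` backbone is accepted for full-scale
    replication but requires an installed torch.
    """

    backbone: str = "small_cnn"
    pretrained: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 50
    pipeline: str = "baseline"
    policy: AugmentPolicy = field(default_factory=AugmentPolicy)
    seed: int = 0
    input_size: int = 48
    channels: tuple[int, ...] = (8, 16, 32, 32)
    pipeline_config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")

    def fingerprint(self) -> str:
        payload = {
            "backbone": self.backbone,
            "pretrained": self.pretrained,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "pipeline": self.pipeline,
            "policy": [
                (s.name, s.chance, s.magnitude) for s in self.policy.specs
            ],
            "policy_seed": self.policy.seed,
            "seed": self.seed,
            "input_size": self.input_size,
            "channels": list(self.channels),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[
            :16
        ]


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold and aggregate classification metrics for one run."""

    name: str
    k: int
    per_fold: pd.DataFrame  # columns = METRIC_NAMES, one row per fold
    fingerprint: str = ""

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold.std(ddof=1)

    def summary(self) -> str:
        lines = [f"run {self.name} ({self.k}-fold, config {self.fingerprint})"]
        for m in METRIC_NAMES:
            lines.append(f"  {m:<10} {self.mean[m]:.3f} +/- {self.std[m]:.3f}")
        return "\n".join(lines)


def make_folds(labels, k: int, seed: int) -> FoldSplit:
    """Stratified fold assignment: per-label counts differ by at most one.

    ``labels`` may be a sequence of label strings or a manifest DataFrame
    with a ``label`` column.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"].to_numpy()
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        short = counts[counts < k].index.tolist()
        raise ValueError(f"labels {short} have fewer than k={k} images")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, val) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[val] = fold
    return FoldSplit(k=k, assignments=assignments)


def compute_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, macro F1).

    Classes with no predictions (or no instances) contribute 0 to the
    macro average of the affected metric.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(LABELS), average="macro", zero_division=0
    )
    return float(acc), float(prec), float(rec), float(f1)


def _prepare_stacks(data, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every image once: pipeline, then resize to the network
    input resolution.  ``data`` is a sequence of (image, label) pairs."""
    stacks, ys = [], []
    label_to_idx = {lab: i for i, lab in enumerate(LABELS)}
    for img, label in data:
        stack = run_pipeline(cfg.pipeline, img, cfg.pipeline_config)
        if stack.shape[1:] != (cfg.input_size, cfg.input_size):
            stack = np.stack(
                [
                    np.clip(
                        _sk_resize(
                            ch,
                            (cfg.input_size, cfg.input_size),
                            order=1,
                            mode="edge",
                            anti_aliasing=True,
                        ),
                        0.0,
                        1.0,
                    )
                    for ch in stack
                ]
            )
        stacks.append(stack.astype(np.float32))
        ys.append(label_to_idx[label])
    return np.stack(stacks), np.asarray(ys)


def train_eval(data, folds: FoldSplit, cfg: TrainConfig, name: str | None = None) -> MetricsReport:
    """Run the full cross-validation rotation and assemble the report.

    ``data`` is a sequence of ``(image, label)`` pairs aligned with the
    fold split.  For each rotation a fresh backbone is trained on the
    preprocessed training folds — the augmentation policy is re-drawn
    per image per epoch — and evaluated on the held-out fold by argmax
    over class probabilities.  Everything (fold order, weight init,
    batch shuffling, augmentation draws) derives from ``cfg.seed``.
    """
    if cfg.backbone == "resnet50":
        raise RuntimeError(
            "the resnet50 backbone requires torch; install it and use the "
            "torch-backed runner, or use backbone='small_cnn'"
        )
    if cfg.backbone != "small_cnn":
        raise ValueError(f"unknown backbone {cfg.backbone!r}")
    x, y = _prepare_stacks(data, cfg)
    if len(x) != len(folds.assignments):
        raise ValueError("data length does not match the fold split")
    rows = []
    for fold in range(folds.k):
        train_idx, val_idx = folds.fold_indices(fold)
        model = SmallCNN(
            in_channels=3,
            n_classes=len(LABELS),
            channels=cfg.channels,
            input_size=cfg.input_size,
            lr=cfg.learning_rate,
            seed=cfg.seed * 1000 + fold,
        )
        fold_rng = np.random.default_rng([cfg.seed, fold])
        augmented = np.empty_like(x[train_idx])
        for epoch in range(cfg.epochs):
            order = fold_rng.permutation(len(train_idx))
            if cfg.policy.specs:
                for i, idx in enumerate(train_idx):
                    augmented[i] = apply_policy_stack(x[idx], cfg.policy, fold_rng)
            else:
                augmented = x[train_idx]
            xs, ys = augmented[order], y[train_idx][order]
            for start in range(0, len(xs), cfg.batch_size):
                xb = xs[start : start + cfg.batch_size]
                yb = ys[start : start + cfg.batch_size]
                try:
                    model.train_batch(xb, yb)
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"{exc} (fold {fold}, epoch {epoch})"
                    ) from exc
        pred_idx = model.predict(x[val_idx])
        y_val = [LABELS[i] for i in y[val_idx]]
        y_hat = [LABELS[i] for i in pred_idx]
        rows.append(dict(zip(METRIC_NAMES, compute_metrics(y_val, y_hat))))
    report_name = name or f"{cfg.pipeline}"
    return MetricsReport(
        name=report_name,
        k=folds.k,
        per_fold=pd.DataFrame(rows),
        fingerprint=cfg.fingerprint(),
    )


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with a variance floor so that
    zero-variance fold accuracies still yield a defined answer."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va = max(a.var(ddof=1), 1e-12)
    vb = max(b.var(ddof=1), 1e-12)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2 * stats.t.sf(abs(t), df))


def compare_runs(reports: list[MetricsReport], baseline_name: str) -> pd.DataFrame:
    """Accuracy deltas and Welch p-values of each run against a baseline.

    All reports must share the same fold split (same k); output has one
    row per non-baseline report.
    """
    by_name = {r.name: r for r in reports}
    if baseline_name not in by_name:
        raise ValueError(f"baseline run {baseline_name!r} not among the reports")
    base = by_name[baseline_name]
    rows = []
    for rep in reports:
        if rep.name == baseline_name:
            continue
        if rep.k != base.k:
            raise ValueError(
                f"run {rep.name!r} used {rep.k} folds but baseline used {base.k}"
            )
        acc = rep.per_fold["accuracy"].to_numpy()
        base_acc = base.per_fold["accuracy"].to_numpy()
        rows.append(
            {
                "run": rep.name,
                "mean_accuracy": acc.mean(),
                "delta_vs_baseline": acc.mean() - base_acc.mean(),
                "p_value": 1.0 if np.array_equal(acc, base_acc) else _welch(acc, base_acc),
            }
        )
    return pd.DataFrame(rows)


def intensity_features(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Pixel-statistics feature vector for the reference linear probe.

    Global mean/spread and quantile structure, optionally extended with
    image statistics over the oracle lesion region: the lesion-to-ring
    intensity deficit, the contrast-to-noise score, and the within-region
    spread.  The regional features are zero for an empty (no-pathology)
    mask and carry no signal when the lesion amplitude is zero, so probe
    accuracy tracks lesion conspicuity rather than mask geometry.
    """
    from .phantom import lesion_contrast_metric

    arr = np.asarray(img, dtype=np.float64)
    qs = np.percentile(arr, [5, 10, 25, 50, 75, 95])
    low = np.sort(arr.ravel())[: max(1, arr.size // 10)]
    feats = [np.concatenate([[arr.mean(), arr.std(), (arr < 0.3).mean(), low.mean()], qs])]
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.any():
            import scipy.ndimage as ndi

            ring = ndi.binary_dilation(m, iterations=5) & ~m
            deficit = arr[ring].mean() - arr[m].mean()
            feats.append(
                [deficit, lesion_contrast_metric(arr, m), arr[m].std()]
            )
        else:
            feats.append([0.0, 0.0, 0.0])
    return np.concatenate(feats)
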