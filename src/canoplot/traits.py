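"""Plot-level trait extraction: canopy height, modality fusion, and
growth-habit / mainstem-prominence classification.

Canopy height comes straight from the nDSM: the 224 x 224 patch is split
horizontally at the plot center, the chosen statistic (max by default, or a
high percentile) is taken per row half, and the plot's height is the mean of
the two halves, in cm. The multimodal "combined" input embeds height into
the RGB image by adding the nDSM (scaled to cm) to the green channel with
clipping at 255, which keeps three channels.

Classification uses a compact built-in model family: a frozen pooling
encoder (per-channel block means on a fixed grid) feeding a trainable
fully-connected head optimized with cross-entropy, decoupled-weight-decay
Adam, dropout 0.5 and a one-cycle cosine learning-rate schedule that decays
to 0.001 of the peak rate. Only the head trains; the encoder has no
parameters. Model selection follows a grid search over batch size, epochs
and learning rate with stratified 5-fold cross-validation scored by macro
F1, and the best configuration is retrained/tested several times to report
mean and SD accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import ClassCounts, classification_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "PlotPatch",
    "TrainSpec",
    "extract_canopy_height",
    "fuse_ndsm_rgb",
    "build_dataset",
    "train_trait_classifier",
    "evaluate_trait_classifier",
    "TraitClassifier",
]

_STATS = {
    "max": lambda a: float(np.nanmax(a)),
    "p95": lambda a: float(np.nanpercentile(a, 95)),
    "p97": lambda a: float(np.nanpercentile(a, 97)),
    "p99": lambda a: float(np.nanpercentile(a, 99)),
}

# frozen-encoder pooling grid and head width per registry key; keys follow
# the familiar CNN naming in decreasing-capacity order
_MODEL_PRESETS = {
    "alexnet": dict(pool=16, hidden=192),
    "resnet18": dict(pool=8, hidden=96),
    "efficientnet_b0": dict(pool=4, hidden=48),
}


@dataclass
class PlotPatch:
    """One plot's co-registered RGB and nDSM crops."""

    rgb: np.ndarray  # (224, 224, 3) uint8
    ndsm: np.ndarray  # (224, 224) float, meters
    center_y: float  # split row, patch coordinates
    plot_id: int = 0
    single_row: bool = False
    occupied_half: str | None = None
    cell_y: tuple[float, float] | None = None  # bed-line bounds, patch coords

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != (224, 224) or self.ndsm.shape != (224, 224):
            raise ValueError("patches must be exactly 224 x 224")


def extract_canopy_height(patch: PlotPatch, stat: str = "max") -> float:
    """Canopy height of one plot in cm.

    The nDSM patch is split at ``center_y`` into top/bottom halves; the
    statistic (``max``, ``p95``, ``p97`` or ``p99``) is computed per half
    over finite pixels and the plot height is the mean of the two, times 100.
    When ``cell_y`` bed-line bounds are present the patch is clipped to them
    first, so canopy from the neighbouring bed inside the crop box cannot
    leak into the statistic. Single-row plots use the occupied half only; an
    all-nodata half falls back to the other half with a warning.
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {sorted(_STATS)}")
    fn = _STATS[stat]
    y_lo, y_hi = 0, patch.ndsm.shape[0]
    if patch.cell_y is not None:
        y_lo = max(int(np.ceil(patch.cell_y[0])), 0)
        y_hi = min(int(np.floor(patch.cell_y[1])) + 1, patch.ndsm.shape[0])
    cy = int(round(patch.center_y))
    cy = min(max(cy, y_lo), y_hi)
    halves = {"top": patch.ndsm[y_lo:cy], "bottom": patch.ndsm[cy:y_hi]}
    if patch.single_row and patch.occupied_half in halves:
        halves = {patch.occupied_half: halves[patch.occupied_half]}
    stats = {}
    for name, half in halves.items():
        finite = half[np.isfinite(half)]
        stats[name] = fn(finite) if finite.size else None
    valid = [v for v in stats.values() if v is not None]
    if not valid:
        raise ValueError(f"plot {patch.plot_id}: no finite nDSM values")
    if len(valid) < len(stats):
        logger.warning("plot %d: one half is all nodata; using the other", patch.plot_id)
    return max(float(np.mean(valid)) * 100.0, 0.0)


def fuse_ndsm_rgb(patch: PlotPatch) -> np.ndarray:
    """Embed height into the green channel: G' = clip(G + 100 * nDSM, 0, 255).

    The nDSM (meters) is scaled by 100 to cm before the addition; sums above
    255 clip and negative sums floor at 0. R and B are unchanged.
    """
    out = patch.rgb.copy()
    nd = np.where(np.isfinite(patch.ndsm), patch.ndsm, 0.0)
    g = np.rint(out[..., 1].astype(np.float64) + 100.0 * nd)
    out[..., 1] = np.clip(g, 0, 255).astype(np.uint8)
    return out


def _ndsm_as_rgb(patch: PlotPatch) -> np.ndarray:
    """Height-only input: the cm-scaled nDSM replicated into 3 channels so a
    standard 3-channel model applies unchanged."""
    nd = np.where(np.isfinite(patch.ndsm), patch.ndsm, 0.0)
    chan = np.clip(np.rint(100.0 * nd), 0, 255).astype(np.uint8)
    return np.stack([chan] * 3, axis=-1)


_MODALITIES = {
    "rgb": lambda p: p.rgb,
    "ndsm": _ndsm_as_rgb,
    "combined": fuse_ndsm_rgb,
}


@dataclass(frozen=True)
class TrainSpec:
    """Classifier training protocol and hyperparameter grid."""

    model_name: str = "alexnet"
    modality: str = "combined"
    batch_grid: tuple[int, ...] = (16, 32)
    epochs_grid: tuple[int, ...] = (10, 15, 20)
    lr_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    dropout: float = 0.5
    weight_decay: float = 0.01
    folds: int = 5
    runs: int = 10
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_name not in _MODEL_PRESETS:
            raise ValueError(f"model_name must be one of {sorted(_MODEL_PRESETS)}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {sorted(_MODALITIES)}")
        if not 0 < self.test_frac < 1:
            raise ValueError("test_frac must be in (0, 1)")


_AUGMENTS = (
    lambda img: img[:, ::-1],  # horizontal flip
    lambda img: img[::-1, :],  # vertical flip
    lambda img: np.swapaxes(img, 0, 1),  # mirror across the diagonal
)


def build_dataset(
    patches: list[PlotPatch],
    labels: list[int],
    modality: str,
    spec: TrainSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified 80:20 train/test split with flip augmentation.

    Returns (X_train, y_train, X_test, y_test); the training images are the
    originals plus their horizontal flip, vertical flip and mirror (4x).
    Raises when fewer than two classes are present or a class is missing
    from either side of the split.
    """
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    images = np.stack([_MODALITIES[modality](p) for p in patches])
    idx = np.arange(len(patches))
    train_idx, test_idx = train_test_split(
        idx, test_size=spec.test_frac, stratify=y, random_state=spec.seed % (2**32)
    )
    for part, name in ((train_idx, "train"), (test_idx, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"a class is absent from the {name} split; insufficient data")
    x_train = [images[i] for i in train_idx]
    y_train = [y[i] for i in train_idx]
    augmented_x = list(x_train)
    augmented_y = list(y_train)
    for aug in _AUGMENTS:
        augmented_x.extend(aug(img) for img in x_train)
        augmented_y.extend(y_train)
    return (
        np.stack(augmented_x),
        np.asarray(augmented_y),
        images[test_idx],
        y[test_idx],
    )


# ---------------------------------------------------------------------------
# frozen pooling encoder + trainable fully-connected head
# ---------------------------------------------------------------------------


def _pool_features(images: np.ndarray, grid: int) -> np.ndarray:
    """Per-channel block-mean pooling to a grid x grid map, flattened.

    Parameter-free ("frozen"): the only trainable weights live in the head.
    """
    n, h, w, c = images.shape
    bh, bw = h // grid, w // grid
    x = images[:, : grid * bh, : grid * bw].astype(np.float64) / 255.0
    x = x.reshape(n, grid, bh, grid, bw, c).mean(axis=(2, 4))
    return x.reshape(n, -1)


class TraitClassifier:
    """Two-class classifier: frozen pooled features + one hidden FC layer.

    Training: cross-entropy loss, AdamW (decoupled weight decay), dropout on
    the hidden activations, one-cycle cosine schedule (10 % linear warmup,
    cosine decay to 0.001 of the peak learning rate).
    """

    def __init__(
        self,
        model_name: str = "alexnet",
        lr: float = 1e-3,
        batch_size: int = 16,
        epochs: int = 15,
        dropout: float = 0.5,
        weight_decay: float = 0.01,
        seed: int = 0,
    ) -> None:
        preset = _MODEL_PRESETS[model_name]
        self.model_name = model_name
        self.pool = preset["pool"]
        self.hidden = preset["hidden"]
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.seed = seed
        self._params: dict[str, np.ndarray] | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, images: np.ndarray, y: np.ndarray) -> "TraitClassifier":
        return self.fit_features(_pool_features(images, self.pool), y)

    def fit_features(self, raw: np.ndarray, y: np.ndarray) -> "TraitClassifier":
        """Fit from pre-pooled encoder features (pooling is deterministic, so
        callers doing grid search pool once and reuse)."""
        rng = np.random.default_rng(self.seed)
        self._mu = raw.mean(axis=0)
        self._sd = raw.std(axis=0) + 1e-8
        x = (raw - self._mu) / self._sd
        y = np.asarray(y, dtype=int)
        n, d = x.shape
        h = self.hidden
        p = {
            "w1": rng.normal(0, np.sqrt(2.0 / d), size=(d, h)),
            "b1": np.zeros(h),
            "w2": rng.normal(0, np.sqrt(2.0 / h), size=(h, 2)),
            "b2": np.zeros(2),
        }
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(val) for k, val in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        steps_per_epoch = max(n // self.batch_size, 1)
        total = self.epochs * steps_per_epoch
        warm = max(int(0.1 * total), 1)
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(steps_per_epoch):
                batch = order[s * self.batch_size : (s + 1) * self.batch_size]
                if batch.size == 0:
                    continue
                step += 1
                if step <= warm:
                    lr_t = self.lr * step / warm
                else:
                    frac = (step - warm) / max(total - warm, 1)
                    lr_t = 0.001 * self.lr + 0.5 * (self.lr - 0.001 * self.lr) * (
                        1 + np.cos(np.pi * min(frac, 1.0))
                    )
                xb, yb = x[batch], y[batch]
                z1 = xb @ p["w1"] + p["b1"]
                a1 = np.maximum(z1, 0.0)
                keep = (rng.random(a1.shape) >= self.dropout) / (1 - self.dropout)
                a1d = a1 * keep
                z2 = a1d @ p["w2"] + p["b2"]
                z2 -= z2.max(axis=1, keepdims=True)
                expz = np.exp(z2)
                prob = expz / expz.sum(axis=1, keepdims=True)
                delta2 = prob
                delta2[np.arange(len(yb)), yb] -= 1.0
                delta2 /= len(yb)
                grads = {
                    "w2": a1d.T @ delta2,
                    "b2": delta2.sum(axis=0),
                }
                delta1 = (delta2 @ p["w2"].T) * keep * (z1 > 0)
                grads["w1"] = xb.T @ delta1
                grads["b1"] = delta1.sum(axis=0)
                for k in p:
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    m_hat = m[k] / (1 - beta1**step)
                    v_hat = v[k] / (1 - beta2**step)
                    p[k] -= lr_t * (m_hat / (np.sqrt(v_hat) + eps))
                    if k.startswith("w"):  # decoupled weight decay
                        p[k] -= lr_t * self.weight_decay * p[k]
        self._params = p
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_features(_pool_features(images, self.pool))

    def predict_features(self, raw: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("classifier is not fitted")
        x = (raw - self._mu) / self._sd
        p = self._params
        a1 = np.maximum(x @ p["w1"] + p["b1"], 0.0)
        z2 = a1 @ p["w2"] + p["b2"]
        return np.argmax(z2, axis=1)


@dataclass
class TraitModelResult:
    model: TraitClassifier
    cv_table: pd.DataFrame
    best_params: dict
    accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    recall0: float
    recall1: float


def train_trait_classifier(
    datasets: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    spec: TrainSpec,
) -> TraitModelResult:
    """Grid search + cross-validation + repeated final runs.

    Every (batch, epochs, lr) combination is scored by mean macro F1 over
    stratified k-fold cross-validation on the training set; the best
    combination is retrained and tested ``spec.runs`` times with distinct
    seeds, reporting mean and SD accuracy and per-class recall from the
    pooled confusion counts.
    """
    x_train, y_train, x_test, y_test = datasets
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    pool = _MODEL_PRESETS[spec.model_name]["pool"]
    f_train = _pool_features(x_train, pool)
    f_test = _pool_features(x_test, pool)
    rows = []
    for batch in spec.batch_grid:
        for epochs in spec.epochs_grid:
            for lr in spec.lr_grid:
                skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed % (2**32))
                fold_scores = []
                for fold, (tr, va) in enumerate(skf.split(x_train, y_train)):
                    if len(np.unique(y_train[tr])) < 2:
                        raise ValueError("a CV fold contains a single class")
                    clf = TraitClassifier(
                        spec.model_name, lr=lr, batch_size=batch, epochs=epochs,
                        dropout=spec.dropout, weight_decay=spec.weight_decay,
                        seed=spec.seed + 31 * fold,
                    ).fit_features(f_train[tr], y_train[tr])
                    pred = clf.predict_features(f_train[va])
                    fold_scores.append(f1_score(y_train[va], pred, average="macro"))
                rows.append(
                    dict(batch=batch, epochs=epochs, lr=lr,
                         **{f"fold{f}": s for f, s in enumerate(fold_scores)},
                         mean_f1=float(np.mean(fold_scores)))
                )
    cv_table = pd.DataFrame(rows)
    best = cv_table.loc[cv_table["mean_f1"].idxmax()]
    best_params = dict(batch=int(best["batch"]), epochs=int(best["epochs"]), lr=float(best["lr"]))

    accuracies = []
    counts = np.zeros(4, dtype=int)  # t0, t1, f0, f1
    final = None
    for run in range(spec.runs):
        clf = TraitClassifier(
            spec.model_name, lr=best_params["lr"], batch_size=best_params["batch"],
            epochs=best_params["epochs"], dropout=spec.dropout,
            weight_decay=spec.weight_decay, seed=spec.seed + 1000 + run,
        ).fit_features(f_train, y_train)
        pred = clf.predict_features(f_test)
        accuracies.append(float(np.mean(pred == y_test)))
        counts[0] += int(np.sum((pred == 0) & (y_test == 0)))
        counts[1] += int(np.sum((pred == 1) & (y_test == 1)))
        counts[2] += int(np.sum((pred != 0) & (y_test == 0)))
        counts[3] += int(np.sum((pred != 1) & (y_test == 1)))
        final = clf
    _, r0, r1 = classification_metrics(ClassCounts(*map(int, counts)))
    return TraitModelResult(
        model=final,
        cv_table=cv_table,
        best_params=best_params,
        accuracies=accuracies,
        mean_accuracy=float(np.mean(accuracies)),
        sd_accuracy=float(np.std(accuracies)),
        recall0=r0,
        recall1=r1,
    )


def evaluate_trait_classifier(
    model: TraitClassifier, x_test: np.ndarray, y_test: np.ndarray
) -> tuple[float, float, float]:
    """(accuracy %, recall class 0 %, recall class 1 %) on a held-out set."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(x_test)
    y = np.asarray(y_test, dtype=int)
    counts = ClassCounts(
        t0=int(np.sum((pred == 0) & (y == 0))),
        t1=int(np.sum((pred == 1) & (y == 1))),
        f0=int(np.sum((pred != 0) & (y == 0))),
        f1=int(np.sum((pred != 1) & (y == 1))),
    )
    return classification_metrics(counts)
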