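"""Resistance classification of 4-band patches with a convolutional network.

The training protocol follows the field study: a 3x3 stem convolution maps
the 4-channel (WSRI, R, G, B) input to 3 channels, followed by a
convolutional backbone trained from scratch, a fully connected head with
30% dropout, and a 2-class (resistant / susceptible) output. Optimization
is Adam at a 1e-4 learning rate with 1e-3 weight decay, batch size 128,
300 epochs of 10 batches each, with rotation augmentation applied
on the fly per batch, and metrics averaged over five repeats of randomized
8:2 holdback cross-validation.

Backbones: ``small_cnn`` (the desk-scale default), plus ``resnet18`` /
``resnet50`` — residual networks with the canonical stage depths (2-2-2-2
basic blocks / 3-4-6-3 bottlenecks) at reduced channel widths so they run
on one CPU. :func:`desk_config` gives a reduced protocol (fewer epochs,
proportionally larger learning rate, smaller batches/patches) for
laptop-scale experiments; the full protocol remains the default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nnet
from .labeling import PatchDataset, split_dataset
from .segmentation import ConfusionReport, confusion

__all__ = [
    "NetConfig",
    "balance_classes",
    "shuffle_labels",
    "TrainReport",
    "FEATURE_CHANNELS",
    "desk_config",
    "build_network",
    "patch_arrays",
    "train",
    "cross_validate",
    "evaluate_by_condition",
]

#: Channel subsets of the (WSRI, R, G, B) patch stack per feature type.
FEATURE_CHANNELS: dict[str, tuple[int, ...]] = {
    "wsri_rgb": (0, 1, 2, 3),
    "wsri": (0,),
    "rgb": (1, 2, 3),
}


@dataclass
class NetConfig:
    """Network and training hyper-parameters (defaults = study protocol)."""

    backbone: str = "small_cnn"
    in_channels: int = 4
    width: int = 8  # base channel width of the backbone
    dropout_rate: float = 0.30
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    batch_size: int = 128
    epochs: int = 300
    batches_per_epoch: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")


def desk_config(**overrides) -> NetConfig:
    """Reduced desk-scale protocol: 20 epochs at a learning rate scaled up
    to compensate for the ~15x fewer optimizer steps, batch size 64."""
    base = dict(epochs=20, learning_rate=3e-3, batch_size=64)
    base.update(overrides)
    return NetConfig(**base)


@dataclass
class TrainReport:
    """Per-epoch curves and the final validation confusion matrix."""

    losses: list[float]
    train_accuracies: list[float]
    val_confusion: ConfusionReport
    val_accuracy: float
    repeat_id: int = 0
    epochs_run: int = 0
    n_parameters: int = 0
    config: NetConfig | None = None


# -- architectures ---------------------------------------------------------


def _head(in_f: int, dropout: float, rng: np.random.Generator) -> list[nnet.Layer]:
    return [
        nnet.Dense(in_f, 32, rng=rng),
        nnet.ReLU(),
        nnet.Dropout(dropout, rng=rng),
        nnet.Dense(32, 2, rng=rng),
    ]


def _basic_block(c_in: int, c_out: int, stride: int, rng) -> nnet.Residual:
    main = nnet.Sequential(
        [
            nnet.Conv2d(c_in, c_out, 3, stride=stride, rng=rng),
            nnet.ReLU(),
            nnet.Conv2d(c_out, c_out, 3, rng=rng),
        ]
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nnet.Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
    return nnet.Residual(main, shortcut)


def _bottleneck_block(c_in: int, c_mid: int, stride: int, rng) -> nnet.Residual:
    c_out = 4 * c_mid
    main = nnet.Sequential(
        [
            nnet.Conv2d(c_in, c_mid, 1, rng=rng),
            nnet.ReLU(),
            nnet.Conv2d(c_mid, c_mid, 3, stride=stride, rng=rng),
            nnet.ReLU(),
            nnet.Conv2d(c_mid, c_out, 1, rng=rng),
        ]
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nnet.Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
    return nnet.Residual(main, shortcut)


def balance_classes(dataset: PatchDataset, seed: int = 0) -> PatchDataset:
    """Subsample majority-class ROIs so both classes have equal ROI counts.

    Keeps chance accuracy at 0.5 for recovery and label-shuffle controls.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[bool, list[int]] = {True: [], False: []}
    for roi in dataset.roi_ids():
        label = next(p.label for p in dataset.patches if p.roi_id == roi)
        by_class[label.is_resistant].append(roi)
    n = min(len(by_class[True]), len(by_class[False]))
    keep: set[int] = set()
    for ids in by_class.values():
        keep.update(int(i) for i in rng.permutation(ids)[:n])
    patches = [p for p in dataset.patches if p.roi_id in keep]
    return PatchDataset(patches, dict(dataset.provenance))


def shuffle_labels(dataset: PatchDataset, seed: int = 0) -> PatchDataset:
    """Permute resistance labels across patches (null-model control)."""
    from dataclasses import replace as _replace

    rng = np.random.default_rng(seed)
    labels = [p.label for p in dataset.patches]
    perm = rng.permutation(len(labels))
    patches = [
        _replace(p, label=labels[j]) for p, j in zip(dataset.patches, perm)
    ]
    return PatchDataset(patches, dict(dataset.provenance))


def build_network(config: NetConfig) -> nnet.Sequential:
    """Build the classifier: 3x3 stem (in_channels -> 3) + ReLU, backbone
    without pretrained weights, dropout-regularized FC head, 2 logits."""
    rng = np.random.default_rng([config.seed, 77])
    w = config.width
    stem: list[nnet.Layer] = [
        nnet.Conv2d(config.in_channels, 3, 3, rng=rng, skip_input_grad=True),
        nnet.ReLU(),
    ]
    if config.backbone == "small_cnn":
        body: list[nnet.Layer] = [
            nnet.Conv2d(3, w, 3, stride=2, rng=rng),
            nnet.ReLU(),
            nnet.MaxPool2d(2),
            nnet.Conv2d(w, 2 * w, 3, rng=rng),
            nnet.ReLU(),
            nnet.MaxPool2d(2),
            nnet.GlobalAvgPool(),
        ]
        feat = 2 * w
    elif config.backbone in ("resnet18", "resnet50"):
        body = [nnet.Conv2d(3, w, 3, stride=2, rng=rng), nnet.ReLU(), nnet.MaxPool2d(2)]
        if config.backbone == "resnet18":
            depths, block = (2, 2, 2, 2), "basic"
        else:
            depths, block = (3, 4, 6, 3), "bottleneck"
        c_in = w
        for stage, n_blocks in enumerate(depths):
            c = w * (2**stage)
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                if block == "basic":
                    body.append(_basic_block(c_in, c, stride, rng))
                    c_in = c
                else:
                    body.append(_bottleneck_block(c_in, c, stride, rng))
                    c_in = 4 * c
        body.append(nnet.GlobalAvgPool())
        feat = c_in
    else:
        raise ValueError(
            f"unknown backbone {config.backbone!r}; choose small_cnn, resnet18 or resnet50"
        )
    return nnet.Sequential(stem + body + _head(feat, config.dropout_rate, rng))


# -- data plumbing ---------------------------------------------------------


def patch_arrays(
    dataset: PatchDataset, split: str | None = None, feature: str = "wsri_rgb"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset (or one split of it) into (X, y) arrays.

    ``y`` is 1 for resistant, 0 for susceptible; ``feature`` selects the
    channel subset (wsri_rgb / wsri / rgb).
    """
    channels = FEATURE_CHANNELS[feature]
    patches = dataset.patches if split is None else [
        p for p in dataset.patches if p.split == split
    ]
    if not patches:
        raise ValueError(f"no patches in split {split!r}")
    X = np.stack([p.pixel_array[list(channels)] for p in patches])
    y = np.array([1 if p.label.is_resistant else 0 for p in patches], dtype=np.int64)
    return X, y


def _standardize(X: np.ndarray, stats=None):
    if stats is None:
        mean = X.mean(axis=(0, 2, 3), keepdims=True)
        sd = X.std(axis=(0, 2, 3), keepdims=True)
        sd[sd == 0] = 1.0
        stats = (mean, sd)
    mean, sd = stats
    return (X - mean) / sd, stats


def _evaluate(model: nnet.Sequential, X: np.ndarray, y: np.ndarray,
              batch: int = 256) -> np.ndarray:
    preds = []
    for i in range(0, len(X), batch):
        logits = model.forward(X[i : i + batch], train=False)
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def train(
    dataset: PatchDataset,
    config: NetConfig | None = None,
    feature: str = "wsri_rgb",
    repeat_id: int = 0,
    model: nnet.Sequential | None = None,
) -> tuple[nnet.Sequential, TrainReport]:
    """Train the classifier on a split (unaugmented) dataset.

    Batches are drawn from the training split with a fresh random rotation
    per sampled patch (real-time augmentation). Returns the fitted model
    and a :class:`TrainReport` with per-epoch loss/accuracy curves and the
    validation confusion matrix.
    """
    config = config or NetConfig()
    config = replace(config, in_channels=len(FEATURE_CHANNELS[feature]))
    X_train, y_train = patch_arrays(dataset, "train", feature)
    X_val, y_val = patch_arrays(dataset, "val", feature)
    if np.unique(y_train).size < 2:
        raise ValueError("training split contains a single class")
    X_train, stats = _standardize(X_train)
    X_val, _ = _standardize(X_val, stats)
    # single precision is ample for SGD and roughly halves CPU time
    X_train = X_train.astype(np.float32)
    X_val = X_val.astype(np.float32)

    if model is None:
        model = build_network(config)
    for layer, name in model.parameters():
        layer.params[name] = layer.params[name].astype(np.float32)
    opt = nnet.Adam(model, lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng([config.seed, 31 + repeat_id])

    losses: list[float] = []
    accs: list[float] = []
    n = len(X_train)
    for _epoch in range(config.epochs):
        epoch_loss = 0.0
        correct = 0
        seen = 0
        for _b in range(config.batches_per_epoch):
            idx = rng.integers(0, n, size=min(config.batch_size, n))
            xb = X_train[idx]
            # real-time augmentation: independent random rotation per patch
            ks = rng.integers(0, 4, size=len(idx))
            xb = np.stack([np.rot90(x, k=-int(k), axes=(1, 2)) for x, k in zip(xb, ks)])
            yb = y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = nnet.softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            correct += int((np.argmax(logits, axis=1) == yb).sum())
            seen += len(yb)
        losses.append(epoch_loss / config.batches_per_epoch)
        accs.append(correct / seen)

    val_pred = _evaluate(model, X_val, y_val)
    report_cm = confusion(y_val, val_pred)
    report = TrainReport(
        losses=losses,
        train_accuracies=accs,
        val_confusion=report_cm,
        val_accuracy=report_cm.overall_accuracy,
        repeat_id=repeat_id,
        epochs_run=config.epochs,
        n_parameters=model.n_params(),
        config=config,
    )
    return model, report


def cross_validate(
    dataset: PatchDataset,
    config: NetConfig | None = None,
    repeats: int = 5,
    feature: str = "wsri_rgb",
    ratio: float = 0.8,
) -> dict:
    """Repeated randomized holdback cross-validation.

    Each repeat redraws the 8:2 ROI split before augmentation, trains from
    scratch and evaluates on its validation split. Returns mean and sd of
    validation accuracy plus the per-repeat reports.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    config = config or NetConfig()
    if len(dataset.roi_ids()) < 5:
        raise ValueError("dataset too small for a holdback split")
    reports = []
    for r in range(repeats):
        ds = split_dataset(dataset, ratio=ratio, seed=config.seed * 1000 + r)
        _, rep = train(ds, config, feature=feature, repeat_id=r)
        reports.append(rep)
    accs = np.array([rep.val_accuracy for rep in reports])
    return {
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)),
        "accuracies": accs.tolist(),
        "reports": reports,
    }


def evaluate_by_condition(
    groups: dict,
    config: NetConfig | None = None,
    repeats: int = 3,
    features: tuple[str, ...] = ("wsri_rgb",),
) -> pd.DataFrame:
    """Accuracy table over experimental conditions (day, density, feature).

    ``groups`` maps a condition key (e.g. a day, a density, or any hashable)
    to an unaugmented :class:`PatchDataset` whose provenance carries the
    condition metadata; a dataset without ``day`` provenance raises. Each
    (condition, feature) cell is a repeated-holdback mean accuracy.
    """
    rows = []
    for key, ds in groups.items():
        prov = ds.provenance or {}
        if prov.get("day") is None:
            raise ValueError(f"dataset for condition {key!r} lacks 'day' provenance")
        for feat in features:
            cv = cross_validate(ds, config, repeats=repeats, feature=feat)
            rows.append(
                dict(
                    condition=key,
                    day=prov.get("day"),
                    density=prov.get("density"),
                    feature=feat,
                    mean_accuracy=cv["mean_accuracy"],
                    sd_accuracy=cv["sd_accuracy"],
                )
            )
    return pd.DataFrame(rows)
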