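"""Dual volumetric deep feature extractors.

Two families are provided:

* a 3D CNN whose convolution/pooling layout was fixed by an ablation over
  four variants — the selected variant stacks convolution blocks of
  2 + 3 + 2 layers with one pooling stage per block — and
* a 15-layer residual network with two stem convolution blocks and five
  residual stages of three units each (two convolutions + skip per unit).

Both networks expose 1000-wide fully connected *tap points* addressed by
name (``FC1``/``FC2`` on the CNN, ``FC4`` on the residual net).  ``FC3``
is the element-wise-max merge of FC1 and FC2 and is computed on demand.
Stacking FC3 with FC4 yields the 2000-column matrix consumed downstream.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .volume_io import VolumeSample

__all__ = [
    "KINDS",
    "NetworkSpec",
    "TrainConfig",
    "FeatureMatrix",
    "build_extractor",
    "train_extractor",
    "extract_features",
    "fc_concat_max",
    "stack_features",
]

KINDS = ("cnn_base", "cnn_variant1", "cnn_variant2", "cnn_variant3", "resnet15")

#: convolution-block layout per CNN kind (filters per conv, grouped by block)
_CNN_BLOCKS = {
    "cnn_base": ((32, 32),),
    "cnn_variant1": ((32, 32, 32),),
    "cnn_variant2": ((32, 32), (64, 64, 64)),
    "cnn_variant3": ((32, 32), (64, 64, 64), (128, 128)),
}


@dataclass
class NetworkSpec:
    """An initialized network plus its layer manifest and tap map."""

    kind: str
    n_classes: int
    input_shape: tuple[int, int, int]
    layer_manifest: list[tuple[int, str, dict]]
    tap_points: dict[str, int]
    network: nn.Sequential = field(repr=False)
    fc_width: int = 1000

    def manifest_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "n_classes": self.n_classes,
                "input_shape": list(self.input_shape),
                "fc_width": self.fc_width,
                "layers": [
                    {"index": i, "kind": k, "params": p}
                    for i, k, p in self.layer_manifest
                ],
                "tap_points": self.tap_points,
            },
            indent=2,
        )


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 30
    weight_decay: float = 1e-4
    optimizer: str = "adam"
    batch_size: int = 64
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FeatureMatrix:
    """Samples x features with per-column provenance."""

    values: np.ndarray
    feature_provenance: list[tuple[str, str]]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.feature_provenance) != self.values.shape[1]:
            raise ValueError("provenance length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _check_input_shape(input_shape: Sequence[int], n_pools: int) -> tuple:
    shape = tuple(int(s) for s in input_shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"input_shape must be a positive voxel triple, got {shape}")
    if any(s < 2 ** n_pools for s in shape):
        raise ValueError(
            f"input shape {shape} incompatible with {n_pools} pooling stages")
    return shape


def _build_cnn(kind: str, input_shape, n_classes: int, rng, fc_width: int,
               width_scale: float, dtype) -> tuple[nn.Sequential, list, dict]:
    blocks = _CNN_BLOCKS[kind]
    shape = _check_input_shape(input_shape, n_pools=len(blocks))
    layers: list[tuple[str, nn.Layer]] = []
    manifest: list[tuple[int, str, dict]] = [(1, "input", {"shape": list(shape)})]
    c_in = 1
    idx = 2
    for bi, block in enumerate(blocks, start=1):
        for ci, c_out in enumerate(block, start=1):
            c_out = max(2, int(round(c_out * width_scale)))
            name = f"b{bi}_conv{ci}"
            layers.append((name, nn.Conv3D(c_in, c_out, rng, dtype=dtype)))
            manifest.append((idx, "conv3d", {"name": name, "filters": c_out,
                                             "kernel": [3, 3, 3]}))
            idx += 1
            layers.append((f"b{bi}_relu{ci}", nn.ReLU()))
            manifest.append((idx, "relu", {"name": f"b{bi}_relu{ci}"}))
            idx += 1
            c_in = c_out
        layers.append((f"b{bi}_pool", nn.MaxPool3D()))
        manifest.append((idx, "maxpool3d", {"name": f"b{bi}_pool",
                                            "size": [2, 2, 2]}))
        idx += 1
        layers.append((f"b{bi}_bn", nn.BatchNorm3D(c_in, dtype=dtype)))
        manifest.append((idx, "batchnorm3d", {"name": f"b{bi}_bn"}))
        idx += 1
    layers.append(("gmp", nn.GlobalMaxPool3D()))
    manifest.append((idx, "global_max_pool", {"name": "gmp"}))
    idx += 1
    layers.append(("fc1", nn.Dense(c_in, fc_width, rng, dtype=dtype)))
    manifest.append((idx, "dense", {"name": "fc1", "units": fc_width}))
    idx += 1
    layers.append(("fc1_act", nn.ReLU()))
    manifest.append((idx, "relu", {"name": "fc1_act"}))
    fc1_idx = idx
    idx += 1
    layers.append(("fc2", nn.Dense(fc_width, fc_width, rng, dtype=dtype)))
    manifest.append((idx, "dense", {"name": "fc2", "units": fc_width}))
    idx += 1
    layers.append(("fc2_act", nn.ReLU()))
    manifest.append((idx, "relu", {"name": "fc2_act"}))
    fc2_idx = idx
    idx += 1
    layers.append(("head", nn.Dense(fc_width, n_classes, rng, dtype=dtype)))
    manifest.append((idx, "dense_softmax", {"name": "head", "units": n_classes}))
    taps = {"FC1": fc1_idx, "FC2": fc2_idx, "FC3": -1}  # FC3 is virtual
    return nn.Sequential(layers), manifest, taps


def _build_resnet(input_shape, n_classes: int, rng, fc_width: int,
                  width_scale: float, dtype) -> tuple[nn.Sequential, list, dict]:
    shape = _check_input_shape(input_shape, n_pools=2)
    c = max(2, int(round(48 * width_scale)))
    layers: list[tuple[str, nn.Layer]] = []
    manifest = [(1, "input", {"shape": list(shape)})]
    idx = 2
    # two stem conv blocks (conv + BN + ReLU); the first halves the
    # resolution so the residual stages stay affordable, later pooling
    # belongs to the residual stages
    c_in = 1
    for si in (1, 2):
        name = f"stem{si}"
        layers += [
            (f"{name}_conv", nn.Conv3D(c_in, c, rng, dtype=dtype)),
            (f"{name}_bn", nn.BatchNorm3D(c, dtype=dtype)),
            (f"{name}_relu", nn.ReLU()),
        ]
        if si == 1:
            layers.append((f"{name}_pool", nn.MaxPool3D()))
        manifest.append((idx, "conv_block", {"name": name, "filters": c}))
        idx += 1
        c_in = c
    spatial = min(shape) // 2
    for ri in range(1, 6):
        units = []
        for ui in range(1, 4):
            body = nn.Sequential([
                ("conv1", nn.Conv3D(c, c, rng, dtype=dtype)),
                ("bn1", nn.BatchNorm3D(c, dtype=dtype)),
                ("relu1", nn.ReLU()),
                ("conv2", nn.Conv3D(c, c, rng, dtype=dtype)),
                ("bn2", nn.BatchNorm3D(c, dtype=dtype)),
                ("relu2", nn.ReLU()),
            ])
            units.append((f"res{ri}_unit{ui}", nn.ResidualUnit(body)))
        layers += units
        manifest.append((idx, "residual_block",
                         {"name": f"res{ri}", "units": 3, "filters": c}))
        idx += 1
        # pool only while a useful spatial extent remains: the global max
        # pool needs a grid (not a single voxel) to stay shift-tolerant
        active = spatial >= 8
        if active:
            layers.append((f"res{ri}_pool", nn.MaxPool3D()))
            spatial //= 2
        manifest.append((idx, "maxpool3d",
                         {"name": f"res{ri}_pool", "active": active}))
        idx += 1
    layers.append(("gmp", nn.GlobalMaxPool3D()))
    layers.append(("fc4", nn.Dense(c, fc_width, rng, dtype=dtype)))
    layers.append(("fc4_act", nn.ReLU()))
    manifest.append((idx, "dense", {"name": "fc4", "units": fc_width}))
    fc4_idx = idx
    idx += 1
    layers.append(("head", nn.Dense(fc_width, n_classes, rng, dtype=dtype)))
    manifest.append((idx, "dense_softmax", {"name": "head", "units": n_classes}))
    return nn.Sequential(layers), manifest, {"FC4": fc4_idx}


def build_extractor(kind: str, input_shape: Sequence[int], n_classes: int = 3,
                    fc_width: int = 1000, width_scale: float = 1.0,
                    seed: int = 0, dtype=np.float32) -> NetworkSpec:
    """Initialize an extractor network of the requested kind.

    ``width_scale`` shrinks the convolution widths uniformly (the fully
    connected tap width is untouched) so tests can run reduced volumes.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown extractor kind {kind!r}; expected one of {KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "resnet15":
        net, manifest, taps = _build_resnet(input_shape, n_classes, rng,
                                            fc_width, width_scale, dtype)
    else:
        net, manifest, taps = _build_cnn(kind, input_shape, n_classes, rng,
                                         fc_width, width_scale, dtype)
    return NetworkSpec(kind=kind, n_classes=n_classes,
                       input_shape=tuple(int(s) for s in input_shape),
                       layer_manifest=manifest, tap_points=taps,
                       network=net, fc_width=fc_width)


def _as_batch(data: Sequence[VolumeSample], dtype) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(v.voxels, dtype=dtype) for v in data])[:, None]
    labels = [v.label for v in data]
    if any(l is None for l in labels):
        raise ValueError("all volumes must carry a label for training")
    return x, np.asarray(labels, dtype=np.int64)


def _stratified_split(y: np.ndarray, fractions, rng) -> tuple[np.ndarray, ...]:
    idx_train, idx_val, idx_test = [], [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = len(idx)
        n_tr = max(1, int(round(fractions[0] * n)))
        n_val = int(round(fractions[1] * n))
        idx_train.extend(idx[:n_tr])
        idx_val.extend(idx[n_tr:n_tr + n_val])
        idx_test.extend(idx[n_tr + n_val:])
    return (np.sort(np.array(idx_train, dtype=int)),
            np.sort(np.array(idx_val, dtype=int)),
            np.sort(np.array(idx_test, dtype=int)))


def _eval_net(net: nn.Sequential, x, y, batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = net.forward(xb, train=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_extractor(spec: NetworkSpec, data: Sequence[VolumeSample],
                    cfg: TrainConfig) -> tuple[NetworkSpec, dict]:
    """Train the extractor; returns the best-validation checkpoint + history.

    Early stopping monitors validation loss with the configured patience;
    the returned network carries the weights of the best validation epoch
    (or the final weights if no validation split is available).
    """
    if len(data) == 0:
        raise ValueError("empty training data")
    dtype = next(iter(spec.network.parameter_layers()))[1].params()["w"].dtype
    x, y = _as_batch(data, dtype)
    if x.shape[2:] != spec.input_shape:
        raise ValueError(
            f"volumes of shape {x.shape[2:]} do not match spec input "
            f"shape {spec.input_shape}; preprocess first")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")

    history = {"epoch": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": []}
    if cfg.epochs == 0:
        return spec, history

    rng = np.random.default_rng(cfg.seed)
    tr, va, _ = _stratified_split(y, cfg.split, rng)
    x_tr, y_tr = x[tr], y[tr]
    x_va, y_va = x[va], y[va]
    net = spec.network
    if cfg.optimizer == "adam":
        opt = nn.Adam(net, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    else:
        opt = nn.SGD(net, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    best_val = np.inf
    best_snap = nn.snapshot_params(net)
    patience_left = cfg.early_stopping_patience
    t0 = time.time()
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        train_loss = ep_loss / len(x_tr)
        train_acc = ep_correct / len(x_tr)
        if len(x_va):
            val_loss, val_acc = _eval_net(net, x_va, y_va, cfg.batch_size)
        else:
            val_loss, val_acc = train_loss, train_acc
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(train_acc)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snap = nn.snapshot_params(net)
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    history["elapsed_s"] = time.time() - t0
    nn.restore_params(net, best_snap)
    return spec, history


def _tap_layer_name(spec: NetworkSpec, tap: str) -> str:
    mapping = {"FC1": "fc1_act", "FC2": "fc2_act", "FC4": "fc4_act"}
    if tap not in mapping or tap not in spec.tap_points:
        raise KeyError(
            f"unknown tap {tap!r} for kind {spec.kind!r}; "
            f"available: {sorted(spec.tap_points)}")
    return mapping[tap]


def extract_features(spec: NetworkSpec, data: Sequence[VolumeSample],
                     tap: str = "FC1", batch_size: int = 16) -> FeatureMatrix:
    """Forward-pass feature extraction at a named tap (no weight update).

    ``FC3`` on the CNN kinds is the element-wise maximum merge of the FC1
    and FC2 activations.
    """
    if tap == "FC3":
        fm1 = extract_features(spec, data, "FC1", batch_size)
        fm2 = extract_features(spec, data, "FC2", batch_size)
        merged = np.stack([fc_concat_max(a, b)
                           for a, b in zip(fm1.values, fm2.values)])
        prov = [(spec.kind, "FC3")] * merged.shape[1]
        return FeatureMatrix(merged, prov, fm1.sample_ids)
    layer_name = _tap_layer_name(spec, tap)
    dtype = next(iter(spec.network.parameter_layers()))[1].params()["w"].dtype
    x, _ = _as_batch_unlabeled(data, dtype)
    feats = []
    for i in range(0, len(x), batch_size):
        captured: dict[str, np.ndarray] = {}
        spec.network.forward(x[i:i + batch_size], train=False,
                             capture={layer_name}, captured=captured)
        feats.append(captured[layer_name])
    values = np.concatenate(feats, axis=0).astype(np.float64)
    prov = [(spec.kind, tap)] * values.shape[1]
    ids = [v.subject_id for v in data]
    return FeatureMatrix(values, prov, ids)


def _as_batch_unlabeled(data: Sequence[VolumeSample], dtype):
    x = np.stack([np.asarray(v.voxels, dtype=dtype) for v in data])[:, None]
    return x, None


def fc_concat_max(fv1: np.ndarray, fv2: np.ndarray) -> np.ndarray:
    """Element-wise maximum merge of two equal-length feature vectors.

    Equal elements contribute once (the shared value), so the output always
    has the same length as the inputs — merging never duplicates entries.
    """
    a = np.asarray(fv1, dtype=np.float64)
    b = np.asarray(fv2, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"feature vectors must be 1-D with equal length, got "
            f"{a.shape} and {b.shape}")
    return np.maximum(a, b)


def stack_features(*mats: FeatureMatrix) -> FeatureMatrix:
    """Column-wise stack of feature matrices with aligned samples."""
    n = mats[0].n_samples
    if any(m.n_samples != n for m in mats):
        raise ValueError("feature matrices must have equal sample counts")
    values = np.concatenate([m.values for m in mats], axis=1)
    prov = [p for m in mats for p in m.feature_provenance]
    return FeatureMatrix(values, prov, mats[0].sample_ids)
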