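"""U-Net / FCN model assembly, prediction and checkpoint I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from svimon.errors import ParameterError, ShapeError
from svimon.segnet.nn import (
    Concat,
    Conv2D,
    Dropout,
    MaxPool2,
    ReLU,
    Upsample2,
    softmax_channel,
)

__all__ = [
    "UNetSpec",
    "SegModel",
    "build_unet",
    "build_fcn",
    "predict_mask",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling levels; input sides must be divisible
    by ``2**depth``. The decoder mirrors the encoder level-for-level.
    """

    depth: int = 4
    base_filters: int = 16
    n_classes: int = 3
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.base_filters < 1:
            raise ParameterError("base_filters must be >= 1")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ParameterError("dropout_rate must be in [0, 1)")


class SegModel:
    """Encoder-decoder segmentation network.

    With ``skips=True`` each decoder level concatenates the matching encoder
    feature maps (U-Net); with ``skips=False`` the decoder sees only the
    upsampled path (the FCN-style baseline used for comparison runs).
    """

    def __init__(self, spec: UNetSpec, skips: bool = True, seed: int = 0, in_channels: int = 3):
        self.spec = spec
        self.skips = skips
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        d, base = spec.depth, spec.base_filters
        ch = [base * 2**lvl for lvl in range(d + 1)]

        self.enc: list[list] = []
        self.pools: list[MaxPool2] = []
        cin = in_channels
        for lvl in range(d):
            self.enc.append(
                [Conv2D(cin, ch[lvl], 3, rng), ReLU(), Conv2D(ch[lvl], ch[lvl], 3, rng), ReLU()]
            )
            self.pools.append(MaxPool2())
            cin = ch[lvl]

        self.bottleneck = [
            Conv2D(ch[d - 1], ch[d], 3, rng),
            ReLU(),
            Conv2D(ch[d], ch[d], 3, rng),
            ReLU(),
            Dropout(spec.dropout_rate, rng),
        ]

        # decoder level lvl consumes features from level lvl+1 (or bottleneck)
        self.dec: list[dict] = []
        for lvl in range(d):
            above = ch[lvl + 1]
            merged = 2 * ch[lvl] if skips else ch[lvl]
            self.dec.append(
                {
                    "up": Upsample2(),
                    "reduce": Conv2D(above, ch[lvl], 3, rng),
                    "concat": Concat() if skips else None,
                    "convs": [Conv2D(merged, ch[lvl], 3, rng), ReLU()],
                }
            )
        self.head = Conv2D(ch[0], spec.n_classes, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _conv_layers(self) -> list[Conv2D]:
        convs: list[Conv2D] = []
        for block in self.enc:
            convs.extend(l for l in block if isinstance(l, Conv2D))
        convs.extend(l for l in self.bottleneck if isinstance(l, Conv2D))
        for blk in self.dec:
            convs.append(blk["reduce"])
            convs.extend(l for l in blk["convs"] if isinstance(l, Conv2D))
        convs.append(self.head)
        return convs

    def params(self):
        out = []
        for conv in self._conv_layers():
            out.extend(conv.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pairs = self.params()
        if len(weights) != len(pairs):
            raise ParameterError("weight count mismatch")
        for (p, _), w in zip(pairs, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        div = 2**self.spec.depth
        if h % div or w % div:
            raise ShapeError(f"input sides ({h}, {w}) must be divisible by {div}")
        if x.shape[1] != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} channels, got {x.shape[1]}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, H, W) float input -> (N, n_classes, H, W) logits."""
        self._check_input(x)
        skips = []
        for lvl in range(self.spec.depth):
            for layer in self.enc[lvl]:
                x = layer.forward(x, train)
            skips.append(x)
            x = self.pools[lvl].forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        for lvl in reversed(range(self.spec.depth)):
            blk = self.dec[lvl]
            x = blk["up"].forward(x, train)
            x = blk["reduce"].forward(x, train)
            if self.skips:
                x = blk["concat"].forward(skips[lvl], x)
            for layer in blk["convs"]:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * self.spec.depth
        for lvl in range(self.spec.depth):
            blk = self.dec[lvl]
            for layer in reversed(blk["convs"]):
                d = layer.backward(d)
            if self.skips:
                dskips[lvl], d = blk["concat"].backward(d)
            d = blk["reduce"].backward(d)
            d = blk["up"].backward(d)
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        for lvl in reversed(range(self.spec.depth)):
            d = self.pools[lvl].backward(d)
            if dskips[lvl] is not None:
                d = d + dskips[lvl]
            for layer in reversed(self.enc[lvl]):
                d = layer.backward(d)

    def zero_grad(self) -> None:
        for conv in self._conv_layers():
            conv.dw[...] = 0.0
            conv.db[...] = 0.0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax_channel(self.forward(x, train=False))


def build_unet(spec: UNetSpec = UNetSpec(), seed: int = 0) -> SegModel:
    """Symmetric encoder-decoder with skip connections."""
    return SegModel(spec, skips=True, seed=seed)


def build_fcn(spec: UNetSpec = UNetSpec(), seed: int = 0) -> SegModel:
    """Skip-free encoder-decoder baseline with matching capacity layout."""
    return SegModel(spec, skips=False, seed=seed)


def image_to_input(image: np.ndarray) -> np.ndarray:
    """HxWx3 uint8 (or float) image -> (1, 3, H, W) float32 in [0, 1]."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError(f"expected an HxWx3 image, got {img.shape}")
    x = img.astype(np.float32)
    if img.dtype == np.uint8:
        x /= 255.0
    return x.transpose(2, 0, 1)[None]


def predict_mask(model: SegModel, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment one image.

    Returns ``(class_ids, probs)`` where ``class_ids`` is (H, W) uint8 (ties
    broken toward the lowest class id, as argmax returns the first maximum)
    and ``probs`` is (H, W, n_classes).
    """
    probs = model.predict_proba(image_to_input(image))[0]
    mask = probs.argmax(axis=0).astype(np.uint8)
    return mask, probs.transpose(1, 2, 0)


def save_model(model: SegModel, path: str | Path) -> Path:
    """Single-file checkpoint (NumPy .npz with spec metadata)."""
    path = Path(path)
    meta = dict(
        depth=model.spec.depth,
        base_filters=model.spec.base_filters,
        n_classes=model.spec.n_classes,
        dropout_rate=model.spec.dropout_rate,
        skips=int(model.skips),
        in_channels=model.in_channels,
    )
    arrays = {f"param_{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, meta=np.array(list(meta.items()), dtype=object), **arrays)
    return path


def load_model(path: str | Path) -> SegModel:
    data = np.load(path, allow_pickle=True)
    meta = dict(data["meta"].tolist())
    spec = UNetSpec(
        depth=int(meta["depth"]),
        base_filters=int(meta["base_filters"]),
        n_classes=int(meta["n_classes"]),
        dropout_rate=float(meta["dropout_rate"]),
    )
    model = SegModel(spec, skips=bool(int(meta["skips"])), in_channels=int(meta["in_channels"]))
    n_params = len(model.params())
    model.set_weights([data[f"param_{i}"] for i in range(n_params)])
    return model
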