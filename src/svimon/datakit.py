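"""Dataset plumbing: colour-mask codec, resizing, splitting, augmentation.

Masks travel on disk as colour PNGs (vegetation = (107, 142, 35)) and in
memory as small-integer class-id rasters; this module converts between the
two, resizes image/mask pairs without inventing class ids, partitions a
dataset 80/15/5, and applies paired geometric / image-only photometric
augmentations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from svimon.errors import MaskCodecError, ParameterError
from svimon.scenegen import ScenePair

__all__ = [
    "ColorMap",
    "DEFAULT_COLORMAP",
    "SplitSpec",
    "AugmentationOp",
    "GEOMETRIC_KINDS",
    "PHOTOMETRIC_KINDS",
    "decode_color_to_mask",
    "encode_mask_to_color",
    "resize_pair",
    "split_dataset",
    "apply_augmentation",
    "augment_dataset",
]


@dataclass(frozen=True)
class ColorMap:
    """Invertible mapping from class id to RGB colour."""

    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: {
            0: (0, 0, 0),  # other
            1: (107, 142, 35),  # vegetation
            2: (70, 130, 180),  # sky
        }
    )

    def __post_init__(self):
        triples = list(self.colors.values())
        if len(set(triples)) != len(triples):
            raise ParameterError("colormap colours must be distinct")

    @property
    def inverse(self) -> dict[tuple[int, int, int], int]:
        return {rgb: cid for cid, rgb in self.colors.items()}

    def as_array(self) -> tuple[np.ndarray, np.ndarray]:
        ids = np.array(sorted(self.colors), dtype=np.int64)
        rgb = np.array([self.colors[i] for i in ids], dtype=np.int64)
        return ids, rgb


DEFAULT_COLORMAP = ColorMap()


def encode_mask_to_color(mask: np.ndarray, colormap: ColorMap = DEFAULT_COLORMAP) -> np.ndarray:
    """Class-id raster -> RGB uint8 image by per-pixel lookup."""
    mask = np.asarray(mask)
    ids, rgb = colormap.as_array()
    unknown = ~np.isin(mask, ids)
    if unknown.any():
        bad = int(mask[unknown].ravel()[0])
        raise MaskCodecError(f"class id {bad} not in colormap")
    lut = np.zeros((int(ids.max()) + 1, 3), dtype=np.uint8)
    lut[ids] = rgb
    return lut[mask]


def decode_color_to_mask(
    rgb_image: np.ndarray,
    colormap: ColorMap = DEFAULT_COLORMAP,
    strict: bool = True,
) -> np.ndarray:
    """RGB mask image -> class-id raster.

    Exact-colour lookup. In strict mode an unknown colour raises
    :class:`MaskCodecError` naming the offending RGB triple; in lenient mode
    unknown pixels take the nearest colormap colour by Euclidean RGB distance.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise MaskCodecError(f"expected a 3-channel image, got shape {img.shape}")
    img = img[..., :3].astype(np.int64)
    ids, rgb = colormap.as_array()
    # distance to every colormap colour; exact hits have distance 0
    d2 = ((img[..., None, :] - rgb[None, None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=-1)
    exact = d2.min(axis=-1) == 0
    if strict and not exact.all():
        bad = img[~exact].reshape(-1, 3)[0]
        raise MaskCodecError(f"unknown colour {tuple(int(v) for v in bad)} in strict decode")
    return ids[nearest].astype(np.uint8)


def resize_pair(pair: ScenePair, side: int) -> ScenePair:
    """Resize to ``side``x``side``: image bilinear, mask nearest-neighbour."""
    if side < 16:
        raise ParameterError("side must be >= 16")
    if pair.shape == (side, side):
        return replace(pair)
    image = _sk_resize(
        pair.image, (side, side), order=1, anti_aliasing=True, preserve_range=True
    )
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    mask = _sk_resize(
        pair.mask, (side, side), order=0, anti_aliasing=False, preserve_range=True
    ).astype(pair.mask.dtype)
    return ScenePair(image=image, mask=mask, site_id=pair.site_id, timestamp=pair.timestamp)


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.80
    val_frac: float = 0.15
    test_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        total = self.train_frac + self.val_frac + self.test_frac
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ParameterError(f"split fractions must sum to 1, got {total}")
        if min(self.train_frac, self.val_frac, self.test_frac) < 0:
            raise ParameterError("split fractions must be non-negative")


def split_dataset(
    n_items: int, spec: SplitSpec = SplitSpec()
) -> tuple[list[int], list[int], list[int]]:
    """Shuffle indices and partition train/val/test.

    Validation and test sizes are ``floor(frac * n)``; the remainder goes to
    training, so 3500 items at 80/15/5 yield (2800, 525, 175).
    """
    if n_items < 3:
        raise ParameterError("need at least 3 items to split")
    n_val = int(math.floor(spec.val_frac * n_items))
    n_test = int(math.floor(spec.test_frac * n_items))
    n_train = n_items - n_val - n_test
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_items)
    train = sorted(int(i) for i in order[:n_train])
    val = sorted(int(i) for i in order[n_train : n_train + n_val])
    test = sorted(int(i) for i in order[n_train + n_val :])
    return train, val, test


GEOMETRIC_KINDS = ("hflip", "vflip", "rot90", "rot180", "zoom", "translate")
PHOTOMETRIC_KINDS = ("gaussian_noise", "blur")


@dataclass(frozen=True)
class AugmentationOp:
    """One augmentation: geometric ops transform image and mask identically;
    photometric ops (noise, blur) touch the image only."""

    kind: str
    zoom_factor: float = 0.9  # central crop factor, (0, 1]
    translate_px: tuple[int, int] = (4, 4)  # (dx, dy), positive = right/down
    noise_sd: float = 10.0  # 8-bit intensity units
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in GEOMETRIC_KINDS + PHOTOMETRIC_KINDS:
            raise ParameterError(f"unsupported augmentation kind '{self.kind}'")
        if not (0.0 < self.zoom_factor <= 1.0):
            raise ParameterError("zoom_factor must be in (0, 1]")
        if self.noise_sd < 0 or self.blur_sigma <= 0:
            raise ParameterError("invalid photometric magnitude")


def _translate(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift with zero fill (class 'other' / black at exposed borders)."""
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = arr[src_y, src_x]
    return out


def apply_augmentation(pair: ScenePair, op: AugmentationOp) -> ScenePair:
    """Apply one op to a pair; deterministic given ``op.seed``."""
    img, mask = pair.image, pair.mask
    if op.kind == "hflip":
        img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    elif op.kind == "vflip":
        img, mask = img[::-1].copy(), mask[::-1].copy()
    elif op.kind == "rot90":
        img, mask = np.rot90(img).copy(), np.rot90(mask).copy()
    elif op.kind == "rot180":
        img, mask = np.rot90(img, 2).copy(), np.rot90(mask, 2).copy()
    elif op.kind == "zoom":
        h, w = mask.shape
        ch = max(1, int(round(op.zoom_factor * h)))
        cw = max(1, int(round(op.zoom_factor * w)))
        y0, x0 = (h - ch) // 2, (w - cw) // 2
        img_c = img[y0 : y0 + ch, x0 : x0 + cw]
        mask_c = mask[y0 : y0 + ch, x0 : x0 + cw]
        img = np.clip(
            np.rint(_sk_resize(img_c, (h, w), order=1, preserve_range=True, anti_aliasing=False)),
            0,
            255,
        ).astype(np.uint8)
        mask = _sk_resize(mask_c, (h, w), order=0, preserve_range=True, anti_aliasing=False).astype(
            mask.dtype
        )
    elif op.kind == "translate":
        dx, dy = op.translate_px
        img = _translate(img, dx, dy)
        mask = _translate(mask, dx, dy)
    elif op.kind == "gaussian_noise":
        rng = np.random.default_rng(op.seed)
        noisy = img.astype(float) + rng.normal(0.0, op.noise_sd, size=img.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        mask = mask.copy()
    elif op.kind == "blur":
        blurred = gaussian_filter(img.astype(float), sigma=(op.blur_sigma, op.blur_sigma, 0))
        img = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
        mask = mask.copy()
    else:  # pragma: no cover - guarded by AugmentationOp validation
        raise ParameterError(f"unsupported augmentation kind '{op.kind}'")
    return ScenePair(image=img, mask=mask, site_id=pair.site_id, timestamp=pair.timestamp)


def augment_dataset(
    pairs: list[ScenePair],
    multiplier: int,
    op_pool: list[AugmentationOp] | None = None,
    seed: int = 0,
) -> list[ScenePair]:
    """Originals plus ``multiplier - 1`` augmented copies each.

    Ops are sampled from ``op_pool`` with fresh per-copy seeds derived from
    ``seed``, so the expansion is reproducible.
    """
    if multiplier < 1:
        raise ParameterError("multiplier must be >= 1")
    if multiplier > 1 and not op_pool:
        raise ParameterError("op_pool must be non-empty when multiplier > 1")
    out = list(pairs)
    if multiplier == 1:
        return out
    rng = np.random.default_rng(seed)
    for pair in pairs:
        for _ in range(multiplier - 1):
            op = op_pool[int(rng.integers(len(op_pool)))]
            op = replace(op, seed=int(rng.integers(0, 2**31 - 1)))
            out.append(apply_augmentation(pair, op))
    return out
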