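"""Synthetic repeat-photography scenes with exact ground-truth masks.

Scenes are composed of a sky band, a terrain floor and blobby vegetation
regions. The vegetation share of the mask is controlled exactly: a smooth
random field (Gaussian bumps plus filtered noise) is thresholded at the
quantile that yields the requested pixel count, so the realised fraction is
within one pixel of the request. Seasonal dynamics and viewpoint jitter give
every downstream stage (registration, segmentation, index series) a testable
ground truth.

Class ids: 0 = other (terrain/ground), 1 = vegetation, 2 = sky.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from svimon.errors import ParameterError
from svimon.registration import AffineTransform, warp_image

__all__ = [
    "CLASS_OTHER",
    "CLASS_VEGETATION",
    "CLASS_SKY",
    "SceneParams",
    "SeasonalModel",
    "ScenePair",
    "generate_scene",
    "generate_site_album",
    "perturb_viewpoint",
]

CLASS_OTHER = 0
CLASS_VEGETATION = 1
CLASS_SKY = 2

# mean RGB per class; jittered per scene and per pixel
_BASE_COLORS = {
    CLASS_OTHER: np.array([139.0, 115.0, 85.0]),
    CLASS_VEGETATION: np.array([70.0, 120.0, 45.0]),
    CLASS_SKY: np.array([150.0, 200.0, 235.0]),
}


@dataclass(frozen=True)
class SceneParams:
    """Geometry and photometry of one synthetic scene."""

    height: int = 64
    width: int = 64
    veg_fraction: float = 0.3
    sky_fraction: float = 0.25
    blob_count: int = 6
    texture_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ParameterError("height and width must be >= 16")
        if not (0.0 <= self.veg_fraction <= 1.0):
            raise ParameterError(f"veg_fraction must be in [0,1], got {self.veg_fraction}")
        if not (0.0 <= self.sky_fraction < 1.0):
            raise ParameterError(f"sky_fraction must be in [0,1), got {self.sky_fraction}")
        if self.veg_fraction + self.sky_fraction > 1.0:
            raise ParameterError("veg_fraction + sky_fraction must be <= 1")
        if self.blob_count < 1:
            raise ParameterError("blob_count must be >= 1")
        if self.texture_noise_sd < 0:
            raise ParameterError("texture_noise_sd must be >= 0")


@dataclass(frozen=True)
class SeasonalModel:
    """Sinusoidal quarterly vegetation-fraction dynamics with linear trend.

    Fraction of (year t, quarter q), before clipping to [0, 1]:
    ``base + amplitude * sin(2*pi*(q - phase_quarter)/4)
    + annual_trend * (t - t0) + Normal(0, noise_sd)``.
    """

    base_fraction: float = 0.3
    amplitude: float = 0.1
    phase_quarter: int = 1
    annual_trend: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.base_fraction <= 1.0):
            raise ParameterError("base_fraction must be in [0,1]")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ParameterError("amplitude and noise_sd must be >= 0")
        if self.phase_quarter not in (1, 2, 3, 4):
            raise ParameterError("phase_quarter must be in 1..4")

    def fraction(self, year: int, quarter: int, t0: int, noise: float = 0.0) -> float:
        """Noise-free seasonal mean plus an externally drawn noise term."""
        val = (
            self.base_fraction
            + self.amplitude * np.sin(2.0 * np.pi * (quarter - self.phase_quarter) / 4.0)
            + self.annual_trend * (year - t0)
            + noise
        )
        return float(np.clip(val, 0.0, 1.0))


@dataclass
class ScenePair:
    """An RGB image and its aligned per-pixel class-id mask."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, ids in {0, 1, 2}
    site_id: str = ""
    timestamp: tuple[int, int] | None = None  # (year, quarter 1..4)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ParameterError(f"image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ParameterError("image and mask dimensions differ")
        if not np.isin(self.mask, [CLASS_OTHER, CLASS_VEGETATION, CLASS_SKY]).all():
            raise ParameterError("mask contains undefined class ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def veg_share(self) -> float:
        return float(np.mean(self.mask == CLASS_VEGETATION))


def _vegetation_field(
    rng: np.random.Generator, h: int, w: int, sky_rows: int, blobs: int
) -> np.ndarray:
    """Smooth scalar field whose top-k pixels become vegetation."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    field = np.zeros((h, w))
    lo = min(sky_rows, h - 1)
    for _ in range(blobs):
        cy = rng.uniform(max(lo - 0.05 * h, 0), h - 1)
        cx = rng.uniform(0, w - 1)
        sy = rng.uniform(0.06, 0.20) * h
        sx = rng.uniform(0.06, 0.20) * w
        amp = rng.uniform(0.6, 1.0)
        field += amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    field += 0.25 * gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 24.0)
    field[:sky_rows, :] = -np.inf  # vegetation never replaces sky
    return field


def generate_scene(params: SceneParams) -> ScenePair:
    """Render one scene; deterministic in ``params`` (including seed).

    The vegetation pixel count is exactly ``round(veg_fraction * H * W)``
    (clipped to the non-sky area), so the realised share is within one pixel
    of the request.
    """
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)

    sky_rows = int(round(params.sky_fraction * h))
    mask = np.full((h, w), CLASS_OTHER, dtype=np.uint8)
    mask[:sky_rows, :] = CLASS_SKY

    k = int(round(params.veg_fraction * h * w))
    k = min(k, (h - sky_rows) * w)
    if k > 0:
        field = _vegetation_field(rng, h, w, sky_rows, params.blob_count)
        flat = field.ravel()
        top = np.argpartition(flat, -k)[-k:]
        veg = np.zeros(h * w, dtype=bool)
        veg[top] = True
        mask[veg.reshape(h, w)] = CLASS_VEGETATION
    else:
        # keep the rng stream aligned between k=0 and k>0 scenes
        _vegetation_field(rng, h, w, sky_rows, params.blob_count)

    img = np.zeros((h, w, 3), dtype=float)
    for cls, base in _BASE_COLORS.items():
        scene_jitter = rng.normal(0.0, 12.0, size=3)
        img[mask == cls] = base + scene_jitter
    # vertical illumination gradient plus texture: a smooth luminance field
    # (coherent under warping, so repeat views stay matchable) and fine noise
    grad = np.linspace(12.0, -12.0, h)[:, None, None]
    img = img + grad
    if params.texture_noise_sd > 0:
        smooth = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
        img = img + (3.0 * params.texture_noise_sd) * smooth[:, :, None]
        img = img + rng.normal(0.0, params.texture_noise_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ScenePair(image=image, mask=mask)


def generate_site_album(
    site_id: str,
    seasonal: SeasonalModel,
    years: range,
    per_quarter: int = 1,
    scene: SceneParams = SceneParams(),
) -> list[ScenePair]:
    """Quarterly scenes for one site across ``years``.

    One :class:`ScenePair` per (year, quarter, replicate), ordered
    chronologically. The true vegetation fraction follows the seasonal model;
    with ``noise_sd=0`` it matches the closed-form sinusoid exactly.
    """
    years = list(years)
    if not years:
        raise ParameterError("years range is empty")
    if per_quarter < 1:
        raise ParameterError("per_quarter must be >= 1")
    t0 = min(years)
    master = np.random.default_rng(scene.seed)
    album: list[ScenePair] = []
    for year in years:
        for quarter in (1, 2, 3, 4):
            noise = (
                master.normal(0.0, seasonal.noise_sd) if seasonal.noise_sd > 0 else 0.0
            )
            frac = seasonal.fraction(year, quarter, t0, noise)
            for _ in range(per_quarter):
                child_seed = int(master.integers(0, 2**31 - 1))
                pair = generate_scene(replace(scene, veg_fraction=frac, seed=child_seed))
                pair.site_id = site_id
                pair.timestamp = (year, quarter)
                album.append(pair)
    return album


def perturb_viewpoint(
    pair: ScenePair,
    max_rotation_deg: float = 5.0,
    max_translation_frac: float = 0.05,
    max_scale_delta: float = 0.05,
    seed: int = 0,
    rotation_deg: float | None = None,
    translation_px: tuple[float, float] | None = None,
    scale: float | None = None,
) -> tuple[ScenePair, AffineTransform]:
    """Simulate a camera vantage change; returns the jittered pair + true map.

    The returned :class:`AffineTransform` is the forward jitter, mapping
    original pixel coordinates to jittered coordinates (its ``.inverse`` is
    the ground truth a registration step should recover). Jitter magnitudes
    are drawn uniformly within the given bounds unless pinned explicitly via
    ``rotation_deg`` / ``translation_px`` / ``scale``. Image and mask receive
    the same geometric transform (bilinear vs nearest resampling).
    """
    if max_rotation_deg < 0 or max_translation_frac < 0 or max_scale_delta < 0:
        raise ParameterError("jitter bounds must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = pair.shape
    rot = rng.uniform(-max_rotation_deg, max_rotation_deg)
    tx = rng.uniform(-max_translation_frac, max_translation_frac) * w
    ty = rng.uniform(-max_translation_frac, max_translation_frac) * h
    sc = 1.0 + rng.uniform(-max_scale_delta, max_scale_delta)
    if rotation_deg is not None:
        rot = rotation_deg
    if translation_px is not None:
        tx, ty = translation_px
    if scale is not None:
        sc = scale
    tf = AffineTransform.from_params(
        rotation_deg=rot,
        translation=(tx, ty),
        scale=sc,
        center=((w - 1) / 2.0, (h - 1) / 2.0),
    )
    image = warp_image(pair.image, tf, output_shape=(h, w), order=1)
    mask = warp_image(pair.mask, tf, output_shape=(h, w), order=0)
    out = ScenePair(image=image, mask=mask, site_id=pair.site_id, timestamp=pair.timestamp)
    return out, tf
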