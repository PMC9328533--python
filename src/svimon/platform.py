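"""End-to-end orchestration: generate → register → prepare → train → evaluate → series.

A single :class:`RunConfig` (loadable from a YAML file) carries every nested
stage configuration plus one global seed from which each module seed is
derived deterministically, so a rerun with the same config reproduces the
same artifacts. Every file written is recorded, with its SHA-256 checksum,
in a run manifest JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from svimon import imageio
from svimon.datakit import (
    AugmentationOp,
    SplitSpec,
    augment_dataset,
    resize_pair,
    split_dataset,
)
from svimon.errors import ParameterError, RegistrationError, StageError
from svimon.evalkit import evaluate_testset
from svimon.registration import register_pair
from svimon.scenegen import ScenePair, SceneParams, SeasonalModel, generate_site_album, perturb_viewpoint
from svimon.segnet import TrainConfig, UNetSpec, build_unet, save_model, train_model
from svimon.sviseries import export_series, plot_series, quarterly_series, svi_from_pairs

__all__ = ["RunConfig", "run_end_to_end", "derive_seed"]

log = logging.getLogger("svimon")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunConfig:
    out_dir: str = "runs/svi"
    data_dir: str | None = None  # existing manifest dir; None -> synthetic
    n_sites: int = 2
    years: tuple[int, int] = (2015, 2020)  # inclusive
    per_quarter: int = 1
    image_side: int = 64  # resize target (training resolution)
    jitter_rotation_deg: float = 4.0
    jitter_translation_frac: float = 0.04
    jitter_scale_delta: float = 0.04
    register: bool = True
    ransac_threshold_px: float = 2.0
    scene: SceneParams = field(default_factory=SceneParams)
    seasonal: SeasonalModel = field(default_factory=SeasonalModel)
    split: SplitSpec = field(default_factory=SplitSpec)
    unet: UNetSpec = field(default_factory=lambda: UNetSpec(depth=3, base_filters=16))
    train: TrainConfig = field(default_factory=TrainConfig)
    augment_multiplier: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.years[0] > self.years[1]:
            raise ParameterError("years must be (first, last) with first <= last")
        if self.n_sites < 1 or self.per_quarter < 1:
            raise ParameterError("n_sites and per_quarter must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        nested = {
            "scene": SceneParams,
            "seasonal": SeasonalModel,
            "split": SplitSpec,
            "unet": UNetSpec,
            "train": TrainConfig,
        }
        try:
            for key, typ in nested.items():
                if key in kwargs and isinstance(kwargs[key], dict):
                    kwargs[key] = typ(**kwargs[key])
            if "years" in kwargs:
                kwargs["years"] = tuple(kwargs["years"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ParameterError(f"bad config: {exc}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        return d


class _Manifest:
    """Collects every artifact path + checksum written during a run."""

    def __init__(self, root: Path):
        self.root = root
        self.files: dict[str, str] = {}

    def add(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.relative_to(self.root))] = digest

    def write(self, extra: dict) -> Path:
        out = self.root / "run_manifest.json"
        payload = {"files": dict(sorted(self.files.items())), **extra}
        out.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return result

        return wrapper

    return deco


@_stage("generate")
def _generate(cfg: RunConfig, manifest: _Manifest, root: Path) -> list[ScenePair]:
    seed = derive_seed(cfg.seed, "generate")
    years = range(cfg.years[0], cfg.years[1] + 1)
    pairs: list[ScenePair] = []
    for s in range(cfg.n_sites):
        site = f"site{s + 1:03d}"
        scene = replace(cfg.scene, seed=seed + s)
        album = generate_site_album(site, cfg.seasonal, years, cfg.per_quarter, scene)
        # jitter every non-first visit to exercise registration
        for i, pair in enumerate(album):
            if i > 0:
                jit, _ = perturb_viewpoint(
                    pair,
                    cfg.jitter_rotation_deg,
                    cfg.jitter_translation_frac,
                    cfg.jitter_scale_delta,
                    seed=derive_seed(cfg.seed, f"jitter:{site}:{i}"),
                )
                album[i] = jit
        pairs.extend(album)
    rows = []
    for i, pair in enumerate(pairs):
        year, quarter = pair.timestamp
        stem = root / "album" / pair.site_id / f"{year}Q{quarter}_{i:04d}"
        img_p, mask_p = imageio.write_pair(pair, f"{stem}.png", f"{stem}_mask.png")
        manifest.add(img_p)
        manifest.add(mask_p)
        rows.append(
            {
                "site_id": pair.site_id,
                "image_path": str(img_p.relative_to(root)),
                "mask_path": str(mask_p.relative_to(root)),
                "year": year,
                "quarter": quarter,
            }
        )
    manifest.add(imageio.write_manifest(rows, root / "album_manifest.csv"))
    return pairs


@_stage("register")
def _register(cfg: RunConfig, pairs: list[ScenePair]) -> list[ScenePair]:
    """Align every image to the chronologically first image of its site."""
    by_site: dict[str, list[int]] = {}
    for i, p in enumerate(pairs):
        by_site.setdefault(p.site_id, []).append(i)
    seed = derive_seed(cfg.seed, "register")
    out = list(pairs)
    n_fail = 0
    for site, idxs in by_site.items():
        ref = pairs[idxs[0]]
        for i in idxs[1:]:
            p = pairs[i]
            try:
                registered, tf, _ = register_pair(
                    ref.image, p.image, cfg.ransac_threshold_px, seed=seed
                )
                from svimon.registration import warp_image

                mask = warp_image(p.mask, tf, output_shape=ref.shape, order=0)
                out[i] = ScenePair(
                    image=registered, mask=mask, site_id=p.site_id, timestamp=p.timestamp
                )
            except RegistrationError as exc:
                n_fail += 1
                log.warning("registration failed for %s[%d] (%s); using unregistered image", site, i, exc)
    if n_fail:
        log.info("registration fell back to identity on %d image(s)", n_fail)
    return out


@_stage("prepare")
def _prepare(cfg: RunConfig, pairs: list[ScenePair]):
    pairs = [resize_pair(p, cfg.image_side) for p in pairs]
    split_seed = derive_seed(cfg.seed, "split")
    tr, va, te = split_dataset(len(pairs), replace(cfg.split, seed=split_seed))
    train = [pairs[i] for i in tr]
    val = [pairs[i] for i in va]
    test = [pairs[i] for i in te]
    if cfg.augment_multiplier > 1:
        pool = [
            AugmentationOp("hflip"),
            AugmentationOp("vflip"),
            AugmentationOp("rot180"),
            AugmentationOp("zoom"),
            AugmentationOp("translate"),
            AugmentationOp("gaussian_noise"),
            AugmentationOp("blur"),
        ]
        # augmentation is applied to the training partition only (no leakage)
        train = augment_dataset(
            train, cfg.augment_multiplier, pool, seed=derive_seed(cfg.seed, "augment")
        )
    return train, val, test, (tr, va, te)


@_stage("train")
def _train(cfg: RunConfig, train_pairs, val_pairs, root: Path, manifest: _Manifest):
    model = build_unet(cfg.unet, seed=derive_seed(cfg.seed, "init"))
    tcfg = replace(cfg.train, seed=derive_seed(cfg.seed, "train"))
    model, history = train_model(model, train_pairs, val_pairs, tcfg)
    ckpt = save_model(model, root / "model.npz")
    manifest.add(ckpt)
    import pandas as pd

    curves = pd.DataFrame(history.to_rows())
    curves_path = root / "training_curves.csv"
    curves.to_csv(curves_path, index=False)
    manifest.add(curves_path)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].plot(curves["epoch"], curves["train_loss"], label="train")
        axes[0].plot(curves["epoch"], curves["val_loss"], label="validation")
        axes[0].set_xlabel("epoch"), axes[0].set_ylabel("loss"), axes[0].legend()
        axes[1].plot(curves["epoch"], curves["train_acc"], label="train")
        axes[1].plot(curves["epoch"], curves["val_acc"], label="validation")
        axes[1].set_xlabel("epoch"), axes[1].set_ylabel("accuracy"), axes[1].legend()
        fig.tight_layout()
        plot_path = root / "training_curves.png"
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
        manifest.add(plot_path)
    except Exception as exc:  # plotting is best-effort
        log.warning("could not render training curves: %s", exc)
    return model, history


@_stage("evaluate")
def _evaluate(model, test_pairs, root: Path, manifest: _Manifest):
    report = evaluate_testset(model, test_pairs, positive_class=1)
    path = root / "metrics.json"
    path.write_text(json.dumps(report.to_dict(), indent=2))
    manifest.add(path)
    return report


@_stage("series")
def _series(model, pairs: list[ScenePair], root: Path, manifest: _Manifest):
    by_site: dict[str, list[ScenePair]] = {}
    for p in pairs:
        by_site.setdefault(p.site_id, []).append(p)
    series_paths = []
    for site, site_pairs in sorted(by_site.items()):
        records = svi_from_pairs(model, site_pairs)
        series = quarterly_series(records)
        csv_path = export_series(series, root / f"series_{site}.csv")
        manifest.add(csv_path)
        png_path = plot_series(series, root / f"series_{site}.png")
        manifest.add(png_path)
        series_paths.append(csv_path)
    return series_paths


def run_end_to_end(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run-manifest path.

    Stage order: generate (or load) the album, register each image to its
    site's first image, resize + split (+ augment train only), train the
    U-Net, evaluate on the held-out test partition, and emit per-site
    quarterly SVI series. Any stage failure raises :class:`StageError` with
    the stage name; artifacts written before the failure are retained.
    """
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(root / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = _Manifest(root)
    try:
        log.info("run config: %s", json.dumps(config.to_dict(), default=str))
        for stage in ("generate", "register", "split", "augment", "init", "train"):
            log.info("derived seed %s=%d", stage, derive_seed(config.seed, stage))
        if config.data_dir is not None:
            df = imageio.read_manifest(Path(config.data_dir) / "album_manifest.csv")
            pairs = imageio.load_pairs(df, root=config.data_dir)
        else:
            pairs = _generate(config, manifest, root)
        if config.register:
            pairs = _register(config, pairs)
        # resizing happens after registration, inside the prepare stage
        train_pairs, val_pairs, test_pairs, _ = _prepare(config, pairs)
        model, _history = _train(config, train_pairs, val_pairs, root, manifest)
        _evaluate(model, test_pairs, root, manifest)
        _series(model, [resize_pair(p, config.image_side) for p in pairs], root, manifest)
        path = manifest.write({"config": config.to_dict(), "seed": config.seed})
        log.info("run complete: %s", path)
        return path
    finally:
        log.removeHandler(handler)
        handler.close()
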