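"""PNG and manifest I/O for scene pairs.

Images are plain RGB PNGs; masks are stored as colour PNGs using the
package colormap (vegetation = (107, 142, 35)). Album manifests are CSV
files with columns ``site_id,image_path,mask_path,year,quarter[,split]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from svimon.datakit import DEFAULT_COLORMAP, ColorMap, decode_color_to_mask, encode_mask_to_color
from svimon.errors import ParameterError
from svimon.scenegen import ScenePair

__all__ = [
    "read_image",
    "write_image",
    "write_pair",
    "read_pair",
    "write_manifest",
    "read_manifest",
]

MANIFEST_COLUMNS = ["site_id", "image_path", "mask_path", "year", "quarter"]


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image)).save(path)
    return path


def write_pair(
    pair: ScenePair,
    image_path: str | Path,
    mask_path: str | Path,
    colormap: ColorMap = DEFAULT_COLORMAP,
) -> tuple[Path, Path]:
    write_image(pair.image, image_path)
    write_image(encode_mask_to_color(pair.mask, colormap), mask_path)
    return Path(image_path), Path(mask_path)


def read_pair(
    image_path: str | Path,
    mask_path: str | Path,
    site_id: str = "",
    timestamp: tuple[int, int] | None = None,
    colormap: ColorMap = DEFAULT_COLORMAP,
) -> ScenePair:
    image = read_image(image_path)
    mask = decode_color_to_mask(read_image(mask_path), colormap, strict=True)
    return ScenePair(image=image, mask=mask, site_id=site_id, timestamp=timestamp)


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    df = pd.DataFrame(rows)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"manifest rows missing columns {missing}")
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"manifest {path} missing columns {missing}")
    return df


def load_pairs(manifest: pd.DataFrame, root: str | Path = ".") -> list[ScenePair]:
    """Materialise every manifest row as a ScenePair (paths relative to root)."""
    root = Path(root)
    pairs = []
    for row in manifest.itertuples():
        pairs.append(
            read_pair(
                root / row.image_path,
                root / row.mask_path,
                site_id=str(row.site_id),
                timestamp=(int(row.year), int(row.quarter)),
            )
        )
    return pairs
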