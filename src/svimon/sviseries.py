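"""Semantic Vegetation Index (SVI) per image and quarterly per-site series.

The index of one image is the percentage of its pixels classified as
vegetation: ``100 * sp_a / area_t`` with ``sp_a`` the vegetation pixel count
and ``area_t`` the total pixel count. Site series average the per-image
indices within each calendar quarter; quarters without any image appear as
explicit gaps (no interpolation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from svimon.errors import ParameterError, SeriesParseError
from svimon.scenegen import CLASS_VEGETATION

__all__ = [
    "SVIRecord",
    "SeriesEntry",
    "SiteSeries",
    "compute_svi",
    "svi_from_image",
    "svi_from_pairs",
    "quarterly_series",
    "export_series",
    "read_series",
    "plot_series",
]

SERIES_HEADER = ["site_id", "year", "quarter", "svi_percent", "n_images"]


@dataclass(frozen=True)
class SVIRecord:
    """Vegetation index of one image (or one pooled group of images)."""

    site_id: str
    year: int
    quarter: int
    svi_percent: float
    sp_a: int  # vegetation (semantic) pixel count
    area_t: int  # total pixel count
    n_images: int = 1

    def __post_init__(self):
        if self.quarter not in (1, 2, 3, 4):
            raise ParameterError(f"quarter must be 1..4, got {self.quarter}")
        if self.area_t <= 0:
            raise ParameterError("area_t must be positive")
        expected = 100.0 * self.sp_a / self.area_t
        if abs(self.svi_percent - expected) > 1e-9:
            raise ParameterError("svi_percent inconsistent with sp_a/area_t")


@dataclass(frozen=True)
class SeriesEntry:
    year: int
    quarter: int
    svi_percent: float | None  # None marks a gap quarter
    n_images: int


@dataclass
class SiteSeries:
    """Quarterly mean SVI for one site, in strict chronological order."""

    site_id: str
    entries: list[SeriesEntry] = field(default_factory=list)

    def __post_init__(self):
        keys = [(e.year, e.quarter) for e in self.entries]
        if keys != sorted(keys) or len(set(keys)) != len(keys):
            raise ParameterError("series entries must be strictly increasing in (year, quarter)")

    def values(self) -> list[float | None]:
        return [e.svi_percent for e in self.entries]


def compute_svi(
    mask: np.ndarray, vegetation_class: int = CLASS_VEGETATION
) -> tuple[int, int, float]:
    """Return ``(sp_a, area_t, svi_percent)`` for a class-id mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ParameterError("empty mask")
    sp_a = int(np.sum(mask == vegetation_class))
    area_t = int(mask.size)
    return sp_a, area_t, 100.0 * sp_a / area_t


def svi_from_image(
    model,
    image: np.ndarray,
    vegetation_class: int = CLASS_VEGETATION,
    site_id: str = "",
    timestamp: tuple[int, int] = (0, 1),
) -> SVIRecord:
    """Segment ``image`` with ``model`` and compute its SVI."""
    from svimon.segnet import predict_mask

    pred, _ = predict_mask(model, image)
    sp_a, area_t, svi = compute_svi(pred, vegetation_class)
    year, quarter = timestamp
    return SVIRecord(
        site_id=site_id,
        year=year,
        quarter=quarter,
        svi_percent=svi,
        sp_a=sp_a,
        area_t=area_t,
    )


def svi_from_pairs(model, pairs, vegetation_class: int = CLASS_VEGETATION) -> list[SVIRecord]:
    """Per-image SVI records for a list of scene pairs with timestamps."""
    records = []
    for p in pairs:
        if p.timestamp is None:
            raise ParameterError("scene pair lacks a timestamp")
        records.append(
            svi_from_image(
                model, p.image, vegetation_class, site_id=p.site_id, timestamp=p.timestamp
            )
        )
    return records


def quarterly_series(records: list[SVIRecord], fill_gaps: bool = True) -> SiteSeries:
    """Average per-image SVI within each (year, quarter) of one site.

    With ``fill_gaps`` the series covers every quarter between the first and
    last populated one; empty quarters carry ``svi_percent=None`` and
    ``n_images=0``.
    """
    if not records:
        raise ParameterError("no records")
    site_ids = {r.site_id for r in records}
    if len(site_ids) > 1:
        raise ParameterError(f"records span multiple sites: {sorted(site_ids)}")
    site_id = records[0].site_id

    groups: dict[tuple[int, int], list[float]] = {}
    for r in records:
        groups.setdefault((r.year, r.quarter), []).append(r.svi_percent)

    keys = sorted(groups)
    if fill_gaps:
        first, last = keys[0], keys[-1]
        keys = []
        y, q = first
        while (y, q) <= last:
            keys.append((y, q))
            q += 1
            if q == 5:
                y, q = y + 1, 1
    entries = []
    for key in keys:
        vals = groups.get(key)
        if vals:
            entries.append(SeriesEntry(key[0], key[1], float(np.mean(vals)), len(vals)))
        else:
            entries.append(SeriesEntry(key[0], key[1], None, 0))
    return SiteSeries(site_id=site_id, entries=entries)


def export_series(series: SiteSeries, path: str | Path) -> Path:
    """Write a series CSV with header ``site_id,year,quarter,svi_percent,n_images``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SERIES_HEADER)
        for e in series.entries:
            svi = "" if e.svi_percent is None else f"{e.svi_percent:.10g}"
            writer.writerow([series.site_id, e.year, e.quarter, svi, e.n_images])
    return path


def read_series(path: str | Path) -> SiteSeries:
    """Parse a series CSV; raises :class:`SeriesParseError` with a line number."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesParseError("empty file", line=1) from None
        if header != SERIES_HEADER:
            raise SeriesParseError(f"bad header {header!r}", line=1)
        site_id: str | None = None
        entries: list[SeriesEntry] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise SeriesParseError(f"expected 5 fields, got {len(row)}", line=lineno)
            sid, year_s, quarter_s, svi_s, n_s = row
            if site_id is None:
                site_id = sid
            elif sid != site_id:
                raise SeriesParseError(f"mixed site ids {site_id!r}/{sid!r}", line=lineno)
            try:
                year = int(year_s)
                quarter = int(quarter_s)
                n_images = int(n_s)
                svi = None if svi_s == "" else float(svi_s)
            except ValueError as exc:
                raise SeriesParseError(str(exc), line=lineno) from None
            if quarter not in (1, 2, 3, 4):
                raise SeriesParseError(f"quarter must be 1..4, got {quarter}", line=lineno)
            if svi is not None and not (0.0 <= svi <= 100.0):
                raise SeriesParseError(f"svi_percent out of range: {svi}", line=lineno)
            entries.append(SeriesEntry(year, quarter, svi, n_images))
        if site_id is None:
            raise SeriesParseError("no data rows", line=2)
    try:
        return SiteSeries(site_id=site_id, entries=entries)
    except ParameterError as exc:
        raise SeriesParseError(str(exc)) from None


def plot_series(series: SiteSeries, path: str | Path) -> Path:
    """Quarterly trend plot (mean SVI% per quarter) saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{e.year}Q{e.quarter}" for e in series.entries]
    values = [np.nan if e.svi_percent is None else e.svi_percent for e in series.entries]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(range(len(values)), values, marker="o")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=60, fontsize=7)
    ax.set_ylabel("mean SVI (%)")
    ax.set_title(f"Quarterly vegetation index – {series.site_id}")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
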