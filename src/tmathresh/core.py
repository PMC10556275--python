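"""Domain types, file I/O and intensity/weight summaries for TMA spot analysis.

A tissue microarray (TMA) slide carries hundreds of circular tissue cores
("spots") on a regular (i, j) grid.  Each spot is imaged as a multi-channel
immunofluorescence image (one channel per fluorophore).  This module holds the
shared containers — imaging metadata, the per-marker analysis configuration,
per-spot records arranged on slide grids, spot images with their masks — and
the plumbing to read and write them from CSV/TIFF, plus the mean-intensity and
valid-tissue-weight summaries that the adaptive thresholding consumes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Region-mask label codes.  0 is background / outside tissue.
REGION_EPITHELIUM = 1
REGION_STROMA = 2
REGION_EXCLUDED = 3
REGION_LABELS = {"epithelium": REGION_EPITHELIUM, "stroma": REGION_STROMA,
                 "excluded": REGION_EXCLUDED}

COMPARTMENTS = ("nuclear", "membranous_cytoplasmic")


@dataclass(frozen=True)
class ImagingSpec:
    """Imaging metadata: physical pixel size and the ordered channel layout.

    Parameters
    ----------
    pixel_size:
        Side length of one pixel in micrometres.  The default, 0.4976 μm,
        corresponds to 20x multispectral whole-slide scans.
    channel_names:
        Ordered fluorophore/marker labels, one per image channel.
    """

    pixel_size: float = 0.4976
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError(f"channel_names must be unique, got {names}")
        object.__setattr__(self, "channel_names", names)

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in μm²."""
        return self.pixel_size ** 2

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}") from None


@dataclass(frozen=True)
class MarkerConfig:
    """Per-marker analysis parameters.

    ``factor_F`` is the marker-specific multiplier applied to the weighted
    median of neighbourhood spot intensities to obtain the spot threshold;
    ``reference_threshold`` (T_R) is the positivity threshold set on the
    reference slide, from which slide-specific thresholds are scaled.
    ``centre_weighting`` and ``virtual_complement`` enable the two extra
    features used for threshold-sensitive macrophage-type markers (CD68):
    up-weighting the centre spot, and completing boundary neighbourhoods with
    virtual intensity values.
    """

    marker: str
    channel: str
    compartment: str
    factor_F: float
    reference_threshold: float
    centre_weighting: bool = False
    virtual_complement: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, "
                f"got {self.compartment!r}")
        if not self.factor_F > 0:
            raise ValueError(f"factor_F must be > 0, got {self.factor_F}")
        if not self.reference_threshold > 0:
            raise ValueError("reference_threshold must be > 0, "
                             f"got {self.reference_threshold}")


def default_panel(reference_thresholds: Mapping[str, float] | None = None,
                  ) -> list[MarkerConfig]:
    """The standard four-marker immune panel with its published factors.

    CD20/CD8/CD68 are membranous, FoxP3 nuclear; CD68 additionally uses
    centre weighting and the virtual boundary complement.  Reference
    thresholds default to 1.0 (arbitrary intensity units) and should be set
    per cohort by review of the reference slide.
    """
    ref = dict(reference_thresholds or {})
    spec = [("CD20", "membranous_cytoplasmic", 10.0, False),
            ("CD8", "membranous_cytoplasmic", 6.0, False),
            ("FoxP3", "nuclear", 8.0, False),
            ("CD68", "membranous_cytoplasmic", 2.5, True)]
    return [MarkerConfig(marker=m, channel=m, compartment=c, factor_F=f,
                         reference_threshold=ref.get(m, 1.0),
                         centre_weighting=cd68, virtual_complement=cd68)
            for m, c, f, cd68 in spec]


@dataclass
class SpotImage:
    """One spot's multi-channel pixel data with aligned masks.

    ``channels`` is a (C, H, W) float array ordered as ``channel_names``;
    ``tissue_mask`` marks artefact-free tissue; ``region_mask`` (optional)
    labels epithelium/stroma/excluded; ``nuclei_labels`` (optional) is an
    integer label image of segmented nuclei (0 = background).
    """

    channels: np.ndarray
    channel_names: tuple[str, ...]
    tissue_mask: np.ndarray
    region_mask: np.ndarray | None = None
    nuclei_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (C, H, W)")
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError(
                f"expected {len(self.channel_names)} channels, "
                f"found {self.channels.shape[0]}")
        self.tissue_mask = np.asarray(self.tissue_mask) != 0
        shape = self.channels.shape[1:]
        for name, arr in (("tissue_mask", self.tissue_mask),
                          ("region_mask", self.region_mask),
                          ("nuclei_labels", self.nuclei_labels)):
            if arr is not None and arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != image {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


@dataclass
class SpotRecord:
    """One TMA spot: grid position, validity, intensity/weight summaries.

    ``mean_intensity`` maps marker name to the spot's summary intensity
    I_{s,i,j}; ``tissue_weight`` is the amount of valid tissue in μm²
    (w_{s,i,j}), used to weight the spot in neighbourhood medians.  Invalid
    spots keep their record but contribute weight 0 everywhere.
    """

    slide_id: str
    grid_i: int
    grid_j: int
    valid: bool = True
    mean_intensity: dict[str, float] = field(default_factory=dict)
    tissue_weight: float = 0.0
    image_ref: object | None = None  # path or in-memory SpotImage

    def __post_init__(self) -> None:
        if self.grid_i < 0 or self.grid_j < 0:
            raise ValueError(
                f"negative grid index ({self.grid_i}, {self.grid_j})")
        if self.tissue_weight < 0:
            raise ValueError("tissue_weight must be >= 0")

    @property
    def pos(self) -> tuple[int, int]:
        return (self.grid_i, self.grid_j)

    def effective_weight(self) -> float:
        """Tissue weight, forced to 0 for invalid spots."""
        return self.tissue_weight if self.valid else 0.0


class SlideGrid:
    """All spots of one slide arranged on an (i, j) lattice.

    Missing grid positions are simply absent keys within the bounding
    ``n_rows`` x ``n_cols`` lattice.
    """

    def __init__(self, slide_id: str, n_rows: int, n_cols: int,
                 spots: Iterable[SpotRecord] = ()) -> None:
        self.slide_id = slide_id
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.spots: dict[tuple[int, int], SpotRecord] = {}
        for spot in spots:
            self.add(spot)

    def add(self, spot: SpotRecord) -> None:
        if spot.slide_id != self.slide_id:
            raise ValueError(
                f"spot slide {spot.slide_id!r} != grid {self.slide_id!r}")
        if not (0 <= spot.grid_i < self.n_rows
                and 0 <= spot.grid_j < self.n_cols):
            raise ValueError(
                f"spot {spot.pos} outside {self.n_rows}x{self.n_cols} lattice")
        if spot.pos in self.spots:
            raise ValueError(
                f"duplicate spot at ({self.slide_id}, {spot.grid_i}, "
                f"{spot.grid_j})")
        self.spots[spot.pos] = spot

    def get(self, pos: tuple[int, int]) -> SpotRecord | None:
        return self.spots.get(tuple(pos))

    def valid_spots(self) -> list[SpotRecord]:
        return [s for s in self.spots.values() if s.valid]

    def __len__(self) -> int:
        return len(self.spots)

    def __repr__(self) -> str:
        return (f"SlideGrid({self.slide_id!r}, {self.n_rows}x{self.n_cols}, "
                f"{len(self.spots)} spots)")


@dataclass
class SlideIntensitySummary:
    """Per-slide mean marker intensities I_s, with the reference flag."""

    slide_id: str
    mean_intensity: dict[str, float]
    is_reference: bool = False

    def __post_init__(self) -> None:
        for marker, value in self.mean_intensity.items():
            if value < 0:
                raise ValueError(
                    f"negative slide intensity for {marker}: {value}")


@dataclass
class ThresholdMap:
    """Thresholds of one slide: slide-level T_s and spot-level T_{s,i,j}."""

    slide_id: str
    slide_threshold: dict[str, float] = field(default_factory=dict)
    spot_thresholds: dict[tuple[str, tuple[int, int]], float] = field(
        default_factory=dict)
    n_virtual: dict[tuple[str, tuple[int, int]], int] = field(
        default_factory=dict)

    def threshold_for(self, marker: str, pos: tuple[int, int]) -> float:
        """Spot-specific threshold when present, else the slide threshold."""
        key = (marker, tuple(pos))
        if key in self.spot_thresholds:
            return self.spot_thresholds[key]
        if marker in self.slide_threshold:
            return self.slide_threshold[marker]
        raise KeyError(
            f"no threshold for marker {marker!r} on slide "
            f"{self.slide_id!r} at {tuple(pos)}")


# ---------------------------------------------------------------------------
# Grid layout I/O

_GRID_COLUMNS = ("slide_id", "i", "j", "valid")
_OPT_PATH_COLUMNS = ("image_path", "mask_path", "region_path", "nuclei_path")


def read_grid_layout(path: str | Path) -> list[SlideGrid]:
    """Read a TMA grid layout CSV into one :class:`SlideGrid` per slide.

    The CSV needs columns ``slide_id,i,j,valid`` plus optional per-spot file
    path columns.  The bounding lattice of each slide is inferred from the
    maximum indices; rows absent from the file are missing positions.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in _GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid layout missing columns {missing}")
    grids: list[SlideGrid] = []
    for slide_id, sub in df.groupby("slide_id", sort=True):
        if (sub[["i", "j"]] < 0).any().any():
            raise ValueError(f"negative grid indices on slide {slide_id}")
        dup = sub.duplicated(subset=["i", "j"])
        if dup.any():
            i, j = sub.loc[dup.idxmax(), ["i", "j"]]
            raise ValueError(
                f"duplicate spot at ({slide_id}, {int(i)}, {int(j)})")
        grid = SlideGrid(str(slide_id), int(sub["i"].max()) + 1,
                         int(sub["j"].max()) + 1)
        for _, row in sub.iterrows():
            ref = None
            paths = {c: row[c] for c in _OPT_PATH_COLUMNS
                     if c in sub.columns and isinstance(row[c], str)}
            if paths:
                ref = paths
            grid.add(SpotRecord(slide_id=str(slide_id), grid_i=int(row["i"]),
                                grid_j=int(row["j"]),
                                valid=bool(row["valid"]), image_ref=ref))
        grids.append(grid)
    return grids


def write_grid_layout(grids: Sequence[SlideGrid], path: str | Path) -> None:
    """Inverse of :func:`read_grid_layout` (lossless for layout columns)."""
    rows = []
    for grid in grids:
        for spot in grid.spots.values():
            row = {"slide_id": grid.slide_id, "i": spot.grid_i,
                   "j": spot.grid_j, "valid": spot.valid}
            if isinstance(spot.image_ref, dict):
                row.update(spot.image_ref)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spot image I/O

def _read_single_channel(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio
    return np.asarray(iio.imread(path))


def read_spot_image(path: str | Path, spec: ImagingSpec,
                    tissue_path: str | Path | None = None,
                    region_path: str | Path | None = None,
                    nuclei_path: str | Path | None = None) -> SpotImage:
    """Read a multi-channel spot TIFF (+ optional companion masks).

    The channel axis is auto-detected: a (C, H, W) or (H, W, C) array is
    accepted as long as one axis length equals ``len(spec.channel_names)``.
    """
    arr = np.asarray(tifffile.imread(path))
    n = len(spec.channel_names)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D TIFF, got shape {arr.shape}")
    if arr.shape[0] != n and arr.shape[-1] == n:
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] != n:
        raise ValueError(
            f"channel count mismatch: expected {n} channels "
            f"({spec.channel_names}), found {arr.shape[0]} in {path}")
    tissue = (_read_single_channel(tissue_path) != 0) if tissue_path \
        else np.ones(arr.shape[1:], dtype=bool)
    region = _read_single_channel(region_path).astype(np.int32) \
        if region_path else None
    nuclei = _read_single_channel(nuclei_path).astype(np.int32) \
        if nuclei_path else None
    return SpotImage(channels=arr, channel_names=spec.channel_names,
                     tissue_mask=tissue, region_mask=region,
                     nuclei_labels=nuclei)


def write_spot_image(path: str | Path, img: SpotImage) -> None:
    """Write the channel stack as a (C, H, W) TIFF (bit-exact round trip)."""
    tifffile.imwrite(path, np.asarray(img.channels),
                     photometric="minisblack", planarconfig="separate")


# ---------------------------------------------------------------------------
# Summaries

def compute_tissue_weight(img: SpotImage, spec: ImagingSpec) -> float:
    """Amount of valid tissue in the spot, in μm²."""
    return float(np.count_nonzero(img.tissue_mask)) * spec.pixel_area_um2


def compute_spot_mean_intensity(img: SpotImage, marker: MarkerConfig,
                                domain: str = "all_pixels") -> float:
    """Mean intensity of the marker's channel over the chosen domain.

    ``domain`` is one of ``all_pixels`` (every pixel of the spot square, the
    spot-level summary used by the spot-threshold equation),
    ``tissue_pixels`` (restricted to the tissue mask), or ``cells`` (average
    of per-nucleus mean intensities; requires ``nuclei_labels``, the
    slide-level summary convention).
    """
    channel = img.channel(marker.channel)
    if domain == "all_pixels":
        return float(channel.mean())
    if domain == "tissue_pixels":
        if not img.tissue_mask.any():
            raise ValueError("no pixels/cells in domain: empty tissue mask")
        return float(channel[img.tissue_mask].mean())
    if domain == "cells":
        if img.nuclei_labels is None:
            raise ValueError("domain='cells' requires nuclei_labels")
        labels = np.unique(img.nuclei_labels)
        labels = labels[labels > 0]
        if labels.size == 0:
            raise ValueError("no pixels/cells in domain: no nuclei")
        means = ndimage.mean(channel, labels=img.nuclei_labels, index=labels)
        return float(np.mean(means))
    raise ValueError(f"unknown domain {domain!r}")


def populate_spot_summaries(grid: SlideGrid, spec: ImagingSpec,
                            markers: Sequence[MarkerConfig],
                            domain: str = "all_pixels") -> None:
    """Fill ``mean_intensity`` and ``tissue_weight`` of every spot that
    carries an in-memory :class:`SpotImage` (or loadable path dict)."""
    for spot in grid.spots.values():
        img = resolve_spot_image(spot, spec)
        if img is None:
            continue
        spot.tissue_weight = compute_tissue_weight(img, spec)
        for m in markers:
            spot.mean_intensity[m.marker] = compute_spot_mean_intensity(
                img, m, domain=domain)


def resolve_spot_image(spot: SpotRecord,
                       spec: ImagingSpec) -> SpotImage | None:
    """Return the spot's image, loading it from paths if necessary."""
    ref = spot.image_ref
    if ref is None:
        return None
    if isinstance(ref, SpotImage):
        return ref
    if isinstance(ref, dict):
        return read_spot_image(ref["image_path"], spec,
                               tissue_path=ref.get("mask_path"),
                               region_path=ref.get("region_path"),
                               nuclei_path=ref.get("nuclei_path"))
    return read_spot_image(ref, spec)


def summarize_slide(grid: SlideGrid, marker_names: Sequence[str],
                    is_reference: bool = False) -> SlideIntensitySummary:
    """Slide-level mean intensity per marker over the slide's valid spots.

    The summary is the unweighted mean of per-spot summary intensities; spots
    without an intensity entry for a marker are skipped.
    """
    means: dict[str, float] = {}
    for name in marker_names:
        vals = [s.mean_intensity[name] for s in grid.valid_spots()
                if name in s.mean_intensity]
        if not vals:
            raise ValueError(
                f"slide {grid.slide_id!r} has no intensities for {name!r}")
        means[name] = float(np.mean(vals))
    return SlideIntensitySummary(slide_id=grid.slide_id,
                                 mean_intensity=means,
                                 is_reference=is_reference)


# ---------------------------------------------------------------------------
# Results and panel I/O

def write_results(results: Sequence, path: str | Path) -> None:
    """Write quantification results (dataclasses or dicts) to CSV.

    One row per spot x region x marker, stable column order, re-readable
    with :func:`read_results`.
    """
    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in results]
    columns = ["slide_id", "i", "j", "region", "marker", "n_cells_total",
               "n_cells_positive", "area_total_um2", "area_positive_um2",
               "density_cells_per_mm2", "pct_positive_area"]
    if not rows:
        df = pd.DataFrame(columns=columns)
    else:
        df = pd.DataFrame(rows)
        ordered = [c for c in columns if c in df.columns]
        extras = [c for c in df.columns if c not in columns]
        df = df[ordered + extras]
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_marker_panel(path: str | Path) -> list[MarkerConfig]:
    """Read a marker panel from YAML or JSON.

    Expected layout::

        markers:
          - {name: CD8, channel: CD8, compartment: membranous_cytoplasmic,
             factor_F: 6, reference_threshold: 1.2,
             centre_weighting: false, virtual_complement: false}
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    configs = []
    for entry in data["markers"]:
        configs.append(MarkerConfig(
            marker=entry["name"],
            channel=entry.get("channel", entry["name"]),
            compartment=entry["compartment"],
            factor_F=float(entry["factor_F"]),
            reference_threshold=float(entry["reference_threshold"]),
            centre_weighting=bool(entry.get("centre_weighting", False)),
            virtual_complement=bool(entry.get("virtual_complement", False))))
    return configs


def write_marker_panel(configs: Sequence[MarkerConfig],
                       path: str | Path) -> None:
    data = {"markers": [{
        "name": c.marker, "channel": c.channel,
        "compartment": c.compartment, "factor_F": c.factor_F,
        "reference_threshold": c.reference_threshold,
        "centre_weighting": c.centre_weighting,
        "virtual_complement": c.virtual_complement} for c in configs]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
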