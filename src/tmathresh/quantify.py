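"""Pixel-based and cell-based marker quantification.

Cell-based analysis evaluates marker expression per segmented cell, separately
for the nuclear and cytoplasmic compartments; the cytoplasm is a ring of
radius 1 μm around the nucleus, split at the equidistant line when nuclei lie
closer than 1 μm.  Pixel-based analysis classifies every tissue pixel as
positive/negative against the threshold, reporting positive area.  Spot-level
results aggregate to case level by summing counts and areas, with densities
recomputed from the sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (REGION_EPITHELIUM, REGION_STROMA, ImagingSpec,
                   MarkerConfig, SpotImage, ThresholdMap)

logger = logging.getLogger(__name__)

_REGION_IDS = {"epithelium": REGION_EPITHELIUM, "stroma": REGION_STROMA}
REGIONS = ("epithelium", "stroma", "all")

UM2_PER_MM2 = 1e6


@dataclass
class CellRecord:
    """One segmented cell with per-compartment marker means and calls."""

    label: int
    region: str | None  # majority region of the nucleus, None if unlabelled
    n_nucleus_px: int
    n_cytoplasm_px: int
    nucleus_mean: dict[str, float] = field(default_factory=dict)
    cytoplasm_mean: dict[str, float] = field(default_factory=dict)
    positivity: dict[str, bool] = field(default_factory=dict)


@dataclass
class SpotQuantResult:
    """Counts, areas and densities for one spot x region x marker."""

    slide_id: str
    i: int
    j: int
    region: str
    marker: str
    n_cells_total: int = 0
    n_cells_positive: int = 0
    area_total_um2: float = 0.0
    area_positive_um2: float = 0.0
    density_cells_per_mm2: float = float("nan")
    pct_positive_area: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.n_cells_positive <= self.n_cells_total):
            raise ValueError("positive cells must lie within [0, total]")
        if self.area_positive_um2 > self.area_total_um2 + 1e-9:
            raise ValueError("positive area cannot exceed total area")


def _derive_densities(r: SpotQuantResult) -> SpotQuantResult:
    if r.area_total_um2 > 0:
        r.density_cells_per_mm2 = (
            r.n_cells_positive / (r.area_total_um2 / UM2_PER_MM2))
        r.pct_positive_area = 100.0 * r.area_positive_um2 / r.area_total_um2
    else:
        r.density_cells_per_mm2 = float("nan")
        r.pct_positive_area = float("nan")
    return r


def build_cytoplasm_rings(nuclei_labels: np.ndarray, spec: ImagingSpec,
                          radius_um: float = 1.0) -> np.ndarray:
    """Cytoplasm label image: ring of ``radius_um`` around each nucleus.

    Each cytoplasm pixel lies within ``radius_um`` of its nucleus and closer
    to that nucleus than to any other (Euclidean distance to the nearest
    nucleus pixel), which realizes the half-distance rule for nuclei closer
    than ``2*radius_um``.  Nucleus pixels are never cytoplasm; rings of
    different cells are disjoint by construction.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    nuclei_labels = np.asarray(nuclei_labels)
    out = np.zeros_like(nuclei_labels, dtype=np.int32)
    if not (nuclei_labels > 0).any():
        return out
    background = nuclei_labels == 0
    dist, (ind_i, ind_j) = ndimage.distance_transform_edt(
        background, sampling=(spec.pixel_size, spec.pixel_size),
        return_indices=True)
    ring = background & (dist <= radius_um)
    out[ring] = nuclei_labels[ind_i[ring], ind_j[ring]]
    return out


def _majority_region(region_mask: np.ndarray | None,
                     mask: np.ndarray) -> str | None:
    if region_mask is None:
        return None
    vals, counts = np.unique(region_mask[mask], return_counts=True)
    keep = [(c, v) for v, c in zip(vals, counts)
            if v in (REGION_EPITHELIUM, REGION_STROMA)]
    if not keep:
        return None
    _, winner = max(keep)
    return "epithelium" if winner == REGION_EPITHELIUM else "stroma"


def extract_cells(img: SpotImage, configs: Sequence[MarkerConfig],
                  spec: ImagingSpec,
                  radius_um: float = 1.0) -> list[CellRecord]:
    """Build :class:`CellRecord` objects from the spot's nuclei labels.

    Computes the cytoplasm rings, per-compartment mean intensity for every
    configured marker, and each cell's region by majority vote of its
    nucleus pixels.
    """
    if img.nuclei_labels is None:
        raise ValueError("spot image has no nuclei_labels")
    nuclei = np.asarray(img.nuclei_labels)
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []
    cyto = build_cytoplasm_rings(nuclei, spec, radius_um=radius_um)
    nuc_sizes = ndimage.sum_labels(np.ones_like(nuclei), nuclei, labels)
    cyt_sizes = ndimage.sum_labels(np.ones_like(cyto), cyto, labels)
    cells = []
    for k, label in enumerate(labels):
        cells.append(CellRecord(
            label=int(label),
            region=_majority_region(img.region_mask, nuclei == label),
            n_nucleus_px=int(nuc_sizes[k]),
            n_cytoplasm_px=int(cyt_sizes[k])))
    for cfg in configs:
        channel = img.channel(cfg.channel)
        nuc_means = ndimage.mean(channel, labels=nuclei, index=labels)
        # ndimage.mean yields nan for labels absent from the cytoplasm image
        with np.errstate(invalid="ignore"):
            cyt_means = ndimage.mean(channel, labels=cyto, index=labels)
        for k, cell in enumerate(cells):
            cell.nucleus_mean[cfg.marker] = float(nuc_means[k])
            cell.cytoplasm_mean[cfg.marker] = float(cyt_means[k])
    return cells


def classify_cells(cells: Sequence[CellRecord], marker: MarkerConfig,
                   threshold: float) -> list[bool]:
    """Positivity call per cell: compartment mean >= threshold.

    The marker's configured compartment routes the decision (nuclear markers
    use the nucleus mean, membranous/cytoplasmic markers the cytoplasm-ring
    mean).  Cells with an empty compartment are negative and logged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    calls = []
    for cell in cells:
        if marker.compartment == "nuclear":
            mean = cell.nucleus_mean.get(marker.marker, float("nan"))
            empty = cell.n_nucleus_px == 0
        else:
            mean = cell.cytoplasm_mean.get(marker.marker, float("nan"))
            empty = cell.n_cytoplasm_px == 0
        if empty or not np.isfinite(mean):
            logger.debug("cell %d has empty %s compartment for %s; negative",
                         cell.label, marker.compartment, marker.marker)
            call = False
        else:
            call = bool(mean >= threshold)
        cell.positivity[marker.marker] = call
        calls.append(call)
    return calls


def _region_mask(img: SpotImage, region: str) -> np.ndarray:
    """Pixels of the requested region restricted to valid tissue."""
    if region == "all":
        return img.tissue_mask
    if region not in _REGION_IDS:
        raise ValueError(f"unknown region {region!r}")
    if img.region_mask is None:
        raise ValueError(f"region {region!r} requested but spot has no "
                         "region mask")
    return img.tissue_mask & (img.region_mask == _REGION_IDS[region])


def quantify_pixels(img: SpotImage, marker: MarkerConfig, threshold: float,
                    region: str, spec: ImagingSpec) -> tuple[float, float]:
    """(positive area, total area) in μm² for one marker and region."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = _region_mask(img, region)
    channel = img.channel(marker.channel)
    area_total = float(np.count_nonzero(mask)) * spec.pixel_area_um2
    area_pos = float(np.count_nonzero(mask & (channel >= threshold))) \
        * spec.pixel_area_um2
    return area_pos, area_total


def quantify_spot(img: SpotImage, spot_key: tuple[str, int, int],
                  thresholds: ThresholdMap | Mapping[str, float],
                  configs: Sequence[MarkerConfig], spec: ImagingSpec,
                  cells: Sequence[CellRecord] | None = None,
                  regions: Sequence[str] = REGIONS,
                  ) -> list[SpotQuantResult]:
    """Quantify one spot for every marker x region.

    Pixel metrics are always computed; cell metrics when ``cells`` are given
    (or derivable from the image's nuclei labels).  The spot-specific
    threshold is used when present in the map, else the slide threshold.
    """
    slide_id, i, j = spot_key
    if cells is None and img.nuclei_labels is not None:
        cells = extract_cells(img, configs, spec)
    results = []
    for cfg in configs:
        if isinstance(thresholds, ThresholdMap):
            t = thresholds.threshold_for(cfg.marker, (i, j))
        else:
            if cfg.marker not in thresholds:
                raise KeyError(f"no threshold for marker {cfg.marker!r} on "
                               f"slide {slide_id!r}")
            t = thresholds[cfg.marker]
        calls = classify_cells(cells, cfg, t) if cells else []
        for region in regions:
            if region != "all" and img.region_mask is None:
                continue
            area_pos, area_tot = quantify_pixels(img, cfg, t, region, spec)
            if cells:
                in_region = [c for c in cells
                             if region == "all" or c.region == region]
                n_tot = len(in_region)
                n_pos = sum(c.positivity[cfg.marker] for c in in_region)
            else:
                n_tot = n_pos = 0
            results.append(_derive_densities(SpotQuantResult(
                slide_id=slide_id, i=i, j=j, region=region,
                marker=cfg.marker, n_cells_total=n_tot,
                n_cells_positive=n_pos, area_total_um2=area_tot,
                area_positive_um2=area_pos)))
    return results


def aggregate_cases(results: Sequence[SpotQuantResult] | pd.DataFrame,
                    case_map: Mapping[tuple[str, int, int], str],
                    ) -> pd.DataFrame:
    """Aggregate spot-level results to case level.

    Counts and areas are summed per case x region x marker; densities and
    percentages are recomputed from the summed numerators and denominators
    (never by averaging per-spot ratios).  Every spot must map to a case.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        return pd.DataFrame(columns=["case_id", "region", "marker",
                                     "n_cells_total", "n_cells_positive",
                                     "area_total_um2", "area_positive_um2",
                                     "density_cells_per_mm2",
                                     "pct_positive_area"])
    keys = list(zip(df["slide_id"], df["i"].astype(int),
                    df["j"].astype(int)))
    unmapped = sorted({k for k in keys if k not in case_map})
    if unmapped:
        raise KeyError(f"spots not mapped to a case: {unmapped[:5]}")
    df["case_id"] = [case_map[k] for k in keys]
    agg = (df.groupby(["case_id", "region", "marker"], as_index=False)
             [["n_cells_total", "n_cells_positive", "area_total_um2",
               "area_positive_um2"]].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["density_cells_per_mm2"] = np.where(
            agg["area_total_um2"] > 0,
            agg["n_cells_positive"] / (agg["area_total_um2"] / UM2_PER_MM2),
            np.nan)
        agg["pct_positive_area"] = np.where(
            agg["area_total_um2"] > 0,
            100.0 * agg["area_positive_um2"] / agg["area_total_um2"],
            np.nan)
    return agg
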