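"""Adaptive marker thresholds for TMA cohorts.

Two corrections are combined to absorb staining/imaging intensity variation:

* **Slide-specific thresholds** (inter-slide variation): the threshold of
  slide *s* is the reference threshold scaled by the ratio of slide mean
  intensities, ``T_s = T_R * I_s / I_R``.

* **Spot-specific thresholds** (intra-slide variation): the threshold of the
  spot at grid position (i, j) is a marker factor times the tissue-weighted
  median of spot mean intensities over the 7x7 grid neighbourhood centred on
  the spot, ``T_{i,j} = F * wmedian(I_{k,l}, w_{k,l})``.  The median makes
  the local background estimate robust to sparse biologically bright spots,
  while smooth slide-wide gradients are tracked by the moving window.

For threshold-sensitive markers (CD68-style) two extra features apply: the
centre spot's weight is multiplied by the number of neighbouring spots (so
bright spots raise their own threshold), and boundary windows are completed
with *virtual* intensities reflected through the centre so every spot sees a
balanced neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (MarkerConfig, SlideGrid, SlideIntensitySummary,
                   ThresholdMap)

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 3  # 7x7 window ("square of side length 7")


@dataclass(frozen=True)
class NeighborhoodEntry:
    pos: tuple[int, int]
    intensity: float
    weight: float
    is_virtual: bool = False


@dataclass
class NeighborhoodWindow:
    """The (2*half_width+1)² square of spots centred on ``centre``."""

    centre: tuple[int, int]
    half_width: int
    entries: list[NeighborhoodEntry]

    @property
    def n_virtual(self) -> int:
        return sum(e.is_virtual for e in self.entries)

    def present(self) -> list[NeighborhoodEntry]:
        return [e for e in self.entries if not e.is_virtual]


def weighted_median(values: Sequence[float],
                    weights: Sequence[float]) -> float:
    """Lower weighted median of ``values`` with non-negative ``weights``.

    Returns the smallest value v such that the cumulative weight of all
    values <= v reaches at least half the total weight.  Entries with zero
    weight never influence the result.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.ndim != 1:
        raise ValueError(
            f"values and weights must be 1-D and equal length, got "
            f"{values.shape} vs {weights.shape}")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    total = weights.sum()
    if total <= 0:
        raise ValueError("no weighted support (total weight is 0)")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, total / 2.0))
    idx = min(idx, len(cum) - 1)  # guard against cumsum/sum fp drift
    return float(values[order][idx])


def compute_slide_thresholds(
        summaries: Sequence[SlideIntensitySummary],
        configs: Sequence[MarkerConfig],
) -> dict[tuple[str, str], float]:
    """Slide-specific thresholds ``T_s = T_R * I_s / I_R`` per (slide, marker).

    Exactly one summary must be flagged as the reference slide; the
    reference slide maps to exactly ``T_R``.
    """
    refs = [s for s in summaries if s.is_reference]
    if len(refs) != 1:
        raise ValueError(
            f"exactly one reference slide required, found {len(refs)}")
    ref = refs[0]
    out: dict[tuple[str, str], float] = {}
    for cfg in configs:
        i_ref = ref.mean_intensity.get(cfg.marker)
        if i_ref is None or i_ref <= 0:
            raise ValueError(
                f"reference slide intensity for {cfg.marker!r} must be > 0, "
                f"got {i_ref}")
        for s in summaries:
            if s.slide_id == ref.slide_id:
                out[(s.slide_id, cfg.marker)] = cfg.reference_threshold
            else:
                out[(s.slide_id, cfg.marker)] = (
                    cfg.reference_threshold
                    * s.mean_intensity[cfg.marker] / i_ref)
    return out


def _window_positions(centre: tuple[int, int],
                      half_width: int) -> list[tuple[int, int]]:
    i, j = centre
    return [(k, l)
            for k in range(i - half_width, i + half_width + 1)
            for l in range(j - half_width, j + half_width + 1)]


def _present_entries(grid: SlideGrid, centre: tuple[int, int], marker: str,
                     half_width: int) -> list[NeighborhoodEntry]:
    entries = []
    for pos in _window_positions(centre, half_width):
        spot = grid.get(pos)
        if spot is None or not spot.valid:
            continue
        if marker not in spot.mean_intensity:
            continue
        entries.append(NeighborhoodEntry(
            pos=pos, intensity=float(spot.mean_intensity[marker]),
            weight=spot.effective_weight()))
    return entries


def virtual_complement_value(grid: SlideGrid, centre: tuple[int, int],
                             missing: tuple[int, int], marker: MarkerConfig,
                             half_width: int = DEFAULT_HALF_WIDTH) -> float:
    """Virtual intensity for a missing window position.

    The opposite spot in the direction of the centre (point reflection of
    ``missing`` through ``centre``) provides the intensity; the mean of all
    present spots in the window is subtracted, and the result is floored at
    0 since intensities cannot be negative.  If the opposite position is
    itself missing, the mean of the present spots stands in for its
    intensity, so the complement value degenerates to 0 (a constant grid
    therefore yields 0 for every virtual entry).
    """
    present = _present_entries(grid, centre, marker.marker, half_width)
    if not present:
        raise ValueError(
            f"no present spots in window of {centre} on {grid.slide_id!r}")
    mean_present = float(np.mean([e.intensity for e in present]))
    k, l = missing
    i, j = centre
    opposite = (2 * i - k, 2 * j - l)
    opp_spot = grid.get(opposite)
    if opp_spot is None or not opp_spot.valid \
            or marker.marker not in opp_spot.mean_intensity:
        return 0.0
    return max(0.0, float(opp_spot.mean_intensity[marker.marker])
               - mean_present)


def collect_neighborhood(grid: SlideGrid, centre: tuple[int, int],
                         marker: MarkerConfig,
                         half_width: int = DEFAULT_HALF_WIDTH,
                         ) -> NeighborhoodWindow:
    """All spots of the square window centred on ``centre``.

    Invalid and missing spots are omitted (they carry no weight).  When the
    marker uses the virtual complement, every absent window position —
    including positions outside the slide lattice — is filled with a virtual
    entry so the window always holds (2*half_width+1)² entries.  Virtual
    entries carry the mean tissue weight of the present entries.
    """
    centre = tuple(centre)
    spot = grid.get(centre)
    if spot is None or not spot.valid:
        raise ValueError(
            f"centre {centre} is not a valid spot of {grid.slide_id!r}")
    entries = _present_entries(grid, centre, marker.marker, half_width)
    if marker.virtual_complement:
        present_pos = {e.pos for e in entries}
        mean_weight = float(np.mean([e.weight for e in entries])) \
            if entries else 0.0
        for pos in _window_positions(centre, half_width):
            if pos in present_pos:
                continue
            value = virtual_complement_value(grid, centre, pos, marker,
                                             half_width)
            entries.append(NeighborhoodEntry(
                pos=pos, intensity=value, weight=mean_weight,
                is_virtual=True))
    return NeighborhoodWindow(centre=centre, half_width=half_width,
                              entries=entries)


def threshold_from_window(window: NeighborhoodWindow, marker: MarkerConfig,
                          slide_threshold: float | None = None) -> float:
    """Spot threshold ``F * wmedian`` from a collected window.

    With ``centre_weighting`` the centre spot's weight is first multiplied
    by the number of neighbouring entries — every other entry of the
    (possibly virtually completed) window — giving the centre equal weight
    to all the others together.  Counting virtual entries here is what
    keeps boundary thresholds stable: virtual complement values are
    background deviations (0 on a flat field), and were the centre not
    balanced against them they could dominate the weighted median of
    boundary windows and collapse it to 0.  A window with zero total
    weight falls back to the slide threshold when one is given.
    """
    values, weights = [], []
    n_neighbours = sum(1 for e in window.entries
                       if e.pos != window.centre)
    for e in window.entries:
        w = e.weight
        if (marker.centre_weighting and e.pos == window.centre
                and not e.is_virtual and n_neighbours > 0):
            w = w * n_neighbours
        values.append(e.intensity)
        weights.append(w)
    if sum(weights) <= 0:
        if slide_threshold is not None:
            logger.warning(
                "window of %s has zero total weight; falling back to slide "
                "threshold %.6g", window.centre, slide_threshold)
            return float(slide_threshold)
        raise ValueError(
            f"window of {window.centre} has zero total weight and no slide "
            f"threshold to fall back to")
    return marker.factor_F * weighted_median(values, weights)


def compute_spot_threshold(grid: SlideGrid, centre: tuple[int, int],
                           marker: MarkerConfig,
                           half_width: int = DEFAULT_HALF_WIDTH,
                           slide_threshold: float | None = None) -> float:
    """Threshold of one spot: ``F * wmedian`` over its 7x7 neighbourhood."""
    window = collect_neighborhood(grid, centre, marker, half_width)
    return threshold_from_window(window, marker, slide_threshold)


def compute_threshold_map(grid: SlideGrid,
                          summaries: Sequence[SlideIntensitySummary],
                          configs: Sequence[MarkerConfig],
                          mode: str = "both",
                          half_width: int = DEFAULT_HALF_WIDTH,
                          ) -> ThresholdMap:
    """Fill slide- and/or spot-level thresholds for one slide.

    ``mode``: ``slide`` (slide-specific only), ``spot`` (spot-specific
    only), or ``both`` (slide thresholds plus spot thresholds, the slide
    value serving as fallback for zero-weight windows).
    """
    if mode not in ("slide", "spot", "both"):
        raise ValueError(f"mode must be slide|spot|both, got {mode!r}")
    tmap = ThresholdMap(slide_id=grid.slide_id)
    slide_thresholds: Mapping[str, float] = {}
    if mode in ("slide", "both"):
        per_pair = compute_slide_thresholds(summaries, configs)
        slide_thresholds = {cfg.marker: per_pair[(grid.slide_id, cfg.marker)]
                            for cfg in configs}
        tmap.slide_threshold = dict(slide_thresholds)
    if mode in ("spot", "both"):
        for cfg in configs:
            fallback = slide_thresholds.get(cfg.marker)
            for spot in grid.valid_spots():
                window = collect_neighborhood(grid, spot.pos, cfg, half_width)
                t = threshold_from_window(window, cfg,
                                          slide_threshold=fallback)
                if t <= 0 and fallback is not None:
                    # virtual-dominated window degenerated to 0; keep the
                    # per-spot threshold positive via the slide level
                    logger.warning(
                        "spot threshold of %s/%s at %s degenerated to %g; "
                        "using slide threshold", grid.slide_id, cfg.marker,
                        spot.pos, t)
                    t = fallback
                tmap.spot_thresholds[(cfg.marker, spot.pos)] = t
                tmap.n_virtual[(cfg.marker, spot.pos)] = window.n_virtual
    return tmap


# ---------------------------------------------------------------------------
# Threshold table I/O

def write_threshold_maps(tmaps: Sequence[ThresholdMap],
                         path: str | Path) -> None:
    """CSV ``slide_id,marker,i,j,threshold,level,n_virtual`` (slide rows
    leave i,j empty)."""
    rows = []
    for tm in tmaps:
        for marker, t in sorted(tm.slide_threshold.items()):
            rows.append({"slide_id": tm.slide_id, "marker": marker,
                         "i": None, "j": None, "threshold": t,
                         "level": "slide", "n_virtual": 0})
        for (marker, (i, j)), t in sorted(tm.spot_thresholds.items()):
            rows.append({"slide_id": tm.slide_id, "marker": marker,
                         "i": i, "j": j, "threshold": t, "level": "spot",
                         "n_virtual": tm.n_virtual.get((marker, (i, j)), 0)})
    pd.DataFrame(rows, columns=["slide_id", "marker", "i", "j", "threshold",
                                "level", "n_virtual"]).to_csv(path,
                                                              index=False)


def read_threshold_maps(path: str | Path) -> list[ThresholdMap]:
    df = pd.read_csv(path)
    tmaps: dict[str, ThresholdMap] = {}
    for _, row in df.iterrows():
        tm = tmaps.setdefault(str(row["slide_id"]),
                              ThresholdMap(slide_id=str(row["slide_id"])))
        if row["level"] == "slide":
            tm.slide_threshold[row["marker"]] = float(row["threshold"])
        else:
            key = (row["marker"], (int(row["i"]), int(row["j"])))
            tm.spot_thresholds[key] = float(row["threshold"])
            tm.n_virtual[key] = int(row["n_virtual"])
    return list(tmaps.values())
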