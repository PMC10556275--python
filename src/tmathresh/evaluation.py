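"""Validation statistics: pixel-vs-cell correlation, density distributions,
and adaptive-vs-global thresholding error on synthetic cohorts.

The adaptive-vs-global comparison measures, for each thresholding mode, the
mean absolute error of per-spot positive-area fraction against the
generator's ground truth.  The ``global`` baseline is fit in hindsight (the
single threshold minimising cohort error over a dense candidate grid), so
the adaptive method competes against the strongest global competitor rather
than a strawman.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (ImagingSpec, MarkerConfig, SlideGrid, resolve_spot_image,
                   summarize_slide)
from .thresholds import (compute_slide_thresholds, compute_spot_threshold,
                         compute_threshold_map)

logger = logging.getLogger(__name__)

MODES = ("global", "slide", "spot", "slide+spot")


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman correlation of one marker x region comparison."""

    marker: str
    region: str
    n: int
    spearman_rho: float
    p_value: float
    kind: str  # counts_vs_area | density_vs_pct

    def __post_init__(self) -> None:
        if np.isfinite(self.spearman_rho) \
                and not -1 <= self.spearman_rho <= 1:
            raise ValueError(f"rho out of range: {self.spearman_rho}")


def spearman_correlation(x: Sequence[float],
                         y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected average ranks.

    The p value comes from the standard large-sample approximation, except
    for n <= 8 where the exact permutation distribution is enumerated.
    Constant inputs have undefined rho, reported as (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input vector: Spearman rho undefined")
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 8:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, perm)[0, 1])
            count += r >= observed - 1e-12
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def pixel_vs_cell_report(results: pd.DataFrame,
                         regions: Sequence[str] = ("stroma", "epithelium"),
                         ) -> list[CorrelationReport]:
    """Cross-validate pixel-based against cell-based quantification.

    Per marker x region, correlates (a) positive-cell counts with positive
    area in μm² and (b) positive-cell densities (cells/mm²) with the
    percentage of positive area.  Regions absent from the table are skipped
    with a log message.  Row order of the input never affects the report.
    """
    reports = []
    for marker in sorted(results["marker"].unique()):
        for region in regions:
            sub = results[(results["marker"] == marker)
                          & (results["region"] == region)]
            sub = sub.sort_values(["slide_id", "i", "j"])
            if sub.empty:
                logger.info("region %r absent for marker %s; skipped",
                            region, marker)
                continue
            pairs = (("counts_vs_area", "n_cells_positive",
                      "area_positive_um2"),
                     ("density_vs_pct", "density_cells_per_mm2",
                      "pct_positive_area"))
            for kind, xcol, ycol in pairs:
                ok = sub[[xcol, ycol]].notna().all(axis=1)
                x = sub.loc[ok, xcol].to_numpy(float)
                y = sub.loc[ok, ycol].to_numpy(float)
                if x.size < 3:
                    logger.info("fewer than 3 spots for %s/%s %s; skipped",
                                marker, region, kind)
                    continue
                rho, p = spearman_correlation(x, y)
                reports.append(CorrelationReport(
                    marker=marker, region=region, n=int(x.size),
                    spearman_rho=rho, p_value=p, kind=kind))
    return reports


def reports_to_frame(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


# ---------------------------------------------------------------------------
# Adaptive vs global thresholding error

def _spot_pixel_cache(grids: Sequence[SlideGrid], imaging: ImagingSpec,
                      markers: Sequence[MarkerConfig]) -> pd.DataFrame:
    """Sorted tissue-pixel intensities per valid spot and marker."""
    rows = []
    for grid in grids:
        for spot in grid.valid_spots():
            img = resolve_spot_image(spot, imaging)
            tissue = img.tissue_mask
            for cfg in markers:
                vals = np.sort(img.channel(cfg.channel)[tissue])
                rows.append({"slide_id": grid.slide_id, "i": spot.grid_i,
                             "j": spot.grid_j, "marker": cfg.marker,
                             "sorted_vals": vals})
    return pd.DataFrame(rows)


def _fraction_at(sorted_vals: np.ndarray, threshold: float) -> float:
    """Fraction of tissue pixels with intensity >= threshold."""
    n = sorted_vals.size
    if n == 0:
        return float("nan")
    return 1.0 - np.searchsorted(sorted_vals, threshold, side="left") / n


def _best_global_threshold(cache: pd.DataFrame, truth: Mapping,
                           n_candidates: int = 512) -> float:
    vals = np.concatenate([v for v in cache["sorted_vals"]])
    lo, hi = np.quantile(vals, [0.001, 0.999])
    lo = max(lo, 1e-9)
    candidates = np.geomspace(lo, max(hi, lo * 1.001), n_candidates)
    best_t, best_err = candidates[0], math.inf
    frames = [(row["sorted_vals"],
               truth[(row["slide_id"], row["i"], row["j"], row["marker"])])
              for _, row in cache.iterrows()]
    for t in candidates:
        err = float(np.mean([abs(_fraction_at(v, t) - tr)
                             for v, tr in frames]))
        if err < best_err:
            best_t, best_err = t, err
    return float(best_t)


def compare_adaptive_vs_global(grids: Sequence[SlideGrid],
                               truth_spots: pd.DataFrame,
                               configs: Sequence[MarkerConfig],
                               imaging: ImagingSpec,
                               reference_slide: str,
                               modes: Sequence[str] = MODES,
                               ) -> pd.DataFrame:
    """Per-mode mean absolute error of positive-area fraction vs truth.

    Modes: ``global`` (one best-in-hindsight threshold for the cohort),
    ``slide`` (slide-specific thresholds T_R*I_s/I_R), ``spot`` (the
    spot-specific weighted-median equation), ``slide+spot`` (spot
    thresholds with slide fallback for zero-weight windows).  Returns one
    row per mode x marker x slide plus cohort rows (slide_id = "ALL").
    """
    unknown = set(modes) - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes {sorted(unknown)}")
    truth_all = truth_spots[(truth_spots["region"] == "all")
                            & truth_spots["valid"]]
    truth_lut = {(r.slide_id, r.i, r.j, r.marker): r.true_pos_frac
                 for r in truth_all.itertuples()}
    cache = _spot_pixel_cache(grids, imaging, configs)

    summaries = [summarize_slide(g, [c.marker for c in configs],
                                 is_reference=(g.slide_id == reference_slide))
                 for g in grids]
    slide_t = compute_slide_thresholds(summaries, configs)
    tmaps = {g.slide_id: compute_threshold_map(g, summaries, configs,
                                               mode="both")
             for g in grids}

    rows = []
    for cfg in configs:
        sub = cache[cache["marker"] == cfg.marker]
        global_t = _best_global_threshold(
            sub, truth_lut) if "global" in modes else None
        grid_by_id = {g.slide_id: g for g in grids}
        per_mode_errors: dict[str, list[tuple[str, float]]] = {
            m: [] for m in modes}
        for _, row in sub.iterrows():
            key = (row["slide_id"], row["i"], row["j"], cfg.marker)
            tr = truth_lut[key]
            if not np.isfinite(tr):
                continue
            for mode in modes:
                if mode == "global":
                    t = global_t
                elif mode == "slide":
                    t = slide_t[(row["slide_id"], cfg.marker)]
                elif mode == "spot":
                    t = compute_spot_threshold(
                        grid_by_id[row["slide_id"]],
                        (row["i"], row["j"]), cfg)
                else:  # slide+spot
                    t = tmaps[row["slide_id"]].threshold_for(
                        cfg.marker, (row["i"], row["j"]))
                err = abs(_fraction_at(row["sorted_vals"], t) - tr)
                per_mode_errors[mode].append((row["slide_id"], err))
        for mode in modes:
            pairs = per_mode_errors[mode]
            by_slide: dict[str, list[float]] = {}
            for sid, err in pairs:
                by_slide.setdefault(sid, []).append(err)
            for sid, errs in sorted(by_slide.items()):
                rows.append({"mode": mode, "marker": cfg.marker,
                             "slide_id": sid, "n_spots": len(errs),
                             "mae": float(np.mean(errs))})
            rows.append({"mode": mode, "marker": cfg.marker,
                         "slide_id": "ALL",
                         "n_spots": len(pairs),
                         "mae": float(np.mean([e for _, e in pairs]))})
    return pd.DataFrame(rows)


def density_distribution_summary(case_tables: Mapping[str, pd.DataFrame],
                                 value: str = "pct_positive_area",
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group, per-marker distribution summaries of a density measure.

    Returns (summary, distances): quantiles/mean/n per group x marker, and
    two-sample Kolmogorov-Smirnov distances between every pair of groups
    (empty with a single group; reported descriptively, no test decision).
    """
    if not case_tables:
        raise ValueError("at least one group is required")
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    srows, drows = [], []
    for group, df in case_tables.items():
        if df.empty:
            raise ValueError(f"group {group!r} is empty")
        for marker, sub in df.groupby("marker"):
            v = sub[value].dropna().to_numpy(float)
            row = {"group": group, "marker": marker, "n": v.size,
                   "mean": float(v.mean()) if v.size else float("nan")}
            for q in qs:
                row[f"q{int(q * 100):02d}"] = (
                    float(np.quantile(v, q)) if v.size else float("nan"))
            srows.append(row)
    for (g1, d1), (g2, d2) in itertools.combinations(case_tables.items(), 2):
        for marker in sorted(set(d1["marker"]) & set(d2["marker"])):
            v1 = d1.loc[d1["marker"] == marker, value].dropna()
            v2 = d2.loc[d2["marker"] == marker, value].dropna()
            if len(v1) and len(v2):
                ks = stats.ks_2samp(v1, v2)
                drows.append({"group_a": g1, "group_b": g2,
                              "marker": marker,
                              "ks_distance": float(ks.statistic)})
    return pd.DataFrame(srows), pd.DataFrame(drows)
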