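"""Synthetic multi-slide TMA cohorts with known ground truth.

The generator emulates the variation structure that adaptive thresholding is
designed to absorb: multiplicative inter-slide intensity scale factors,
smooth intra-slide intensity gradients, sparse biologically bright "outlier"
spots, variable valid-tissue fractions, and missing boundary spots.  Each
spot is rendered as a small multi-channel image containing a circular tissue
disc with epithelium/stroma sub-regions and non-overlapping disc nuclei;
marker channels place true-positive compartments at a high latent level and
negatives at a low level, then multiply the whole image by
``slide_factor x gradient(i, j)`` and add noise.  Because both distortions
are multiplicative and the positive/negative latent levels are separated by
a wide gap, the spot-threshold equation can invert the distortion exactly in
the noiseless limit — which gives the test suite sharp oracles.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (REGION_EPITHELIUM, REGION_STROMA, ImagingSpec,
                   MarkerConfig, SlideGrid, SpotImage, SpotRecord,
                   populate_spot_summaries)
from .quantify import build_cytoplasm_rings

OFF_TISSUE_LEVEL = 0.05  # optical background outside the tissue disc


@dataclass(frozen=True)
class GradientSpec:
    """Smooth intra-slide multiplicative intensity field.

    ``linear`` ramps geometrically along ``angle_deg`` so that the ratio of
    the brightest to the dimmest grid position equals ``amplitude``;
    ``radial`` ramps from the grid centre outward; ``none`` is flat.  The
    field is normalised to mean 1 over the grid so the slide scale factor
    stays identifiable.
    """

    kind: str = "linear"
    amplitude: float = 3.0
    angle_deg: float = 0.0

    def field(self, n_rows: int, n_cols: int) -> np.ndarray:
        if self.kind == "none" or self.amplitude == 1.0:
            return np.ones((n_rows, n_cols))
        ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols),
                             indexing="ij")
        if self.kind == "linear":
            theta = math.radians(self.angle_deg)
            proj = ii * math.sin(theta) + jj * math.cos(theta)
        elif self.kind == "radial":
            proj = np.hypot(ii - (n_rows - 1) / 2, jj - (n_cols - 1) / 2)
        else:
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        span = proj.max() - proj.min()
        unit = (proj - proj.min()) / span if span > 0 else proj * 0.0
        g = self.amplitude ** unit
        return g / g.mean()


@dataclass(frozen=True)
class NoiseSpec:
    """Additive background noise and multiplicative shot noise."""

    background_sigma: float = 0.02
    shot_cv: float = 0.05

    @property
    def enabled(self) -> bool:
        return self.background_sigma > 0 or self.shot_cv > 0


@dataclass(frozen=True)
class MarkerSim:
    """Latent expression model of one marker channel.

    Negative tissue sits at ``neg_level``, positive compartments at
    ``pos_level`` (arbitrary intensity units, pre-distortion).  The latent
    positivity threshold is their geometric mean.  Per spot, each cell is
    positive with probability drawn from ``pos_frac_range``
    (``outlier_pos_frac_range`` on outlier spots).
    """

    name: str
    compartment: str
    pos_frac_range: tuple[float, float] = (0.02, 0.15)
    outlier_pos_frac_range: tuple[float, float] = (0.30, 0.60)
    neg_level: float = 0.4
    pos_level: float = 3.0
    centre_weighting: bool = False
    virtual_complement: bool = False

    @property
    def latent_threshold(self) -> float:
        return math.sqrt(self.neg_level * self.pos_level)


def default_marker_sims() -> tuple[MarkerSim, ...]:
    return (MarkerSim("CD8", "membranous_cytoplasmic"),
            MarkerSim("CD20", "membranous_cytoplasmic"),
            MarkerSim("FoxP3", "nuclear"),
            MarkerSim("CD68", "membranous_cytoplasmic",
                      centre_weighting=True, virtual_complement=True))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults model a small multi-slide cohort with 4-fold inter-slide scale
    spread, a 3-fold smooth intra-slide ramp, 5% biologically bright spots,
    and occasional missing (mostly boundary) spots.  Spot images are
    rendered at ``image_size_px`` squared — a scaled-down core; real 1.0 mm
    cores at 0.4976 μm/px would be ~2000 px across.
    """

    n_slides: int = 5
    n_rows: int = 10
    n_cols: int = 10
    spot_diameter_mm: float = 1.0
    pixel_size: float = 0.4976
    image_size_px: int = 72
    slide_scale_factors: tuple[float, ...] | None = None  # geomspace(.5,2)
    gradient: GradientSpec = GradientSpec()
    outlier_rate: float = 0.05
    missing_rate: float = 0.02
    boundary_missing: float = 0.25
    invalid_rate: float = 0.02
    tissue_fraction_range: tuple[float, float] = (0.40, 0.70)
    markers: tuple[MarkerSim, ...] = field(default_factory=default_marker_sims)
    noise: NoiseSpec = NoiseSpec()
    nucleus_radius_px: int = 3
    min_nucleus_gap_px: int = 2
    target_cells_per_spot: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "missing_rate", "boundary_missing",
                     "invalid_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_slides < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("cohort must contain at least one spot")
        if self.slide_scale_factors is not None:
            if len(self.slide_scale_factors) != self.n_slides:
                raise ValueError("need one scale factor per slide")
            if any(f <= 0 for f in self.slide_scale_factors):
                raise ValueError("scale factors must be > 0")

    def resolved_scale_factors(self) -> np.ndarray:
        if self.slide_scale_factors is not None:
            return np.asarray(self.slide_scale_factors, dtype=float)
        if self.n_slides == 1:
            return np.ones(1)
        return np.geomspace(0.5, 2.0, self.n_slides)

    def imaging_spec(self) -> ImagingSpec:
        return ImagingSpec(pixel_size=self.pixel_size,
                           channel_names=tuple(m.name for m in self.markers))


@dataclass
class GroundTruth:
    """What the generator knows: per-spot fractions, per-cell calls, fields.

    ``spots`` columns: slide_id, i, j, marker, region, true_pos_frac (area
    fraction of latently positive pixels within tissue∩region),
    true_threshold (latent threshold x applied distortion), latent_mean
    (undistorted all-pixel mean), distortion, slide_factor, gradient,
    outlier, valid.  ``cells`` columns: slide_id, i, j, label, marker,
    positive.
    """

    spots: pd.DataFrame
    cells: pd.DataFrame
    slide_factors: dict[str, float]


@dataclass
class SyntheticCohort:
    grids: list[SlideGrid]
    truth: GroundTruth
    marker_configs: list[MarkerConfig]
    imaging: ImagingSpec
    reference_slide: str


def _throw_nuclei(rng: np.random.Generator, tissue: np.ndarray,
                  radius: int, min_gap: int, target: int) -> np.ndarray:
    """Dart-throwing placement of non-overlapping disc nuclei inside tissue."""
    h, w = tissue.shape
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.ogrid[:h, :w]
    centres: list[tuple[int, int]] = []
    min_d2 = (2 * radius + min_gap) ** 2
    attempts = 30 * target
    for _ in range(attempts):
        if len(centres) >= target:
            break
        ci = int(rng.integers(radius, h - radius))
        cj = int(rng.integers(radius, w - radius))
        if not tissue[ci, cj]:
            continue
        if any((ci - a) ** 2 + (cj - b) ** 2 < min_d2 for a, b in centres):
            continue
        disc = (yy - ci) ** 2 + (xx - cj) ** 2 <= radius ** 2
        if not tissue[disc].all():
            continue
        centres.append((ci, cj))
        labels[disc] = len(centres)
    return labels


def _render_spot(rng: np.random.Generator, spec: CohortSpec,
                 outlier: bool) -> tuple[SpotImage, dict, np.ndarray]:
    """Render one spot's latent (undistorted) image and per-cell truth.

    Returns the SpotImage holding LATENT channels, a per-marker dict of
    (pos_frac per region, latent per-pixel positive masks, cell calls), and
    the per-channel latent positive-pixel masks stacked for reuse.
    """
    size = spec.image_size_px
    f_lo, f_hi = spec.tissue_fraction_range
    frac = rng.uniform(f_lo, f_hi)
    radius = math.sqrt(frac / math.pi) * size
    ci = size / 2 + rng.uniform(-2, 2)
    cj = size / 2 + rng.uniform(-2, 2)
    yy, xx = np.ogrid[:size, :size]
    tissue = (yy - ci) ** 2 + (xx - cj) ** 2 <= radius ** 2
    # epithelium: an off-centre disc inside the tissue; stroma: the rest
    er = radius * rng.uniform(0.35, 0.55)
    ang = rng.uniform(0, 2 * math.pi)
    eci = ci + math.cos(ang) * radius * 0.35
    ecj = cj + math.sin(ang) * radius * 0.35
    epi = ((yy - eci) ** 2 + (xx - ecj) ** 2 <= er ** 2) & tissue
    region = np.zeros((size, size), dtype=np.int32)
    region[tissue] = REGION_STROMA
    region[epi] = REGION_EPITHELIUM
    nuclei = _throw_nuclei(rng, tissue, spec.nucleus_radius_px,
                           spec.min_nucleus_gap_px,
                           spec.target_cells_per_spot)
    rings = build_cytoplasm_rings(
        nuclei, ImagingSpec(pixel_size=spec.pixel_size,
                            channel_names=("x",)),
        radius_um=max(spec.pixel_size, 1.0))
    n_cells = int(nuclei.max())
    channels = np.empty((len(spec.markers), size, size), dtype=np.float64)
    per_marker: dict[str, dict] = {}
    for c, m in enumerate(spec.markers):
        lo, hi = (m.outlier_pos_frac_range if outlier else m.pos_frac_range)
        p = rng.uniform(lo, hi)
        calls = rng.random(n_cells) < p if n_cells else np.zeros(0, bool)
        latent = np.full((size, size), OFF_TISSUE_LEVEL)
        latent[tissue] = m.neg_level
        pos_mask = np.zeros((size, size), dtype=bool)
        pos_labels = np.flatnonzero(calls) + 1
        if pos_labels.size:
            comp = nuclei if m.compartment == "nuclear" else rings
            pos_mask = np.isin(comp, pos_labels) & tissue
            latent[pos_mask] = m.pos_level
        channels[c] = latent
        per_marker[m.name] = {"pos_mask": pos_mask, "calls": calls,
                              "pos_frac": p}
    img = SpotImage(channels=channels,
                    channel_names=tuple(m.name for m in spec.markers),
                    tissue_mask=tissue, region_mask=region,
                    nuclei_labels=nuclei)
    return img, per_marker, tissue


def _region_masks(img: SpotImage) -> dict[str, np.ndarray]:
    return {"all": img.tissue_mask,
            "epithelium": img.tissue_mask
            & (img.region_mask == REGION_EPITHELIUM),
            "stroma": img.tissue_mask & (img.region_mask == REGION_STROMA)}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Deterministic for a fixed ``spec.seed``.  The returned marker configs
    carry factors F calibrated from the cohort's undistorted latent spot
    means (F = latent threshold / median latent mean) and reference
    thresholds matching the reference slide (the slide whose scale factor is
    closest to 1).
    """
    factors = spec.resolved_scale_factors()
    ref_idx = int(np.argmin(np.abs(np.log(factors))))
    imaging = spec.imaging_spec()
    root = np.random.SeedSequence(spec.seed)
    slide_seeds = root.spawn(spec.n_slides)
    grids: list[SlideGrid] = []
    spot_rows: list[dict] = []
    cell_rows: list[dict] = []
    slide_factor_map: dict[str, float] = {}
    latent_means: dict[str, list[float]] = {m.name: [] for m in spec.markers}

    for s in range(spec.n_slides):
        slide_id = f"S{s + 1:02d}"
        slide_factor_map[slide_id] = float(factors[s])
        grad = spec.gradient.field(spec.n_rows, spec.n_cols)
        grid = SlideGrid(slide_id, spec.n_rows, spec.n_cols)
        spot_seeds = iter(slide_seeds[s].spawn(spec.n_rows * spec.n_cols))
        for i in range(spec.n_rows):
            for j in range(spec.n_cols):
                rng = np.random.default_rng(next(spot_seeds))
                on_boundary = (i in (0, spec.n_rows - 1)
                               or j in (0, spec.n_cols - 1))
                p_missing = spec.missing_rate + (
                    spec.boundary_missing if on_boundary else 0.0)
                if rng.random() < p_missing:
                    continue
                valid = rng.random() >= spec.invalid_rate
                outlier = rng.random() < spec.outlier_rate
                img, per_marker, _ = _render_spot(rng, spec, outlier)
                d = float(factors[s] * grad[i, j])
                distorted = img.channels * d
                if spec.noise.enabled:
                    shot = rng.normal(1.0, spec.noise.shot_cv,
                                      distorted.shape)
                    add = rng.normal(0.0, spec.noise.background_sigma,
                                     distorted.shape)
                    distorted = np.clip(distorted * shot + add, 0.0, None)
                regions = _region_masks(img)
                for m in spec.markers:
                    latent_mean = float(img.channels[
                        img.channel_names.index(m.name)].mean())
                    if valid:
                        latent_means[m.name].append(latent_mean)
                    info = per_marker[m.name]
                    for rname, rmask in regions.items():
                        denom = int(np.count_nonzero(rmask))
                        num = int(np.count_nonzero(info["pos_mask"] & rmask))
                        spot_rows.append({
                            "slide_id": slide_id, "i": i, "j": j,
                            "marker": m.name, "region": rname,
                            "true_pos_frac": (num / denom if denom
                                              else float("nan")),
                            "true_threshold": m.latent_threshold * d,
                            "latent_mean": latent_mean, "distortion": d,
                            "slide_factor": float(factors[s]),
                            "gradient": float(grad[i, j]),
                            "outlier": outlier, "valid": valid})
                    for label0, call in enumerate(info["calls"]):
                        cell_rows.append({
                            "slide_id": slide_id, "i": i, "j": j,
                            "label": label0 + 1, "marker": m.name,
                            "positive": bool(call)})
                final = SpotImage(
                    channels=distorted.astype(np.float32),
                    channel_names=img.channel_names,
                    tissue_mask=img.tissue_mask,
                    region_mask=img.region_mask,
                    nuclei_labels=img.nuclei_labels)
                grid.add(SpotRecord(slide_id=slide_id, grid_i=i, grid_j=j,
                                    valid=valid, image_ref=final))
        grids.append(grid)

    configs = []
    ref_factor = float(factors[ref_idx])
    for m in spec.markers:
        med = float(np.median(latent_means[m.name]))
        configs.append(MarkerConfig(
            marker=m.name, channel=m.name, compartment=m.compartment,
            factor_F=m.latent_threshold / med,
            reference_threshold=m.latent_threshold * ref_factor,
            centre_weighting=m.centre_weighting,
            virtual_complement=m.virtual_complement))

    for grid in grids:
        populate_spot_summaries(grid, imaging, configs, domain="all_pixels")

    truth = GroundTruth(spots=pd.DataFrame(spot_rows),
                        cells=pd.DataFrame(cell_rows),
                        slide_factors=slide_factor_map)
    return SyntheticCohort(grids=grids, truth=truth, marker_configs=configs,
                           imaging=imaging,
                           reference_slide=f"S{ref_idx + 1:02d}")


def validation_cohort_spec(seed: int = 1) -> CohortSpec:
    """Study conditions for the pixel-vs-cell cross-validation.

    Larger spots with well-separated nuclei (bigger minimum gap) and a wide
    per-spot positive-fraction range, so both the stromal and the small
    epithelial compartment hold enough positive cells for the rank
    correlation to have dynamic range — the regime in which cell counts and
    positive area measure the same biology.
    """
    markers = tuple(replace(m, pos_frac_range=(0.05, 0.40))
                    for m in default_marker_sims())
    return CohortSpec(seed=seed, image_size_px=96, min_nucleus_gap_px=4,
                      target_cells_per_spot=70, markers=markers)


# ---------------------------------------------------------------------------
# Small deterministic fixtures for threshold unit tests

def generate_worked_grid(kind: str, n: int = 9, base: float = 2.0,
                         slope: float = 0.5, weight: float = 24.0,
                         marker: str = "CD68",
                         slide_id: str = "W01") -> SlideGrid:
    """Small closed-form grids: ``uniform``, ``single_outlier`` (centre spot
    at 100x base), ``ramp`` (I = base*(1 + slope*j)), ``boundary_missing``
    (uniform grid minus its last column)."""
    if kind not in ("uniform", "single_outlier", "ramp", "boundary_missing"):
        raise ValueError(f"unknown worked grid kind {kind!r}")
    grid = SlideGrid(slide_id, n, n)
    centre = (n // 2, n // 2)
    for i in range(n):
        for j in range(n):
            if kind == "boundary_missing" and j == n - 1:
                continue
            value = base
            if kind == "ramp":
                value = base * (1 + slope * j)
            elif kind == "single_outlier" and (i, j) == centre:
                value = base * 100.0
            grid.add(SpotRecord(slide_id=slide_id, grid_i=i, grid_j=j,
                                valid=True,
                                mean_intensity={marker: value},
                                tissue_weight=weight))
    return grid
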