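"""Cytoplasm-ring geometry, positivity calls, pixel/cell quantification
and case-level aggregation."""

import numpy as np
import pandas as pd
import pytest

from tmathresh import (ImagingSpec, MarkerConfig, SpotImage, SpotQuantResult,
                       aggregate_cases, build_cytoplasm_rings,
                       classify_cells, extract_cells, quantify_pixels,
                       quantify_spot)
from tmathresh.core import REGION_EPITHELIUM, REGION_STROMA
from tmathresh.quantify import _derive_densities


def disc_labels(shape, centres, radius, start=1):
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    for k, (ci, cj) in enumerate(centres):
        labels[(yy - ci) ** 2 + (xx - cj) ** 2 <= radius ** 2] = start + k
    return labels


def make_marker(name="CD8", compartment="membranous_cytoplasmic"):
    return MarkerConfig(marker=name, channel=name, compartment=compartment,
                        factor_F=1.0, reference_threshold=1.0)


class TestCytoplasmRings:
    # pixel_size 0.1 μm keeps quantization fine relative to the 1 μm radius
    spec = ImagingSpec(pixel_size=0.1, channel_names=("CD8",))

    def test_isolated_nucleus_gets_annulus_of_ring_width(self):
        nuclei = disc_labels((80, 80), [(40, 40)], radius=15)
        rings = build_cytoplasm_rings(nuclei, self.spec, radius_um=1.0)
        assert set(np.unique(rings)) == {0, 1}
        assert not (rings & (nuclei > 0)).any()
        yy, xx = np.nonzero(rings)
        d = np.hypot(yy - 40, xx - 40)
        assert d.min() > 15  # outside the nucleus
        # within 1 μm (10 px) of the nucleus boundary, +-1 px quantization
        assert d.max() <= 15 + 10 + 1.5

    def test_close_nuclei_split_at_equidistant_line(self):
        # boundary gap 0.6 μm = 6 px: rings meet halfway (3 px each)
        nuclei = disc_labels((60, 120), [(30, 40), (30, 40 + 2 * 15 + 6)],
                             radius=15)
        rings = build_cytoplasm_rings(nuclei, self.spec, radius_um=1.0)
        mid = 40 + 15 + 3  # equidistant column between the two boundaries
        cols1 = np.nonzero(rings == 1)[1]
        cols2 = np.nonzero(rings == 2)[1]
        assert cols1.max() <= mid
        assert cols2.min() >= mid
        # both rings reach the equidistant line (within 1 px)
        assert cols1.max() >= mid - 1
        assert cols2.min() <= mid + 1

    def test_zero_nuclei_zero_cytoplasm(self):
        rings = build_cytoplasm_rings(np.zeros((20, 20), np.int32),
                                      self.spec)
        assert not rings.any()

    def test_rings_disjoint_and_exclude_nuclei(self):
        rng = np.random.default_rng(0)
        centres = [(int(rng.integers(10, 50)), int(rng.integers(10, 50)))
                   for _ in range(6)]
        nuclei = disc_labels((60, 60), centres, radius=4)
        rings = build_cytoplasm_rings(nuclei, self.spec, radius_um=1.0)
        assert not ((rings > 0) & (nuclei > 0)).any()


def two_cell_image(nuc_vals=(10.0, 2.0), cyt_vals=(1.0, 9.0)):
    """Two well-separated cells with prescribed compartment intensities."""
    spec = ImagingSpec(pixel_size=0.5, channel_names=("CD8",))
    nuclei = disc_labels((40, 80), [(20, 20), (20, 60)], radius=5)
    rings = build_cytoplasm_rings(nuclei, spec, radius_um=1.0)
    ch = np.zeros((1, 40, 80))
    for k in (1, 2):
        ch[0][nuclei == k] = nuc_vals[k - 1]
        ch[0][rings == k] = cyt_vals[k - 1]
    region = np.zeros((40, 80), np.int32)
    region[:, :40] = REGION_EPITHELIUM
    region[:, 40:] = REGION_STROMA
    img = SpotImage(channels=ch, channel_names=("CD8",),
                    tissue_mask=np.ones((40, 80), bool),
                    region_mask=region, nuclei_labels=nuclei)
    return img, spec


class TestClassifyCells:
    def test_nuclear_marker_thresholds_on_nucleus_mean(self):
        img, spec = two_cell_image()
        m = make_marker(compartment="nuclear")
        cells = extract_cells(img, [m], spec)
        assert classify_cells(cells, m, threshold=8.0) == [True, False]
        assert classify_cells(cells, m, threshold=12.0) == [False, False]

    def test_membranous_marker_routes_to_cytoplasm(self):
        # bright nucleus / dark cytoplasm with the threshold in between:
        # a membranous marker must call the cell negative
        img, spec = two_cell_image(nuc_vals=(10.0, 2.0),
                                   cyt_vals=(1.0, 9.0))
        m = make_marker(compartment="membranous_cytoplasmic")
        cells = extract_cells(img, [m], spec)
        assert classify_cells(cells, m, threshold=5.0) == [False, True]

    def test_cell_region_assignment(self):
        img, spec = two_cell_image()
        cells = extract_cells(img, [make_marker()], spec)
        assert [c.region for c in cells] == ["epithelium", "stroma"]

    def test_monotonicity_in_threshold(self):
        img, spec = two_cell_image()
        m = make_marker(compartment="nuclear")
        cells = extract_cells(img, [m], spec)
        counts = [sum(classify_cells(cells, m, t))
                  for t in (1.0, 3.0, 9.0, 11.0)]
        assert counts == sorted(counts, reverse=True)


class TestQuantifyPixels:
    spec = ImagingSpec(pixel_size=1.0, channel_names=("CD8",))

    def test_fraction_above_threshold(self):
        ch = np.zeros((1, 10, 10))
        ch[0].ravel()[:30] = 5.0
        img = SpotImage(channels=ch, channel_names=("CD8",),
                        tissue_mask=np.ones((10, 10), bool))
        pos, tot = quantify_pixels(img, make_marker(), 2.0, "all", self.spec)
        assert (pos, tot) == (30.0, 100.0)

    def test_threshold_above_max_gives_zero(self):
        ch = np.full((1, 8, 8), 3.0)
        img = SpotImage(channels=ch, channel_names=("CD8",),
                        tissue_mask=np.ones((8, 8), bool))
        pos, _ = quantify_pixels(img, make_marker(), 100.0, "all", self.spec)
        assert pos == 0.0

    def test_random_image_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        ch = rng.uniform(0, 10, (1, 16, 16))
        tissue = rng.random((16, 16)) < 0.7
        region = np.where(rng.random((16, 16)) < 0.5, REGION_STROMA,
                          REGION_EPITHELIUM)
        img = SpotImage(channels=ch, channel_names=("CD8",),
                        tissue_mask=tissue, region_mask=region)
        t = 4.5
        n_pos = n_tot = 0
        for i in range(16):
            for j in range(16):
                if tissue[i, j] and region[i, j] == REGION_STROMA:
                    n_tot += 1
                    if ch[0, i, j] >= t:
                        n_pos += 1
        pos, tot = quantify_pixels(img, make_marker(), t, "stroma",
                                   self.spec)
        assert (pos, tot) == (float(n_pos), float(n_tot))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        ch = rng.uniform(0, 10, (1, 16, 16))
        img = SpotImage(channels=ch, channel_names=("CD8",),
                        tissue_mask=np.ones((16, 16), bool))
        areas = [quantify_pixels(img, make_marker(), t, "all", self.spec)[0]
                 for t in (1.0, 3.0, 6.0, 9.0)]
        assert areas == sorted(areas, reverse=True)


class TestQuantifySpot:
    def test_planted_positives_recovered(self):
        img, spec = two_cell_image()
        m = make_marker(compartment="nuclear")
        # 9.5 sits above cell 2's bright cytoplasm (9.0) so the only
        # positive pixels are cell 1's nucleus (10.0)
        res = quantify_spot(img, ("s1", 0, 0), {"CD8": 9.5}, [m], spec)
        by_region = {r.region: r for r in res}
        assert by_region["all"].n_cells_total == 2
        assert by_region["all"].n_cells_positive == 1
        assert by_region["epithelium"].n_cells_positive == 1
        assert by_region["stroma"].n_cells_positive == 0
        # positive area = the bright nucleus' pixels
        nuc1_px = int((img.nuclei_labels == 1).sum())
        assert by_region["all"].area_positive_um2 == \
            pytest.approx(nuc1_px * spec.pixel_area_um2)

    def test_empty_region_flagged_with_nan_densities(self):
        img, spec = two_cell_image()
        img.region_mask[:] = REGION_EPITHELIUM
        cells = extract_cells(img, [make_marker()], spec)
        for c in cells:
            c.region = "epithelium"
        res = quantify_spot(img, ("s1", 0, 0), {"CD8": 8.0},
                            [make_marker()], spec, cells=cells)
        stroma = next(r for r in res if r.region == "stroma")
        assert stroma.area_total_um2 == 0.0
        assert np.isnan(stroma.density_cells_per_mm2)
        assert np.isnan(stroma.pct_positive_area)

    def test_all_negative_spot(self):
        img, spec = two_cell_image()
        res = quantify_spot(img, ("s1", 0, 0), {"CD8": 1e6},
                            [make_marker()], spec)
        assert all(r.n_cells_positive == 0 and r.area_positive_um2 == 0.0
                   for r in res)

    def test_missing_threshold_names_marker(self):
        img, spec = two_cell_image()
        with pytest.raises(KeyError, match="CD8.*s1"):
            quantify_spot(img, ("s1", 0, 0), {}, [make_marker()], spec)


def result(slide="s1", i=0, j=0, n_pos=10, area_mm2=1.0, region="all",
           marker="CD8"):
    return _derive_densities(SpotQuantResult(
        slide_id=slide, i=i, j=j, region=region, marker=marker,
        n_cells_total=n_pos * 2, n_cells_positive=n_pos,
        area_total_um2=area_mm2 * 1e6, area_positive_um2=area_mm2 * 1e5))


class TestAggregateCases:
    def test_sum_then_divide_not_mean_of_ratios(self):
        res = [result(i=0, n_pos=10, area_mm2=1.0),
               result(i=1, n_pos=20, area_mm2=1.0)]
        agg = aggregate_cases(res, {("s1", 0, 0): "P1", ("s1", 1, 0): "P1"})
        row = agg.iloc[0]
        assert row["n_cells_positive"] == 30
        assert row["area_total_um2"] == pytest.approx(2e6)
        assert row["density_cells_per_mm2"] == pytest.approx(15.0)

    def test_single_spot_case_identical_to_spot(self):
        r = result()
        agg = aggregate_cases([r], {("s1", 0, 0): "P1"})
        row = agg.iloc[0]
        assert row["density_cells_per_mm2"] == \
            pytest.approx(r.density_cells_per_mm2)
        assert row["pct_positive_area"] == pytest.approx(r.pct_positive_area)

    def test_area_conservation_is_exact(self):
        rng = np.random.default_rng(2)
        res = [result(i=i, n_pos=int(rng.integers(0, 30)),
                      area_mm2=float(rng.uniform(0.1, 2.0)))
               for i in range(10)]
        cmap = {("s1", i, 0): f"P{i % 3}" for i in range(10)}
        agg = aggregate_cases(res, cmap)
        assert agg["area_total_um2"].sum() == \
            sum(r.area_total_um2 for r in res)
        assert agg["n_cells_positive"].sum() == \
            sum(r.n_cells_positive for r in res)

    def test_unmapped_spot_errors(self):
        with pytest.raises(KeyError, match="not mapped"):
            aggregate_cases([result()], {})

    def test_dataframe_input_and_empty(self):
        df = pd.DataFrame([vars(result())])
        agg = aggregate_cases(df, {("s1", 0, 0): "P1"})
        assert len(agg) == 1
        assert aggregate_cases(pd.DataFrame(), {}).empty


class TestPixelCellAgreement:
    def test_counts_times_cell_area_tracks_positive_area(self):
        """On well-separated uniform-intensity cells, positive-cell count x
        mean cell area approximates the positive pixel area (<15% rel)."""
        spec = ImagingSpec(pixel_size=0.5, channel_names=("CD8",))
        centres = [(10 + 12 * a, 10 + 12 * b)
                   for a in range(4) for b in range(4)]
        nuclei = disc_labels((60, 60), centres, radius=3)
        rings = build_cytoplasm_rings(nuclei, spec, radius_um=1.0)
        ch = np.zeros((1, 60, 60))
        positive = list(range(1, 8))  # first 7 of 16 cells
        for k in positive:
            ch[0][(nuclei == k) | (rings == k)] = 10.0
        img = SpotImage(channels=ch, channel_names=("CD8",),
                        tissue_mask=np.ones((60, 60), bool),
                        nuclei_labels=nuclei)
        m = make_marker()
        res = quantify_spot(img, ("s1", 0, 0), {"CD8": 5.0}, [m], spec,
                            regions=("all",))
        (r,) = res
        cell_px = (nuclei > 0).sum() + (rings > 0).sum()
        mean_cell_area = cell_px / 16 * spec.pixel_area_um2
        approx = r.n_cells_positive * mean_cell_area
        assert r.n_cells_positive == 7
        assert abs(approx - r.area_positive_um2) / r.area_positive_um2 < 0.15
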