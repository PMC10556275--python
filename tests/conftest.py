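"""Shared fixtures: session-scoped synthetic cohorts and quantification.

Cohort generation and full-cohort quantification are the slow steps, so
they are generated once per session and reused by unit, property and
acceptance tests alike.
"""

from __future__ import annotations

import pandas as pd
import pytest

from tmathresh import (CohortSpec, NoiseSpec, SyntheticCohort,
                       compute_threshold_map, generate_cohort,
                       quantify_spot, summarize_slide)
from tmathresh.synthetic import validation_cohort_spec


def quantify_cohort(cohort: SyntheticCohort, mode: str = "both",
                    ) -> pd.DataFrame:
    """Threshold and quantify every valid spot of a synthetic cohort."""
    markers = [m.marker for m in cohort.marker_configs]
    summaries = [summarize_slide(
        g, markers, is_reference=(g.slide_id == cohort.reference_slide))
        for g in cohort.grids]
    results = []
    for grid in cohort.grids:
        tmap = compute_threshold_map(grid, summaries,
                                     cohort.marker_configs, mode=mode)
        for spot in grid.valid_spots():
            results.extend(quantify_spot(
                spot.image_ref, (grid.slide_id, spot.grid_i, spot.grid_j),
                tmap, cohort.marker_configs, cohort.imaging))
    return pd.DataFrame([vars(r) for r in results])


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    """3-slide 6x6 cohort with default noise — quick shared input."""
    return generate_cohort(CohortSpec(n_slides=3, n_rows=6, n_cols=6,
                                      image_size_px=56,
                                      target_cells_per_spot=30, seed=11))


@pytest.fixture(scope="session")
def default_cohort() -> SyntheticCohort:
    """The parameter-recovery study conditions (5 slides, 10x10, noise on)."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort() -> SyntheticCohort:
    """Same conditions with noise disabled (sharp-oracle limit)."""
    return generate_cohort(CohortSpec(seed=7, noise=NoiseSpec(0.0, 0.0)))


@pytest.fixture(scope="session")
def validation_cohort() -> SyntheticCohort:
    """Well-separated-cells cohort for pixel-vs-cell cross-validation."""
    return generate_cohort(validation_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def validation_results(validation_cohort) -> pd.DataFrame:
    return quantify_cohort(validation_cohort)
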