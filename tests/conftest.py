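"""Shared fixtures: analytic shapes, random masks, and a cached cohort."""

from __future__ import annotations

import numpy as np
import pytest

from nucmorph.geometry import extract_contour
from nucmorph.pipeline import RunConfig, score_items
from nucmorph.synthetic import CohortSpec, generate_cohort


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    """Solid digital disk: pixels within ``radius`` of the center."""
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[:size, :size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def random_blob(seed: int, size: int = 64) -> np.ndarray:
    """Random single-component blob mask (threshold of smoothed noise)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=(size, size)), 6)
    mask = field > np.quantile(field, 0.75)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


@pytest.fixture(scope="session")
def disk20():
    return disk_mask(20)


@pytest.fixture(scope="session")
def disk20_contour(disk20):
    return extract_contour(disk20)


@pytest.fixture(scope="session")
def cohort_small():
    """Default-parameter cohort, 30 per class, cached for the session."""
    items, manifest = generate_cohort(CohortSpec(n_per_class=30, master_seed=7))
    return items, manifest


@pytest.fixture(scope="session")
def cohort_scores_small(cohort_small):
    items, _ = cohort_small
    return score_items(items, RunConfig())
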