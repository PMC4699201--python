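"""Shared fixtures: the default phantom study and its reconstruction.

The expensive artifacts (sliced study, end-to-end reconstruction) are built
once per session and shared by the unit, property and acceptance tests.
"""

import numpy as np
import pytest

from lheart.phantom import PhantomSpec, slice_study
from lheart.pipeline import PipelineConfig, reconstruct


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def study(spec):
    """(contours, metas) of the default unperturbed phantom."""
    return slice_study(spec)


@pytest.fixture(scope="session")
def clouds(study):
    from lheart.contours_io import project_study_to_clouds

    contours, metas = study
    return project_study_to_clouds(contours, metas)


@pytest.fixture(scope="session")
def default_result(study):
    """End-to-end reconstruction of the default phantom, default config."""
    contours, metas = study
    return reconstruct(contours, metas, PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_simple_polygon(rng, n=12, r_lo=0.5, r_hi=1.5):
    """Random star-shaped polygon about the origin, re-drawn until simple
    (near-duplicate angles can numerically self-intersect)."""
    from shapely.geometry import Polygon

    while True:
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radii = rng.uniform(r_lo, r_hi, n)
        pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        if np.min(np.diff(angles)) > 0.05 and Polygon(pts).is_valid:
            return pts
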