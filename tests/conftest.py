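"""Shared fixtures: default phantoms, contours and segment maps.

Session-scoped where construction is non-trivial; all stochastic fixtures
are explicitly seeded so the suite is fully deterministic.
"""

import pytest

import cardiomap as cm
from cardiomap.segmentation import (
    build_segments,
    contours_from_phantom,
    exclude_inner_rim,
    split_transmural,
)


@pytest.fixture(scope="session")
def geometry():
    return cm.GeometryConfig()


@pytest.fixture(scope="session")
def healthy_phantom(geometry):
    return cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM)


@pytest.fixture(scope="session")
def iron_phantom(geometry):
    """Phantom with one transmural iron/RBC wedge and one inflammatory wedge."""
    lesions = (
        cm.Lesion(shape="wedge", angle_deg=15.0, span_deg=90.0,
                  iron_concentration=1.0, infiltration_level=0.5,
                  edema_level=0.3, fibrosis_level=0.2),
        cm.Lesion(shape="wedge", angle_deg=200.0, span_deg=70.0,
                  edema_level=0.6, infiltration_level=0.5),
    )
    return cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM,
                              cm.PathologyConfig(lesions=lesions))


@pytest.fixture(scope="session")
def contours(healthy_phantom):
    return contours_from_phantom(healthy_phantom)


@pytest.fixture(scope="session")
def labelmap6(contours, healthy_phantom):
    return build_segments(contours, "mid", healthy_phantom.shape)


@pytest.fixture(scope="session")
def labelmap12(labelmap6, contours):
    rimless = exclude_inner_rim(labelmap6, contours, 0.05)
    return split_transmural(rimless, contours)
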