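import numpy as np
import pytest
from hypothesis import settings

import gigaslide as gs
from gigaslide.synthetic import TissueSpec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def gradient_plane(fixture_dir):
    """1000x800 RGB gradient plane, 256x256 tiles, deflate. Content is a pure
    per-pixel function of coordinates (the analytic oracle)."""
    path = fixture_dir / "gradient.tif"
    container = gs.generate_tiled_plane(
        path, 1000, 800, pattern="gradient", magnification=40, focus_offset=0
    )
    yield container
    container.close()


@pytest.fixture(scope="session")
def gradient_full(gradient_plane):
    """The same plane fully decoded (small enough), for naive-slice oracles."""
    plane = gradient_plane.planes[0]
    return gs.extract_region(plane, gs.Region(0, 0, plane.width, plane.height))


@pytest.fixture(scope="session")
def checkerboard_plane(fixture_dir):
    path = fixture_dir / "checkerboard.tif"
    container = gs.generate_tiled_plane(path, 1024, 768, pattern="checkerboard")
    yield container
    container.close()


@pytest.fixture(scope="session")
def pyramid_container(fixture_dir):
    """5 magnifications x 11 focus offsets = 55 planes."""
    path = fixture_dir / "pyramid.tif"
    container = gs.generate_pyramid(
        path, 512, 384, [40, 20, 10, 5, 2.5], list(range(-5, 6))
    )
    yield container
    container.close()


@pytest.fixture(scope="session")
def tissue_small(fixture_dir):
    """4000x3000 tissue plane with 250 ground-truth nuclei."""
    spec = TissueSpec(width=4000, height=3000, n_nuclei=250, seed=7)
    path = fixture_dir / "tissue_small.tif"
    container, truth = gs.generate_tissue(spec, path)
    yield spec, container, truth
    container.close()


DETECT = dict(threshold=145, min_area=20, max_area=2000)


@pytest.fixture(scope="session")
def detect_params():
    """Detection settings matched to the tissue fixtures: the threshold sits
    midway between nucleus (60) and background (230) luminosity, and the area
    window brackets disks of radius 5-14 px."""
    return dict(DETECT)
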