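import numpy as np
import pytest

import ribeyegrade as rg

PANEL_SEED = 123


@pytest.fixture
def cal100() -> rg.ScaleCalibration:
    """A clean 100 px/cm calibration from an axis-aligned 5 cm reference."""
    return rg.calibrate_scale((0, 0), (500, 0), 5.0)


@pytest.fixture
def cal20() -> rg.ScaleCalibration:
    return rg.calibrate_scale((0, 0), (100, 0), 5.0)


@pytest.fixture
def table() -> rg.GradingTable:
    return rg.default_grading_table()


def make_image(pixels: np.ndarray) -> rg.RGBImage:
    return rg.RGBImage(pixels=np.asarray(pixels, dtype=np.uint8))


def constant_image(h: int, w: int, rgb) -> rg.RGBImage:
    px = np.empty((h, w, 3), dtype=np.uint8)
    px[:] = rgb
    return make_image(px)


@pytest.fixture(scope="session")
def grade_panel():
    """Fixed-seed 30-sample panel, 6 per grade, shared across tests."""
    return rg.generate_grade_panel(6, seed=PANEL_SEED)


@pytest.fixture(scope="session")
def panel_results(grade_panel):
    """Pipeline output for every panel sample, computed once."""
    return [
        (truth, rg.analyze_sample(ci, sample_id=f"syn{i:03d}"))
        for i, (ci, truth) in enumerate(grade_panel)
    ]
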