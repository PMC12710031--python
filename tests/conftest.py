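import numpy as np
import pytest

from aircolor import load_reference_chart, render_chart_template


@pytest.fixture(scope="session")
def chart():
    return load_reference_chart("classic-srgb-d65")


@pytest.fixture(scope="session")
def template(chart):
    return render_chart_template(chart)


@pytest.fixture(scope="session")
def layout_corners(chart):
    return np.array(chart.corner_coords)
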