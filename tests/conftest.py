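import numpy as np
import pytest

from petalspectrum.outlines import Outline
from petalspectrum.simulate import FlowerParams, gen_front_outline, gen_side_outline


def circle_points(radius=1.0, n=256, start_angle=0.0):
    th = start_angle + 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(th), radius * np.sin(th)])


def mirror_gap(points, axis="y"):
    """Max vertex distance between a closed CCW polyline and its mirror image.

    The mirrored point sequence is reversed (to restore CCW) and cyclically
    rolled to the best-matching start before comparing.
    """
    flip = np.array([-1.0, 1.0]) if axis == "y" else np.array([1.0, -1.0])
    mir = (points * flip)[::-1]
    shift = int(np.argmin(np.linalg.norm(mir - points[0], axis=1)))
    mir = np.roll(mir, -shift, axis=0)
    return float(np.abs(mir - points).max())


@pytest.fixture
def circle_outline():
    return Outline("circle", "circle", "front", circle_points(radius=2.0, n=512))


@pytest.fixture
def front_flower():
    return gen_front_outline(
        FlowerParams(petal_count=5, lobe_depth=0.3, dorsoventral_gradient=0.3)
    )


@pytest.fixture
def side_flower():
    return gen_side_outline(FlowerParams(view="side", tube_length=2.0))
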