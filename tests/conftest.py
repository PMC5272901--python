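import numpy as np
import pytest

from hiersim.shapes import Sphere, Spheroid, Tube


@pytest.fixture
def rng():
    return np.random.default_rng(20160607)


def random_sphere(rng, center_scale=3.0):
    return Sphere(rng.uniform(-center_scale, center_scale, 3),
                  float(rng.uniform(0.3, 2.0)))


def random_tube(rng, center_scale=3.0):
    c = rng.uniform(-center_scale, center_scale, 3)
    ax = rng.normal(size=3)
    ax /= np.linalg.norm(ax)
    half = rng.uniform(0.2, 2.0)
    return Tube(c - half * ax, c + half * ax, float(rng.uniform(0.3, 1.5)))


def random_spheroid(rng, center_scale=3.0, lo=0.5, hi=3.0):
    ax = rng.normal(size=3)
    ax /= np.linalg.norm(ax)
    a, b = rng.uniform(lo, hi, 2)
    return Spheroid(rng.uniform(-center_scale, center_scale, 3), ax,
                    float(a), float(b))


def random_shape(rng, kind=None, center_scale=3.0):
    if kind is None:
        kind = rng.choice(["sphere", "tube", "spheroid"])
    if kind == "sphere":
        return random_sphere(rng, center_scale)
    if kind == "tube":
        return random_tube(rng, center_scale)
    return random_spheroid(rng, center_scale)
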