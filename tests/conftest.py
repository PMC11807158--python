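import numpy as np
import pytest

from pathaware.phantom import (FovealDip, LesionSpec, Noise, PhantomSpec,
                               Undulation, make_bscan)

SMALL_W, SMALL_H = 320, 160


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced-resolution phantom used across the suite."""

    return PhantomSpec(width=SMALL_W, height=SMALL_H, seed=11)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noise-free variant for exact-rendering checks."""

    return PhantomSpec(width=SMALL_W, height=SMALL_H, seed=11,
                       noise=Noise(speckle_looks=None, gaussian_sigma=0.0))


@pytest.fixture(scope="session")
def flat_spec() -> PhantomSpec:
    """No undulation, no dip: boundaries are horizontal lines."""

    return PhantomSpec(width=SMALL_W, height=SMALL_H, seed=0,
                       base_depths=(40, 70, 90, 100, 110, 120),
                       undulation=Undulation(amplitude=0.0,
                                             thickness_amplitude=0.0),
                       foveal_dip=FovealDip(depth=0.0),
                       noise=Noise(speckle_looks=None, gaussian_sigma=0.0))


@pytest.fixture(scope="session")
def healthy_scan(small_spec):
    image, sub, total, box = make_bscan(small_spec)
    assert box is None
    return image, sub, total


@pytest.fixture(scope="session")
def diseased_scan(small_spec):
    lesion = LesionSpec(column_spans=((100, 180),),
                        absent_layers=("PR-IS", "PR-OS"), severity=1.0)
    return make_bscan(small_spec, lesion)


@pytest.fixture(scope="session")
def directional_experiment():
    """The frozen standard-vs-pathology-aware comparison (trains models)."""

    from pathaware import study

    return study.run_directional_experiment(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_probs(rng, shape, n_classes):
    """Random probability map of the given spatial shape."""

    raw = rng.gamma(1.0, 1.0, size=(*shape, n_classes))
    return raw / raw.sum(axis=-1, keepdims=True)
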