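import numpy as np
import pytest
from hypothesis import settings

import debriscope as dsc

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def study_scene_spec(seed: int = 0, **overrides) -> dsc.SceneSpec:
    """Scene conditions used for the closure studies: 200 particles of at
    least 2 μm (the reliably observable regime), 20% aggregated, three
    field-spanning fibers."""
    kw = dict(
        n_particles=200,
        size_distribution=dsc.SizeDistribution(
            median_um=3.0, sigma_log=0.5, min_um=2.0, max_um=20.0
        ),
        aggregate_fraction=0.2,
        n_fibers=3,
        fiber_diameters_um=(4.0, 6.0, 10.0),
        stained_fraction=0.05,
        seed=seed,
    )
    kw.update(overrides)
    if kw["n_fibers"] != 3 and "fiber_diameters_um" not in overrides:
        kw["fiber_diameters_um"] = None
    return dsc.SceneSpec(**kw)


@pytest.fixture(scope="session")
def default_scene() -> dsc.GroundTruthScene:
    """One generator-defaults scene shared by read-only tests."""
    return dsc.generate_scene(dsc.SceneSpec(seed=1))


@pytest.fixture(scope="session")
def trained_classifier(default_scene):
    """A forest trained on the shared default scene."""
    feats = dsc.compute_features(default_scene.dic_image.data)
    scribbles = dsc.sample_scribbles(default_scene.class_map, seed=1)
    clf = dsc.train_classifier(feats, scribbles, n_trees=200, seed=1)
    return clf, feats, scribbles


@pytest.fixture()
def dic_acq() -> dsc.AcquisitionSpec:
    return dsc.AcquisitionSpec.dic()


def make_disk(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
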