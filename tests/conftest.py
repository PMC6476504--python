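import numpy as np
import pytest

import vinepest as vp


@pytest.fixture(scope="session")
def small_scene() -> vp.SyntheticScene:
    """Desk-top scene for unit tests: 15 x 15 m at 3 cm GSD, sparse cloud."""
    params = vp.SceneParams(
        extent=(15.0, 15.0), gsd=0.03, point_density=300.0, seed=7
    )
    return vp.generate_scene(params)


@pytest.fixture(scope="session")
def default_scene() -> vp.SyntheticScene:
    """The reference study conditions: 50 x 50 m, 1.5 cm GSD,
    1,536 pts/m2, seed 42."""
    return vp.generate_scene(vp.SceneParams())


@pytest.fixture(scope="session")
def default_scene_classified(default_scene) -> vp.PointCloud:
    """Ground-filtered default scene cloud (truth labels stripped first)."""
    bare = vp.PointCloud(default_scene.cloud.xyz)
    return vp.classify_ground(bare, vp.GroundFilterParams())


@pytest.fixture(scope="session")
def pipeline_report(default_scene, default_scene_classified) -> dict:
    """Both analysis arms on the default scene (shared across tests)."""
    config = vp.config_for_scene(default_scene, seed=1)
    return vp.run_all(
        default_scene.ortho,
        default_scene.cloud,
        default_scene.truth_affected_mask,
        config,
        truth_veg=default_scene.truth_veg_mask,
        scene=default_scene,
        classified_cloud=default_scene_classified,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def unit_grid() -> vp.GridSpec:
    """64 x 64 grid, 0.5 m pixels, origin at (100, 200)."""
    return vp.GridSpec(origin_x=100.0, origin_y=200.0, pixel_size=0.5,
                       n_rows=64, n_cols=64)
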