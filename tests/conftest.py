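import numpy as np
import pytest

from spectroclust.synthetic_scene import SceneConfig, generate_scene, preset_config


@pytest.fixture(scope="session")
def small_scene():
    """Compact 4-cluster scene (well separated) for structural tests."""
    cfg = preset_config("four-cluster-separated", seed=11).replace(
        n_per_cluster=(60, 60, 60, 60)
    )
    return generate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_csv(tmp_path):
    """3-sample wide CSV with two wavelength columns."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "id,lon,lat,soc,400,410\n"
        "a,1.0,40.0,12.0,0.5,0.6\n"
        "b,2.0,41.0,25.0,0.4,0.5\n"
        "c,3.0,42.0,8.0,0.6,0.7\n"
    )
    return path
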