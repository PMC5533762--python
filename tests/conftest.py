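import numpy as np
import pandas as pd
import pytest

from canopylidar.point_cloud import GROUND, VEGETATION, PointCloud
from canopylidar.synthetic import ScanConfig, SyntheticStandConfig, uniform_slab_cloud


@pytest.fixture
def tiny_table(tmp_path):
    """3-point CSV: one 2-return pulse plus one single-return ground pulse."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "x,y,z,return_number,number_of_returns,pulse_id,point_class\n"
        "1.0,2.0,105.0,1,2,p1,vegetation\n"
        "1.0,2.0,101.0,2,2,p1,ground\n"
        "3.0,4.0,100.0,1,1,p2,ground\n"
    )
    return path


@pytest.fixture
def flat_ground_cloud():
    """Dense ground-classified points at z=100 on a 10x10 m grid."""
    xs, ys = np.meshgrid(np.linspace(0, 10, 21), np.linspace(0, 10, 21))
    n = xs.size
    df = pd.DataFrame(
        {
            "x": xs.ravel(),
            "y": ys.ravel(),
            "z": np.full(n, 100.0),
            "return_number": 1,
            "number_of_returns": 1,
            "pulse_id": np.arange(n),
            "point_class": GROUND,
        }
    )
    return PointCloud(df)


@pytest.fixture
def two_slab_cloud():
    """Two vertically separated uniform slabs: 18-25 m (dense) and 5-10 m."""
    return uniform_slab_cloud([(18.0, 25.0, 3000), (5.0, 10.0, 1200)], radius=10.0, seed=7)


@pytest.fixture
def occluded_stand_config():
    """Two-layer stand with enough vertical separation to stratify."""
    return SyntheticStandConfig(
        plot_radius=10.0,
        n_layers=2,
        trees_per_layer=[8, 8],
        layer_height_ranges=[(18.0, 25.0), (6.0, 10.0)],
        crown_base_frac_range=(0.6, 0.75),
        seed=0,
    )


@pytest.fixture
def default_scan_config():
    return ScanConfig(pulse_density=25.0, seed=0)


def make_cloud(x, y, z, pulse=None, point_class=VEGETATION, height_mode="above_ground", area=None):
    n = len(x)
    df = pd.DataFrame(
        {
            "x": np.asarray(x, float),
            "y": np.asarray(y, float),
            "z": np.asarray(z, float),
            "return_number": 1,
            "number_of_returns": 1,
            "pulse_id": np.arange(n) if pulse is None else pulse,
            "point_class": point_class,
        }
    )
    return PointCloud(df, height_mode=height_mode, area=area)
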