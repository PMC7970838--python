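import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from driftquant.flowfield import FlowField

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_field(u_fn=None, v_fn=None, *, lon=(-1.0, 2.0, 0.1), lat=(-1.0, 1.0, 0.1),
               n_days=3, start="2017-03-15", max_speed=1.0, land_mask=None):
    """Small analytic flow field on an equatorial grid for advection tests."""
    lon_ax = np.arange(lon[0], lon[1] + lon[2] / 2, lon[2])
    lat_ax = np.arange(lat[0], lat[1] + lat[2] / 2, lat[2])
    depth = np.array([0.0, 50.0])
    time = pd.date_range(start, periods=n_days, freq="D")
    lon_g, lat_g = np.meshgrid(lon_ax, lat_ax)
    u2 = u_fn(lon_g, lat_g) if u_fn else np.zeros_like(lon_g)
    v2 = v_fn(lon_g, lat_g) if v_fn else np.zeros_like(lon_g)
    shape = (n_days, depth.size, lat_ax.size, lon_ax.size)
    return FlowField(
        lon=lon_ax, lat=lat_ax, depth=depth, time=time.values,
        u=np.broadcast_to(u2, shape).copy(), v=np.broadcast_to(v2, shape).copy(),
        land_mask=land_mask, max_speed=max_speed,
    )


@pytest.fixture(scope="session")
def jet_field():
    """Idealised northward coastal jet used across drift tests."""
    from driftquant.synthetic import gen_flow_field

    return gen_flow_field(n_days=70, eddy_amplitude=0.1, seed=3)
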