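import numpy as np
import pytest

from coartsim import (CoarticulationSpec, MotorPrimitive, PrimitiveLibrary,
                      Timeline, default_config, make_primitive_library)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def lib(cfg):
    return make_primitive_library(cfg, seed=7)


def constant_primitive(name, role, duration, mean, var, n_channels=1):
    mean_vec = np.full(n_channels, float(mean))
    var_vec = np.full(n_channels, float(var))
    return MotorPrimitive(name=name, role=role, duration_ms=duration,
                          mean_fn=lambda t: mean_vec.copy(),
                          var_fn=lambda t: var_vec.copy())


@pytest.fixture
def make_lib_1d():
    """Factory for a 1-channel library: constant proximal m1 and distal m2."""

    def _make(m1, v1, m2, v2):
        prims = {
            "p": constant_primitive("p", "proximal", 1000.0, m1, v1),
            "d": constant_primitive("d", "distal", 500.0, m2, v2),
        }
        channel_map = {"index": [0], "thumb": [], "wrist": [], "other": []}
        return PrimitiveLibrary(primitives=prims, channel_map=channel_map,
                                dt_ms=10.0, timeline=Timeline(1000.0, 1500.0))

    return _make


@pytest.fixture
def spec_1d():
    """Coarticulation spec blending 'p' with 'd' on the single channel."""

    def _make(w=1.0, max_tries=10000):
        return CoarticulationSpec(primary="p", future=("d",),
                                  weights={"p": 1.0, "d": w},
                                  window_ms=(0.0, 1000.0),
                                  dof_channels=np.array([0]),
                                  max_tries=max_tries)

    return _make
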