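import numpy as np
import pytest

import hemoflow as hf


@pytest.fixture(scope="session")
def default_spec():
    return hf.StenosisSpec()


@pytest.fixture(scope="session")
def default_geometry(default_spec):
    return hf.build_geometry(default_spec, n_axial=384)


@pytest.fixture(scope="session")
def poiseuille_flow():
    """Exact analytic Poiseuille tube field at the standard operating point."""
    return hf.poiseuille_fixture(D=0.003, Q=0.83e-6, mu=0.0035)


def make_wall(ess, s=None, area=None, segment=None):
    """Construct a WallField directly from a signed ESS series array."""
    ess = np.atleast_2d(np.asarray(ess, dtype=float))
    nt, n = ess.shape
    s = np.arange(n, dtype=float) if s is None else np.asarray(s, dtype=float)
    area = np.ones(n) if area is None else np.asarray(area, dtype=float)
    times = np.arange(nt) * (0.8 / max(nt, 1))
    return hf.WallField(x=s.copy(), s=s, ess=ess, times=times, area=area,
                        wall_mu=np.full_like(ess, 0.0035), segment=segment)
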