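import numpy as np
import pytest

import podonano as pn


@pytest.fixture(scope="session")
def default_layout():
    """A seeded default sealing-zone layout (~50 cores in 8 islets)."""
    return pn.make_layout(pn.LayoutParams(seed=1))


@pytest.fixture(scope="session")
def default_frame(default_layout):
    """A rendered noisy frame of the default layout."""
    return pn.render_frame(default_layout, rng=1)


@pytest.fixture(scope="session")
def truth_cores(default_layout):
    """Ground-truth core coordinates of the default layout as a CoreSet."""
    df = default_layout.cores
    return pn.CoreSet.from_arrays(df.x_nm, df.y_nm, core_id=df.core_id)


def single_core_layout(radius_nm=100.0, base=50.0, field=3000.0,
                       x=None, y=None):
    """A layout with exactly one core, placed explicitly (test helper)."""
    import pandas as pd
    from podonano.synthetic import GroundTruthLayout
    x = field / 2 if x is None else x
    y = field / 2 if y is None else y
    cores = pd.DataFrame({"core_id": [0], "islet_id": [0], "x_nm": [x],
                          "y_nm": [y], "radius_nm": [radius_nm],
                          "base_intensity": [base]})
    islets = pd.DataFrame({"islet_id": [0], "x_nm": [x], "y_nm": [y]})
    return GroundTruthLayout(cores, islets, (field, field), 850.0)


def row_layout(xs, y, field=(8000.0, 4000.0), radius_nm=100.0, base=50.0):
    """A belt-like layout: one islet, cores in a horizontal row."""
    import pandas as pd
    from podonano.synthetic import GroundTruthLayout
    xs = np.asarray(xs, float)
    cores = pd.DataFrame({"core_id": np.arange(len(xs)), "islet_id": 0,
                          "x_nm": xs, "y_nm": float(y),
                          "radius_nm": radius_nm, "base_intensity": base})
    islets = pd.DataFrame({"islet_id": [0], "x_nm": [xs.mean()],
                           "y_nm": [float(y)]})
    return GroundTruthLayout(cores, islets, field, 850.0)
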