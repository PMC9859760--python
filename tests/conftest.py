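import numpy as np
import pandas as pd
import pytest

from dolinekit.cap_geometry import coat_preset
from dolinekit.smlm import COLUMNS, LocalizationTable


@pytest.fixture(scope="session")
def cav1():
    return coat_preset("cav1")


@pytest.fixture(scope="session")
def ptrf():
    return coat_preset("ptrf")


def make_table(frames, x, y, sigma=None, intensity=None, uncertainty=None,
               roi_area=1e6, roi_polygon=None) -> LocalizationTable:
    """Small helper: build a LocalizationTable from column arrays with
    filter-passing defaults."""
    n = len(x)
    df = pd.DataFrame({
        "frame": np.asarray(frames, dtype=int),
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
        "sigma": np.full(n, 150.0) if sigma is None else np.asarray(sigma, float),
        "intensity": (np.full(n, 1000.0) if intensity is None
                      else np.asarray(intensity, float)),
        "uncertainty": (np.full(n, 15.0) if uncertainty is None
                        else np.asarray(uncertainty, float)),
    })[list(COLUMNS)]
    return LocalizationTable(df, roi_area=roi_area, roi_polygon=roi_polygon)
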