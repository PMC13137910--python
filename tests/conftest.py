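import numpy as np
import pandas as pd
import pytest

from nitromics.containers import IntensityMatrix, make_design, raw_design


@pytest.fixture
def design4():
    """Donor-free 2x2 design with 2 replicates per cell (8 samples)."""
    return make_design(donors=("none",), n_replicates=2)


@pytest.fixture
def intensity_factory(design4):
    """Build a small IntensityMatrix from a values array (NaN = missing)."""

    def build(values, scale_state="linear", design=None):
        design = design4 if design is None else design
        values = np.asarray(values, dtype=float)
        frame = pd.DataFrame(values,
                             index=[f"F{i}" for i in range(values.shape[0])],
                             columns=design["sample_id"].to_numpy())
        return IntensityMatrix(frame, design, scale_state)

    return build


@pytest.fixture
def raw16():
    """16-sample cell-line-like design (4 replicates per cell)."""
    return raw_design(4)
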