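import numpy as np
import pandas as pd
import pytest

from spatialsr.data_model import CellTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cells():
    """Two samples, three cell types, hand-placed coordinates."""
    rows = []
    for sid, offset in (("s1", 0.0), ("s2", 1000.0)):
        rows += [
            (sid, 0.0 + offset, 0.0, "cancer"),
            (sid, 3.0 + offset, 4.0, "cd8_t"),
            (sid, 10.0 + offset, 0.0, "cancer"),
            (sid, 5.0 + offset, 5.0, "negative"),
        ]
    df = pd.DataFrame(rows, columns=["sample_id", "x", "y", "cell_type"])
    return CellTable.from_dataframe(df)


def make_cell_table(points_by_type: dict, sample_id: str = "s") -> CellTable:
    """Build a single-sample CellTable from {cell_type: (n,2) array}."""
    frames = []
    for ct, pts in points_by_type.items():
        pts = np.atleast_2d(pts)
        if pts.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {"sample_id": sample_id, "x": pts[:, 0], "y": pts[:, 1], "cell_type": ct}
            )
        )
    return CellTable.from_dataframe(pd.concat(frames, ignore_index=True))
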