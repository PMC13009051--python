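import numpy as np
import pandas as pd
import pytest

from shapegrade.mask_io import SegmentationMask
from shapegrade.synthetic_shapes import CohortSpec, simulate_cohort


@pytest.fixture
def single_voxel_mask():
    vox = np.zeros((3, 3, 3), dtype=np.uint8)
    vox[1, 1, 1] = 1
    return SegmentationMask(vox)


@pytest.fixture(scope="session")
def ball_r20():
    from shapegrade.synthetic_shapes import make_ball

    return make_ball(20.0, 1.0)


def cohort_frame(seed: int, coupling: float = 0.45, mode: str = "tabular", **kw) -> pd.DataFrame:
    """Tabular cohort as the analysis-facing DataFrame."""
    recs = simulate_cohort(CohortSpec(seed=seed, coupling=coupling, **kw), mode)
    rows = []
    for r in recs:
        row = {"case_id": r.case_id, "who_grade": r.who_grade, "mitotic_rate": r.mitotic_rate}
        if r.features is not None:
            row.update(r.features.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cohort():
    return cohort_frame(seed=1)
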