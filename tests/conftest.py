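import numpy as np
import pandas as pd
import pytest

from glymseg import RegionSeries


@pytest.fixture
def noiseless_series():
    """Exact plateau-then-slope data: baseline 10 until 2 h, then slope 5/h."""
    t = np.array([-1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.where(t <= 2.0, 10.0, 10.0 + 5.0 * (t - 2.0))
    return RegionSeries(cohort="REF", region="test", time_h=t, signal=y)


@pytest.fixture
def scan_frame():
    """Small long-format scan table: two subjects, two segments, two cohorts."""
    rows = []
    for cohort, subjects in (("REF", ["r1", "r2"]), ("IIH", ["i1", "i2"])):
        for subj in subjects:
            for t in (-0.5, 0.5, 2.0, 4.0, 6.0):
                for seg, vol in (("ctx-lh-frontal", 100.0), ("ctx-rh-frontal", 300.0)):
                    rows.append(
                        dict(subject_id=subj, cohort=cohort, region=seg,
                             time_h=t, signal=1.0 + max(t - 1.5, 0) * 0.05,
                             volume_mm3=vol)
                    )
    return pd.DataFrame(rows)
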