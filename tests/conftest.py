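import numpy as np
import pandas as pd
import pytest

from gaitsig import GeneratorConfig, LINEAR, ONE_PHASE, generate_cohort
from gaitsig.kinematics import STRIDE_COLUMNS, StrideTable


def table_from_xy(v, y, parameter="stride_length_mm"):
    """Build a kinematically consistent StrideTable with ``parameter`` = y at
    velocity v.  Columns other than the focal parameter are derived so that
    the stride identities hold."""
    v = np.asarray(v, float)
    y = np.asarray(y, float)
    if parameter == "stride_length_mm":
        length = y
    else:
        length = np.full_like(v, 60.0)
    stride_s = length / 10.0 / v
    swing = 0.4 * stride_s
    data = pd.DataFrame(
        {
            "subject_id": "s0",
            "trial_id": "t0",
            "paw": "LH",
            "cue": "uncued",
            "stride_velocity_cm_s": v,
            "stride_length_mm": length,
            "stride_s": stride_s,
            "swing_s": swing,
            "stance_s": stride_s - swing,
            "cadence_per_s": 1.0 / stride_s,
            "swing_speed_mm_s": length / swing,
            "base_width_mm": np.nan,
        },
        columns=list(STRIDE_COLUMNS),
    )
    if parameter != "stride_length_mm":
        data[parameter] = y
    return StrideTable(data, {"source": "test"})


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def linear_cohort():
    cfg = GeneratorConfig(
        seed=42,
        generating_curves={
            "stride_length_mm": (LINEAR, (40.0, 2.0)),
            "swing_s": (LINEAR, (0.18, -0.004)),
        },
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def one_phase_cohort():
    cfg = GeneratorConfig(
        seed=9,
        generating_curves={
            "stride_length_mm": (ONE_PHASE, (30.0, 75.0, 0.25)),
            "swing_s": (LINEAR, (0.18, -0.004)),
        },
    )
    return generate_cohort(cfg)
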