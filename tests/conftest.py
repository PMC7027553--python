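import numpy as np
import pytest
from hypothesis import settings

from coldmeta import StudyRecord

settings.register_profile("default", deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def make_record():
    """Factory for valid, normalized study records."""

    def _make(**overrides):
        base = dict(
            study_id="s1", dataset_id="s1-tundra", response="N mineralization",
            mean_w=1.2, sd_w=0.4, n_w=5,
            mean_c=1.0, sd_c=0.5, n_c=5,
            latitude_deg=68.0, mat_c=-8.0, map_mm=400.0,
            depth_cm=5.0, delta_t=2.0, duration_yr=3.0, moisture_effect=-0.1,
            control_cluster="s1-c1",
        )
        base.update(overrides)
        return StudyRecord(**base)

    return _make
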