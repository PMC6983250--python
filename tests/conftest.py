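import numpy as np
import pytest

from mferg_emd.clusters import default_layout
from mferg_emd.recordings import (
    Cohort,
    MfERGRecording,
    N_SECTORS,
    DEFAULT_N_SAMPLES,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


def make_recording(
    subject_id: str,
    group: str,
    sector_fn,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> MfERGRecording:
    """Build a recording whose sector ``s`` trace is ``sector_fn(s)``."""
    sectors = {
        s: np.asarray(sector_fn(s), dtype=float) for s in range(1, N_SECTORS + 1)
    }
    return MfERGRecording(
        subject_id=subject_id, group=group, sectors=sectors, n_samples=n_samples
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cohort(rng):
    """Six controls + two patients with arbitrary finite traces."""
    recs = []
    for i in range(6):
        recs.append(
            make_recording(
                f"c{i}", "control", lambda s: rng.normal(0, 50, DEFAULT_N_SAMPLES)
            )
        )
    for i in range(2):
        recs.append(
            make_recording(
                f"p{i}", "patient", lambda s: rng.normal(0, 50, DEFAULT_N_SAMPLES)
            )
        )
    return Cohort(recs)
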