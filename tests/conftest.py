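import numpy as np
import pytest

from cprqual import events_from_arrays, reference_cohort


@pytest.fixture(scope="session")
def ref_cohort():
    """The shipped fixed-seed 19-attempt reference cohort."""
    return reference_cohort()


@pytest.fixture
def steady_record():
    """12 minutes of compressions every 0.55 s (~109/min), constant 45 mm."""
    times = np.arange(0.55, 720.0, 0.55)
    return events_from_arrays("steady", times, np.full(times.size, 45.0))


def make_record(times, depths=None, attempt_id="T", duration=720.0):
    times = np.asarray(times, dtype=float)
    if depths is None:
        depths = np.full(times.size, 45.0)
    return events_from_arrays(attempt_id, times, depths, duration=duration)
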