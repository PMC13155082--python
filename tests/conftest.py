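import numpy as np
import pytest
from hypothesis import settings

from metwear import ParticipantMeta, Recording

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

META = ParticipantMeta("18-29", "M")


def make_recording(x, y=None, z=None, annotation=None, participant_id="P001", meta=META, time=None):
    """Small-recording builder with sensible defaults for unit tests."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    y = np.asarray(y, dtype=float) if y is not None else np.zeros(n)
    z = np.asarray(z, dtype=float) if z is not None else np.ones(n)
    if annotation is None:
        annotation = np.array([None] * n, dtype=object)
    else:
        annotation = np.asarray(annotation, dtype=object)
    if time is None:
        time = np.arange(n, dtype=np.int64) * 10
    return Recording(participant_id, time, x, y, z, annotation, meta)


@pytest.fixture
def meta():
    return META
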