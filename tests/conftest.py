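import numpy as np
import pytest

from floorgait.dataset import (
    Dataset,
    EventAnnotation,
    EventClass,
    PersonStatus,
    Recording,
    StepBox,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(rng, n_channels=5, n_samples=400, rec_id="rec",
                   event_class=EventClass.WALK_SINGLE,
                   status=PersonStatus.STAFF, boxes=None):
    channels = rng.standard_normal((n_channels, n_samples))
    n_persons = 2 if event_class is EventClass.WALK_MULTI else 1
    ann = EventAnnotation(event_class=event_class, person_status=status,
                          n_persons=n_persons, step_boxes=boxes or [])
    return Recording(channels=channels, rate_hz=100.0, id=rec_id, annotation=ann)


@pytest.fixture
def table2_dataset(rng):
    """Dataset with the reference stratum sizes: single walks 40 staff /
    18 elderly, multi walks 8/3, other 7/17."""
    composition = [
        (EventClass.WALK_SINGLE, PersonStatus.STAFF, 40),
        (EventClass.WALK_SINGLE, PersonStatus.ELDERLY, 18),
        (EventClass.WALK_MULTI, PersonStatus.STAFF, 8),
        (EventClass.WALK_MULTI, PersonStatus.ELDERLY, 3),
        (EventClass.OTHER, PersonStatus.STAFF, 7),
        (EventClass.OTHER, PersonStatus.ELDERLY, 17),
    ]
    recs = []
    for ec, st, n in composition:
        for i in range(n):
            recs.append(make_recording(rng, n_channels=2, n_samples=50,
                                       rec_id=f"{ec.value}_{st.value}_{i}",
                                       event_class=ec, status=st))
    return Dataset(recs)
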